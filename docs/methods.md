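# Methods

## Phenotype classification

Samples carry a 3-character IHC code: position 1 = ER, 2 = PR, 3 = HER2.
A pattern pair assigns arms: a sample matching the TN pattern (default
`NNN`) goes to the TN arm, one matching the ER pattern (default `PXN`)
to the ER+ arm; `X` matches any character, everything else matches
case-sensitively.  The METABRIC dialect uses `Nn1` / `PX1` (`1` encodes
HER2−, lowercase `n` PR−); because matching is plain character
comparison, no dialect is special-cased.  Samples with no code or a
non-matching code are excluded before any statistic is computed.
Exclusion is a classification decision, not a parsing one: readers keep
such rows.

## Probe handling

Probes whose identifiers have been withdrawn from the annotation source
are removed.  Remaining probes are grouped by HUGO symbol and collapsed
by the **per-sample maximum**: for each gene and each sample
independently, the largest value over that gene's probes.  The collapsed
profile can therefore be chimeric across probes.  This differs from the
more common "keep the probe with the highest average signal" rule, which
is available as `collapse="global_max_mean"`; per-sample max is the
default because it is the rule the pipeline is specified around.
Gene symbols are uppercased at ingest, making all downstream gene
comparisons case-insensitive at a single normalization point.

## Per-cohort GSEA

*Ranking metric.* Signal-to-noise (μ_TN − μ_ER)/(σ'_TN + σ'_ER) with the
per-arm floor σ' = max(σ, 0.2·|μ|, 0.2).  The floor (a fixture of
two-class GSEA implementations) stops near-constant genes from
producing huge scores; it needs ≥ 2 samples per arm.  Ties in the metric
are broken by gene symbol so rankings are deterministic.

*Enrichment score.* Weighted KS running sum with default weight
exponent w = 1: hits add |r_i|^w normalized by the set's total, misses
subtract 1/(N − N_hits).  ES is the signed extremum of larger magnitude
(positive wins an exact tie).  The running sum returns to 0 at the end
of the list by construction (tolerance 1e−9 asserted in tests); ES is
invariant to positive rescaling of the metric.  If every hit metric is
exactly zero at w > 0 the walk falls back to unweighted increments so it
stays defined.  Sets are filtered by size *after* intersection with the
cohort's genes (defaults 15–500, matching the desktop tool).

*Leading edge.* For ES > 0, the set members at or before the peak; for
ES < 0, at or after the minimum.  These are the per-cohort "enriched
genes" that feed the consensus stage — the only GSEA construct that
yields a per-set gene list.

*Null and p-value.* Phenotype labels are permuted preserving arm sizes;
each permutation re-ranks all genes once and scores every set against
that ranking (one shared battery per cohort — the standard scheme, and
the only affordable one).  The nominal p is one-sided and sign-matched
with add-one smoothing, p = (b + 1)/(m + 1) where m counts same-sign
permutation scores and b those at least as extreme; p = 0 is therefore
impossible and the attainable floor is 1/(m + 1) ≈ 2/n_perm.  NES
divides ES by the mean magnitude of same-sign permutation scores; with
zero same-sign permutations NES is NaN and p degrades to 1.  All
randomness descends from one top-level seed via spawned per-cohort
substreams.

FDR q-values are deliberately not computed: the downstream meta-stage
consumes the nominal p only, and the final gate is a fixed threshold on
the combined p.

## Cross-cohort combination

For each set, available per-cohort p-values (clipped to each cohort's
permutation floor) are combined by Stouffer's weighted Z with
w_i = √n_i, n_i the cohort's TN + ER+ count — the classical sample-size
weighting, which also reproduces the published combined values from the
published inputs (w_i = n_i is available by config).  The combination is
one-sided in the TN direction; only positive-ES results are fed in by
the pipeline.  Sets missing from some cohorts (size-filtered on that
platform) are combined over the cohorts where they exist, the weight
normalization shrinking accordingly.  Sets are ranked by ascending
combined p (ties by name) and gated at p < .01 strictly.  No
multiple-testing correction is applied beyond that fixed gate, by
design.

Rounding note: combining published 3-decimal p-values cannot always
reproduce a published 3-decimal output exactly; one of the reference
rows computes to 0.0054, one printed ulp from its published 0.006, and
the tests treat agreement through interval propagation of the inputs'
half-ulp rounding.

## Consensus signatures and their fragility

A gene's *support* is the number of cohorts whose leading edge (for the
given set) contains it; the consensus signature keeps the genes at the
maximum observed support.  Support is counted over all cohorts where
the set was TN-enriched, whether or not that cohort's own p-value was
small — the construction the overall workflow implies.

The max-support rule is a 0–1 statistic and inherits a known
brittleness, visible in synthetic studies: when truly-shifted genes are
active in k of K cohorts (the generator's default is 6 of 7, drawn per
gene), the intended outcome is max support k with the signature equal
to the shifted genes.  But if *any* single shifted gene lands in the
leading edge of its inactive cohort by chance — which requires only a
~2.5σ ranking fluctuation among the null genes and so happens with
appreciable probability per study — the maximum jumps to K and the
signature collapses to the one or two lucky genes.  Synthetic
replicates at the default study scale show 1–3 of 5 planted signatures
collapsing this way in every run, capping pooled recovery of
truly-shifted genes well below what the healthy signatures (100%
recovery) achieve.  The package implements the rule as defined and
reports support counts alongside the signature so users can see when a
signature rests on a thin max-support margin; a robust variant (e.g.
support ≥ k − 1) is an obvious extension but is not part of the
reference workflow and is not implemented.

## Drug matching

Perturbation collections follow the MSigDB c2.cgp convention of
`_UP`/`_DN` name suffixes.  A perturbation set covers a signature when
|signature ∩ set| / |signature| ≥ 0.5 — the denominator is the
*signature* size, inclusive at exactly 50%.  Only passing `_DN` matches
appear in the down-regulator report; `_UP` and suffix-less sets are
never reported as down-regulators.

## Synthetic study generator

The generator emulates the data model the analysis assumes, not any
particular platform: per-gene baselines μ_g ~ Normal(7, 1) on a
log-intensity-like scale drawn once per study, samples Normal(μ_g, σ)
with σ = 1, and planted TN shifts of δ·σ.  Defaults are the study
conditions: seven cohorts with the published arm sizes (2088 samples
total, two cohorts using the METABRIC IHC dialect), 2000 genes, 50
motif sets of 20–60 genes, 5 planted sets, effect size δ = 1, penetrance
π = 0.6 (fraction of a set's genes truly shifted — what creates partial
leading edges), per-gene cohort participation κ = 6/7, 1–3 probes per
gene with jitter sd 0.05, 2% withdrawn probes, 3 unlabeled samples per
cohort.  Matched `_DN` perturbation sets contain 60% of a planted set's
shifted genes (decoys 20%) padded with unrelated genes to 100 members.

What this does *not* emulate: platform-specific normalization,
heavy-tailed or gene-correlated noise, probe cross-hybridization, and
biological covariation between gene sets beyond literal membership
overlap.  Passing tests on this generator therefore demonstrate
correctness of the machinery and the statistical behavior of the
workflow under a clean additive model — not performance on real
microarray or RNA-seq data.

## Numerical and scale choices

Permutation counts: 1000 by default in the API; synthetic validation
runs use 200 (full study ≈ 20 s) and unit tests smaller batteries —
sizes chosen to keep the add-one p-value floor (≈ 0.01 at 200
permutations) comfortably below the per-cohort evidence the combined
gate needs.  p-values are clipped to [1/(n_perm+1), 1 − 1/(n_perm+1)]
before Φ⁻¹ so display-rounded zeros cannot produce infinite Z.  Ranks,
set order and gene order in every output are deterministic (lexicographic
tie-breaks throughout), making pipeline reruns byte-identical for a
fixed config and seed.
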