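"""Gene set enrichment analysis for a two-arm (TN vs ER+) cohort.

The implementation follows the classic two-class GSEA recipe:

1. Rank every gene by the signal-to-noise ratio between the TN and ER+
   arms, ``(mu_TN - mu_ER) / (sigma_TN + sigma_ER)``, with a per-arm
   standard-deviation floor ``sigma' = max(sigma, 0.2*|mu|, 0.2)`` so
   near-constant genes cannot dominate the ranking.  Positive scores mean
   higher expression in TN.
2. For each gene set, walk the ranked list accumulating a weighted
   Kolmogorov–Smirnov running sum: a hit at rank *i* adds
   ``|r_i|^w / sum_hits |r|^w`` and a miss subtracts ``1/(N - N_hits)``.
   The enrichment score (ES) is the signed maximum deviation from zero,
   and the leading edge is the subset of hits at or before the maximum
   (for positive ES; at or after the minimum for negative ES).
3. The null is built by permuting phenotype labels while preserving arm
   sizes, re-ranking, and recomputing ES.  The nominal p-value is the
   one-sided, sign-matched exceedance fraction with add-one smoothing,
   ``(b + 1) / (m + 1)``, and the normalized ES (NES) divides the
   observed ES by the mean magnitude of same-sign permuted scores.

Permutations are shared across all sets of a collection within one call
to :func:`run_gsea` (one re-ranking serves every set), which is both the
standard phenotype-permutation scheme and the only affordable one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import GeneSet, GeneSetCollection
from .preprocess import ExpressionCohort

__all__ = [
    "GseaParams",
    "RankedList",
    "EnrichmentResult",
    "signal_to_noise",
    "rank_genes",
    "enrichment_score",
    "permutation_null",
    "run_gsea",
]

TN_ENRICHED = "TN_enriched"
ER_ENRICHED = "ER_enriched"


@dataclass(frozen=True)
class GseaParams:
    """Knobs of a GSEA run (defaults mirror the desktop tool's)."""

    min_size: int = 15
    max_size: int = 500
    n_perm: int = 1000
    weight_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.min_size < 1 or self.max_size < self.min_size:
            raise ValueError("invalid set-size filter")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.weight_exponent < 0:
            raise ValueError("weight exponent must be >= 0")


@dataclass(frozen=True)
class RankedList:
    """Genes in descending metric order with their metric values."""

    genes: tuple[str, ...]
    metric: np.ndarray

    def __post_init__(self) -> None:
        metric = np.asarray(self.metric, dtype=float)
        if metric.shape != (len(self.genes),):
            raise ValueError("metric length must match gene count")
        if np.any(np.diff(metric) > 0):
            raise ValueError("metric must be non-increasing")
        object.__setattr__(self, "metric", metric)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-(cohort, gene set) GSEA output."""

    set_name: str
    es: float
    nes: float
    p_nominal: float
    leading_edge: tuple[str, ...]
    n_perm: int
    direction: str  # TN_enriched | ER_enriched

    @property
    def p_floor(self) -> float:
        """Smallest attainable nominal p given the permutation count."""
        return 1.0 / (self.n_perm + 1)


# ---------------------------------------------------------------------------
# Ranking metric
# ---------------------------------------------------------------------------

def _floored_std(values: np.ndarray, axis: int) -> np.ndarray:
    mu = values.mean(axis=axis)
    sd = values.std(axis=axis, ddof=1)
    return np.maximum(sd, np.maximum(0.2 * np.abs(mu), 0.2))


def signal_to_noise(
    cohort: ExpressionCohort, tn_mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-gene signal-to-noise score, positive = higher in TN.

    ``tn_mask`` overrides the cohort's own labels (used by the
    permutation null); it must preserve the arm sizes.
    """
    mask = cohort.tn_mask if tn_mask is None else np.asarray(tn_mask, bool)
    return _snr(cohort.values, mask)


def _snr(values: np.ndarray, tn_mask: np.ndarray) -> np.ndarray:
    n_tn = int(tn_mask.sum())
    n_er = int((~tn_mask).sum())
    if n_tn < 2 or n_er < 2:
        raise ValueError(
            "signal-to-noise needs >= 2 samples per arm (the variance in "
            "each arm must be estimable); smaller arms are unsupported"
        )
    tn = values[:, tn_mask]
    er = values[:, ~tn_mask]
    return (tn.mean(axis=1) - er.mean(axis=1)) / (
        _floored_std(tn, 1) + _floored_std(er, 1)
    )


def rank_genes(
    cohort: ExpressionCohort, tn_mask: np.ndarray | None = None
) -> RankedList:
    """Rank genes by descending signal-to-noise.

    Ties are broken by gene symbol (ascending) so the ranking — and
    everything downstream of it — is deterministic.
    """
    metric = signal_to_noise(cohort, tn_mask)
    genes = np.asarray(cohort.genes)
    # lexsort: last key is primary.  Sort by -metric, then symbol.
    order = np.lexsort((genes, -metric))
    return RankedList(genes=tuple(genes[order]), metric=metric[order])


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def _running_sum(
    abs_metric_w: np.ndarray, hit_mask: np.ndarray
) -> np.ndarray:
    """Weighted KS running sum over one ranked list (1-D helper)."""
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hits == n:
        raise ValueError(
            "gene set covers the whole ranked list; the KS walk is degenerate"
        )
    hit_weight = abs_metric_w * hit_mask
    total = hit_weight.sum()
    if total == 0:
        # All hit metrics are exactly zero (possible at w > 0); fall back
        # to the unweighted increment so the walk stays defined.
        hit_weight = hit_mask / n_hits
    else:
        hit_weight = hit_weight / total
    steps = hit_weight - (~hit_mask) * (1.0 / (n - n_hits))
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedList,
    geneset: GeneSet | Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """ES, running sum, and leading-edge genes for one gene set.

    The ES is the running sum's signed maximum deviation from zero; on an
    exact magnitude tie between the maximum and the minimum the positive
    extremum wins.  The leading edge contains the hit genes at or before
    the maximum (positive ES) or at or after the minimum (negative ES).
    """
    members = (
        set(geneset.genes)
        if isinstance(geneset, GeneSet)
        else {g.upper() for g in geneset}
    )
    hit_mask = np.fromiter(
        (g in members for g in ranked.genes), dtype=bool, count=len(ranked)
    )
    abs_w = np.abs(ranked.metric) ** weight_exponent
    rs = _running_sum(abs_w, hit_mask)
    i_max = int(np.argmax(rs))
    i_min = int(np.argmin(rs))
    if rs[i_max] >= -rs[i_min]:
        es = float(rs[i_max])
        edge_mask = hit_mask[: i_max + 1]
        edge = tuple(np.asarray(ranked.genes)[: i_max + 1][edge_mask])
    else:
        es = float(rs[i_min])
        edge_mask = hit_mask[i_min:]
        edge = tuple(np.asarray(ranked.genes)[i_min:][edge_mask])
    if es == 0.0:
        edge = ()
    return es, rs, edge


def _batch_es(
    abs_metric_w: np.ndarray, hit_masks: np.ndarray
) -> np.ndarray:
    """Signed max-deviation ES for many sets over one ranked list.

    ``hit_masks`` is (n_sets, N) boolean in ranked order.  Degenerate
    rows (no hits or all hits) are the caller's responsibility.
    """
    n = abs_metric_w.size
    n_hits = hit_masks.sum(axis=1)
    totals = hit_masks @ abs_metric_w
    safe_totals = np.where(totals > 0, totals, 1.0)
    inc = hit_masks * (abs_metric_w / safe_totals[:, None])
    zero_rows = totals == 0
    if np.any(zero_rows):
        inc[zero_rows] = hit_masks[zero_rows] / n_hits[zero_rows, None]
    steps = inc - (~hit_masks) * (1.0 / (n - n_hits))[:, None]
    rs = np.cumsum(steps, axis=1)
    hi = rs.max(axis=1)
    lo = rs.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def _null_es(
    cohort: ExpressionCohort,
    member_masks: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    weight_exponent: float,
) -> np.ndarray:
    """(n_perm, n_sets) ES under phenotype-label permutation.

    ``member_masks`` is (n_sets, n_genes) boolean in cohort gene order.
    Each permutation draws a new TN assignment of the original arm size,
    re-ranks all genes, and scores every set against that one ranking.
    """
    n_samples = cohort.n
    n_tn = cohort.n_tn
    out = np.empty((n_perm, member_masks.shape[0]), dtype=float)
    for b in range(n_perm):
        perm = rng.permutation(n_samples)
        mask = np.zeros(n_samples, dtype=bool)
        mask[perm[:n_tn]] = True
        metric = _snr(cohort.values, mask)
        order = np.argsort(-metric, kind="stable")
        abs_w = np.abs(metric[order]) ** weight_exponent
        out[b] = _batch_es(abs_w, member_masks[:, order])
    return out


def _p_and_nes(es: float, null: np.ndarray) -> tuple[float, float]:
    """Sign-matched nominal p with add-one smoothing, and NES.

    With zero same-sign permutations the p-value degrades to 1 and the
    NES is undefined (NaN).
    """
    if es > 0:
        same = null[null > 0]
    elif es < 0:
        same = -null[null < 0]
    else:
        return 1.0, 0.0
    m = same.size
    if m == 0:
        return 1.0, float("nan")
    b = int(np.sum(same >= abs(es)))
    p = (b + 1) / (m + 1)
    nes = abs(es) / same.mean() * (1 if es > 0 else -1)
    return p, float(nes)


def permutation_null(
    cohort: ExpressionCohort,
    geneset: GeneSet,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    weight_exponent: float = 1.0,
) -> tuple[float, float]:
    """Nominal p-value and NES for a single gene set.

    Convenience wrapper around the shared-permutation machinery used by
    :func:`run_gsea`; results are reproducible given ``seed``.
    """
    ranked = rank_genes(cohort)
    es, _, _ = enrichment_score(ranked, geneset, weight_exponent)
    members = set(geneset.genes)
    mask = np.fromiter(
        (g in members for g in cohort.genes), dtype=bool, count=len(cohort.genes)
    )
    rng = np.random.default_rng(seed)
    null = _null_es(cohort, mask[None, :], n_perm, rng, weight_exponent)[:, 0]
    return _p_and_nes(es, null)


def run_gsea(
    cohort: ExpressionCohort,
    collection: GeneSetCollection,
    params: GseaParams = GseaParams(),
    seed: int | np.random.SeedSequence = 0,
) -> list[EnrichmentResult]:
    """Score every admissible set of a collection against one cohort.

    Sets are filtered by size *after* intersection with the cohort's
    genes (bounds ``[min_size, max_size]`` inclusive); filtered and
    zero-overlap sets are silently absent from the output.  One shared
    battery of ``n_perm`` label permutations serves all sets.
    """
    if len(collection) == 0:
        return []
    gene_index = {g: i for i, g in enumerate(cohort.genes)}
    n_genes = len(cohort.genes)
    kept: list[GeneSet] = []
    masks: list[np.ndarray] = []
    for s in collection:
        idx = [gene_index[g] for g in s.genes if g in gene_index]
        if not params.min_size <= len(idx) <= params.max_size:
            continue
        if len(idx) == n_genes:
            raise ValueError(
                f"gene set {s.name!r} covers every cohort gene; "
                "the enrichment walk is degenerate"
            )
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        kept.append(s)
        masks.append(mask)
    if not kept:
        return []
    member_masks = np.vstack(masks)

    ranked = rank_genes(cohort)
    observed = []
    for s in kept:
        es, _, edge = enrichment_score(ranked, s, params.weight_exponent)
        observed.append((es, edge))

    rng = np.random.default_rng(seed)
    null = _null_es(
        cohort, member_masks, params.n_perm, rng, params.weight_exponent
    )

    results = []
    for j, (s, (es, edge)) in enumerate(zip(kept, observed)):
        p, nes = _p_and_nes(es, null[:, j])
        results.append(
            EnrichmentResult(
                set_name=s.name,
                es=es,
                nes=nes,
                p_nominal=p,
                leading_edge=edge,
                n_perm=params.n_perm,
                direction=TN_ENRICHED if es >= 0 else ER_ENRICHED,
            )
        )
    return results
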