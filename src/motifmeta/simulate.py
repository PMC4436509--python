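"""Synthetic multi-cohort study generator.

Emulates the statistical structure the analysis assumes — several
breast-cancer expression cohorts with TN and ER+ arms, a promoter-motif
gene-set collection in which a few sets carry a genuine TN-enriched
module, and a perturbation collection containing matched ``_DN`` sets —
so the full pipeline can run and be validated without any download.

The generative model, per cohort:

* every gene g has a baseline level ``mu_g`` drawn once for the study
  (Normal(7, 1), a log-intensity-like scale) and samples scatter around
  it as ``Normal(mu_g, noise_sd)``;
* each planted motif set designates a fraction ``penetrance`` of its
  genes as truly shifted; each shifted gene is active in a fraction
  ``cohort_participation`` of the cohorts (chosen per gene), where its
  TN samples gain ``effect_size * noise_sd``.  Partial penetrance and
  partial participation are what produce realistic leading edges rather
  than whole-set shifts;
* genes are expanded into 1..max probes with small independent jitter,
  and a fraction of extra probes carry withdrawn identifiers;
* IHC codes use the plain dialect (``NNN`` / ``P?N``) in most cohorts
  and the METABRIC dialect (``Nn1`` / ``P?1``) in two, plus a few
  samples with no code at all.

Defaults mirror the seven published breast-cancer cohorts' arm sizes
(2088 samples in total).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .io import (
    WITHDRAWN,
    GeneSet,
    GeneSetCollection,
    PhenotypeTable,
    ProbeMap,
    RawExpression,
    write_expression,
    write_gmt,
    write_phenotypes,
    write_probe_map,
)
from .preprocess import PhenotypePattern
import pandas as pd

__all__ = [
    "PUBLISHED_COHORT_ARMS",
    "SimulationConfig",
    "GroundTruth",
    "CohortInputs",
    "SimulatedStudy",
    "simulate_cohorts",
    "simulate_perturbation_collection",
    "simulate_study",
    "write_study",
]

#: (n_TN, n_ER+) arm sizes of the seven published cohorts
#: (GSE25055, GSE25065, TCGA-BRCA, METABRIC discovery, METABRIC
#: validation, E2100, E2197).
PUBLISHED_COHORT_ARMS: tuple[tuple[int, int], ...] = (
    (114, 165),
    (64, 123),
    (58, 228),
    (69, 344),
    (52, 184),
    (49, 65),
    (191, 382),
)

_PLAIN = PhenotypePattern(tn="NNN", er="PXN")
_METABRIC = PhenotypePattern(tn="Nn1", er="PX1")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    cohort_arms: tuple[tuple[int, int], ...] = PUBLISHED_COHORT_ARMS
    #: cohorts (0-based indices) that use the METABRIC IHC dialect
    metabric_dialect: tuple[int, ...] = (3, 4)
    n_genes: int = 2000
    n_motif_sets: int = 50
    set_size_range: tuple[int, int] = (20, 60)
    n_planted_sets: int = 5
    effect_size: float = 1.0  # standardized TN mean shift (units of noise_sd)
    penetrance: float = 0.6  # fraction of a planted set's genes truly shifted
    cohort_participation: float = 6 / 7  # fraction of cohorts a gene shifts in
    max_probes_per_gene: int = 3
    withdrawn_fraction: float = 0.02  # extra withdrawn probes / mapped probes
    noise_sd: float = 1.0
    probe_jitter_sd: float = 0.05
    n_unlabeled_per_cohort: int = 3  # samples shipped without an IHC code
    #: perturbation collection: fraction of a planted set's shifted genes
    #: present in its matched _DN set, and in its low-containment decoy
    containment: float = 0.6
    decoy_containment: float = 0.2
    n_decoy_perturbations: int = 20
    perturbation_set_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_sets > self.n_motif_sets:
            raise ValueError("cannot plant more sets than the collection holds")
        if not 0 < self.penetrance <= 1:
            raise ValueError("penetrance must lie in (0, 1]")
        if not 0 < self.cohort_participation <= 1:
            raise ValueError("cohort_participation must lie in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError("invalid set_size_range")

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_arms)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for validation against pipeline output."""

    #: planted set name -> genes given a real TN shift
    shifted_genes: dict[str, tuple[str, ...]]
    #: gene -> cohort names in which its shift is active
    participation: dict[str, tuple[str, ...]]
    #: matched _DN perturbation set name -> planted set it targets
    matched_dn: dict[str, str]
    #: low-containment decoy _DN set name -> planted set it teases
    decoy_dn: dict[str, str]


@dataclass
class CohortInputs:
    """Everything the pipeline needs to ingest one cohort."""

    name: str
    raw: RawExpression
    phenotypes: PhenotypeTable
    probe_map: ProbeMap
    patterns: PhenotypePattern


@dataclass
class SimulatedStudy:
    cohorts: list[CohortInputs]
    motif_sets: GeneSetCollection
    truth: GroundTruth
    config: SimulationConfig

    @property
    def perturbations(self) -> GeneSetCollection:
        return simulate_perturbation_collection(self.truth, self.config)


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"GENE{i:0{width}d}" for i in range(1, n + 1)]


def _draw_motif_sets(
    rng: np.random.Generator, genes: list[str], config: SimulationConfig
) -> tuple[list[GeneSet], list[str]]:
    """Motif collection; the first ``n_planted_sets`` are the planted ones.

    Planted sets are drawn without replacement from disjoint gene pools
    so ground truth stays unambiguous; decoy sets sample freely.
    """
    lo, hi = config.set_size_range
    sets: list[GeneSet] = []
    pool = rng.permutation(len(genes))
    cursor = 0
    planted_names = []
    for k in range(config.n_planted_sets):
        size = int(rng.integers(lo, hi + 1))
        idx = pool[cursor : cursor + size]
        cursor += size
        name = f"V$PLANTED{k + 1:02d}_01"
        planted_names.append(name)
        sets.append(
            GeneSet(
                name=name,
                description="synthetic planted motif module",
                genes=tuple(genes[i] for i in idx),
            )
        )
    for k in range(config.n_motif_sets - config.n_planted_sets):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(genes), size=size, replace=False)
        sets.append(
            GeneSet(
                name=f"V$DECOY{k + 1:03d}_01",
                description="synthetic decoy motif set",
                genes=tuple(genes[i] for i in idx),
            )
        )
    return sets, planted_names


def simulate_cohorts(
    config: SimulationConfig = SimulationConfig(),
) -> SimulatedStudy:
    """Generate the full multi-cohort study.

    Deterministic given ``config.seed`` (all randomness flows through a
    single :class:`numpy.random.Generator`).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genes = _gene_names(config.n_genes)
    motif_sets, planted_names = _draw_motif_sets(rng, genes, config)

    cohort_names = [f"cohort{i + 1:02d}" for i in range(config.n_cohorts)]

    # Which genes of each planted set truly shift, and where.
    n_active_cohorts = max(
        1, round(config.cohort_participation * config.n_cohorts)
    )
    shifted: dict[str, tuple[str, ...]] = {}
    participation: dict[str, tuple[str, ...]] = {}
    gene_index = {g: i for i, g in enumerate(genes)}
    shift_matrix = np.zeros((config.n_genes, config.n_cohorts), dtype=bool)
    for name in planted_names:
        members = motif_sets[planted_names.index(name)].genes
        n_shift = max(1, round(config.penetrance * len(members)))
        chosen = rng.choice(len(members), size=n_shift, replace=False)
        chosen_genes = tuple(sorted(members[i] for i in chosen))
        shifted[name] = chosen_genes
        for g in chosen_genes:
            active = rng.choice(
                config.n_cohorts, size=n_active_cohorts, replace=False
            )
            participation[g] = tuple(cohort_names[i] for i in sorted(active))
            shift_matrix[gene_index[g], active] = True

    mu = rng.normal(7.0, 1.0, size=config.n_genes)

    cohorts: list[CohortInputs] = []
    for ci, (name, (n_tn, n_er)) in enumerate(
        zip(cohort_names, config.cohort_arms)
    ):
        patterns = _METABRIC if ci in config.metabric_dialect else _PLAIN
        n_unlabeled = config.n_unlabeled_per_cohort
        n_samples = n_tn + n_er + n_unlabeled
        expr = rng.normal(
            mu[:, None], config.noise_sd, size=(config.n_genes, n_samples)
        )
        # TN samples occupy the first columns; order is shuffled below.
        delta = config.effect_size * config.noise_sd
        expr[np.ix_(shift_matrix[:, ci], range(n_tn))] += delta

        sample_order = rng.permutation(n_samples)
        expr = expr[:, sample_order]
        sample_ids = [f"{name}_S{j + 1:04d}" for j in range(n_samples)]

        her2 = "1" if patterns is _METABRIC else "N"
        pr_tn = "n" if patterns is _METABRIC else "N"
        codes_in_order: list[str | None] = (
            ["N" + pr_tn + her2] * n_tn
            + ["P" + ("P" if rng.random() < 0.5 else "N") + her2
               for _ in range(n_er)]
            + [None] * n_unlabeled
        )
        codes = {
            sid: codes_in_order[sample_order[j]]
            for j, sid in enumerate(sample_ids)
        }

        # Expand genes into probes with jitter; append withdrawn probes.
        n_probes_per_gene = rng.integers(
            1, config.max_probes_per_gene + 1, size=config.n_genes
        )
        probe_rows = []
        probe_ids = []
        map_rows = []
        probe_counter = 0
        for gi, g in enumerate(genes):
            for _ in range(int(n_probes_per_gene[gi])):
                probe_counter += 1
                pid = f"{name}_P{probe_counter:06d}"
                probe_ids.append(pid)
                probe_rows.append(
                    expr[gi]
                    + rng.normal(0, config.probe_jitter_sd, size=n_samples)
                )
                map_rows.append((pid, f"ACC{gi + 1:05d}", g))
        n_withdrawn = round(config.withdrawn_fraction * len(probe_ids))
        for k in range(n_withdrawn):
            probe_counter += 1
            pid = f"{name}_P{probe_counter:06d}"
            probe_ids.append(pid)
            probe_rows.append(rng.normal(7.0, 1.0, size=n_samples))
            map_rows.append((pid, f"ACCW{k + 1:04d}", WITHDRAWN))

        cohorts.append(
            CohortInputs(
                name=name,
                raw=RawExpression(
                    probe_ids=probe_ids,
                    sample_ids=sample_ids,
                    values=np.vstack(probe_rows),
                ),
                phenotypes=PhenotypeTable(codes=codes),
                probe_map=ProbeMap(
                    table=pd.DataFrame(
                        map_rows, columns=["probe_id", "accession", "symbol"]
                    )
                ),
                patterns=patterns,
            )
        )

    truth = _build_truth(shifted, participation)
    return SimulatedStudy(
        cohorts=cohorts,
        motif_sets=GeneSetCollection(sets=tuple(motif_sets), kind="motif"),
        truth=truth,
        config=config,
    )


def _build_truth(
    shifted: dict[str, tuple[str, ...]],
    participation: dict[str, tuple[str, ...]],
) -> GroundTruth:
    matched = {
        f"EXP_TARGETS_{name.removeprefix('V$')}_DN": name for name in shifted
    }
    decoys = {
        f"EXP_WEAK_{name.removeprefix('V$')}_DN": name for name in shifted
    }
    return GroundTruth(
        shifted_genes=dict(shifted),
        participation=dict(participation),
        matched_dn=matched,
        decoy_dn=decoys,
    )


def simulate_perturbation_collection(
    truth: GroundTruth, config: SimulationConfig
) -> GeneSetCollection:
    """Perturbation (_DN/_UP) collection matched to the ground truth.

    For each planted set: one ``_DN`` set containing ``containment`` of
    its truly shifted genes (plus unrelated filler), one low-containment
    ``_DN`` decoy at ``decoy_containment``, and a population of unrelated
    ``_DN``/``_UP`` decoy sets with only chance overlap.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = _gene_names(config.n_genes)
    planted_genes = {g for gs in truth.shifted_genes.values() for g in gs}
    filler_pool = [g for g in genes if g not in planted_genes]
    sets: list[GeneSet] = []

    def build(name: str, target: tuple[str, ...], frac: float) -> GeneSet:
        n_take = round(frac * len(target))
        take = rng.choice(len(target), size=n_take, replace=False)
        members = [target[i] for i in sorted(take)]
        n_fill = max(0, config.perturbation_set_size - len(members))
        fill = rng.choice(len(filler_pool), size=n_fill, replace=False)
        members += [filler_pool[i] for i in fill]
        return GeneSet(
            name=name,
            description="synthetic perturbation set",
            genes=tuple(members),
        )

    for dn_name, set_name in truth.matched_dn.items():
        sets.append(build(dn_name, truth.shifted_genes[set_name], config.containment))
    for dn_name, set_name in truth.decoy_dn.items():
        sets.append(
            build(dn_name, truth.shifted_genes[set_name], config.decoy_containment)
        )
    for k in range(config.n_decoy_perturbations):
        suffix = "_DN" if k % 2 == 0 else "_UP"
        idx = rng.choice(
            len(filler_pool), size=config.perturbation_set_size, replace=False
        )
        sets.append(
            GeneSet(
                name=f"EXP_DECOY{k + 1:03d}{suffix}",
                description="synthetic unrelated perturbation set",
                genes=tuple(filler_pool[i] for i in idx),
            )
        )
    return GeneSetCollection(sets=tuple(sets), kind="perturbation")


def simulate_study(
    config: SimulationConfig = SimulationConfig(),
) -> SimulatedStudy:
    """Alias of :func:`simulate_cohorts` (returns the full study bundle)."""
    return simulate_cohorts(config)


def write_study(study: SimulatedStudy, outdir: str | Path) -> Path:
    """Materialize a study as the file dialects the readers consume.

    Writes per-cohort expression/phenotype/probe-map TSVs, the two GMT
    collections, a ground-truth YAML, and a ready-to-run pipeline config
    (``study.yaml``).  Returns the config path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_entries = []
    for c in study.cohorts:
        write_expression(c.raw, outdir / f"{c.name}_expression.tsv")
        write_phenotypes(c.phenotypes, outdir / f"{c.name}_phenotypes.tsv")
        write_probe_map(c.probe_map, outdir / f"{c.name}_probe_map.tsv")
        cohort_entries.append(
            {
                "name": c.name,
                "expression": f"{c.name}_expression.tsv",
                "phenotypes": f"{c.name}_phenotypes.tsv",
                "probe_map": f"{c.name}_probe_map.tsv",
                "tn_pattern": c.patterns.tn,
                "er_pattern": c.patterns.er,
            }
        )
    write_gmt(study.motif_sets, outdir / "motif_sets.gmt")
    write_gmt(study.perturbations, outdir / "perturbation_sets.gmt")
    truth = {
        "shifted_genes": {
            k: list(v) for k, v in study.truth.shifted_genes.items()
        },
        "participation": {
            k: list(v) for k, v in study.truth.participation.items()
        },
        "matched_dn": dict(study.truth.matched_dn),
        "decoy_dn": dict(study.truth.decoy_dn),
    }
    with open(outdir / "ground_truth.yaml", "w") as handle:
        yaml.safe_dump(truth, handle)
    config = {
        "cohorts": cohort_entries,
        "motif_gmt": "motif_sets.gmt",
        "perturbation_gmt": "perturbation_sets.gmt",
        "gsea": {"min_size": 15, "max_size": 500, "n_perm": 200,
                 "weight_exponent": 1.0},
        "alpha": 0.01,
        "overlap_threshold": 0.5,
        "weight_scheme": "sqrt_n",
        "seed": study.config.seed,
        "output_dir": "results",
    }
    config_path = outdir / "study.yaml"
    with open(config_path, "w") as handle:
        yaml.safe_dump(config, handle, sort_keys=False)
    return config_path
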