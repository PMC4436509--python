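"""End-to-end orchestration: cohorts → GSEA → meta → signatures → drugs.

A pipeline run is a pure function of (input files, config, seed): the
same config reproduces byte-identical output tables.  Stages:

1. read and build every cohort (probe collapse + IHC classification);
2. per-cohort GSEA of the motif collection; only TN-enriched (positive
   ES) sets proceed;
3. Stouffer weighted-Z combination across cohorts, gate at
   ``p < alpha``;
4. consensus signature per gated set from the per-cohort leading edges;
5. overlap of each signature with the perturbation collection, keeping
   passing ``_DN`` matches as candidate down-regulators.

Outputs mirror the published table shapes: ``table1.tsv`` (per-cohort
p-values plus combined Z/p per set), ``table2.tsv`` (consensus
signatures), ``table3.tsv`` (down-regulator matches), plus a cohort
summary and a log of parameters and per-stage counts.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu

from .drugs import PerturbationMatch, match_signature, report_down_regulators
from .gsea import GseaParams, run_gsea
from .io import (
    GeneSetCollection,
    read_expression,
    read_gmt,
    read_phenotypes,
    read_probe_map,
)
from .meta import (
    ConsensusSignature,
    MetaGeneSetResult,
    combine_cohorts,
    consensus_signature,
    gate_and_rank,
)
from .preprocess import ExpressionCohort, PhenotypePattern, build_cohort

__all__ = [
    "CohortSpec",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "compare_gene_expression",
    "summarize_cohorts",
]


@dataclass(frozen=True)
class CohortSpec:
    """Paths and phenotype patterns for one cohort."""

    name: str
    expression: Path
    phenotypes: Path
    probe_map: Path
    tn_pattern: str = "NNN"
    er_pattern: str = "PXN"

    @property
    def patterns(self) -> PhenotypePattern:
        return PhenotypePattern(tn=self.tn_pattern, er=self.er_pattern)


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of a full run (YAML-serializable)."""

    cohorts: tuple[CohortSpec, ...]
    motif_gmt: Path
    perturbation_gmt: Path
    gsea: GseaParams = GseaParams()
    alpha: float = 0.01
    overlap_threshold: float = 0.5
    weight_scheme: str = "sqrt_n"
    collapse: str = "per_sample_max"
    seed: int = 0
    output_dir: Path = Path("results")

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("config lists no cohorts")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        cohorts = tuple(
            CohortSpec(
                name=c["name"],
                expression=resolve(c["expression"]),
                phenotypes=resolve(c["phenotypes"]),
                probe_map=resolve(c["probe_map"]),
                tn_pattern=c.get("tn_pattern", "NNN"),
                er_pattern=c.get("er_pattern", "PXN"),
            )
            for c in raw["cohorts"]
        )
        gsea_raw = raw.get("gsea", {})
        return cls(
            cohorts=cohorts,
            motif_gmt=resolve(raw["motif_gmt"]),
            perturbation_gmt=resolve(raw["perturbation_gmt"]),
            gsea=GseaParams(
                min_size=int(gsea_raw.get("min_size", 15)),
                max_size=int(gsea_raw.get("max_size", 500)),
                n_perm=int(gsea_raw.get("n_perm", 1000)),
                weight_exponent=float(gsea_raw.get("weight_exponent", 1.0)),
            ),
            alpha=float(raw.get("alpha", 0.01)),
            overlap_threshold=float(raw.get("overlap_threshold", 0.5)),
            weight_scheme=raw.get("weight_scheme", "sqrt_n"),
            collapse=raw.get("collapse", "per_sample_max"),
            seed=int(raw.get("seed", 0)),
            output_dir=resolve(raw.get("output_dir", "results")),
        )


@dataclass
class PipelineResult:
    """In-memory view of a finished run."""

    cohorts: list[ExpressionCohort]
    enrichment: dict[str, list]  # cohort -> EnrichmentResult list (all signs)
    meta: list[MetaGeneSetResult]
    gated: list[MetaGeneSetResult]
    signatures: list[ConsensusSignature]
    matches: list[PerturbationMatch]
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    cohort_summary: pd.DataFrame
    output_dir: Path | None = None


def summarize_cohorts(cohorts: list[ExpressionCohort]) -> pd.DataFrame:
    """Per-cohort sample bookkeeping plus a grand-total row."""
    if not cohorts:
        raise ValueError("need at least one cohort")
    rows = [
        {"cohort": c.name, "n": c.n, "n_tn": c.n_tn, "n_er": c.n_er}
        for c in cohorts
    ]
    rows.append(
        {
            "cohort": "TOTAL",
            "n": sum(r["n"] for r in rows),
            "n_tn": sum(r["n_tn"] for r in rows),
            "n_er": sum(r["n_er"] for r in rows),
        }
    )
    return pd.DataFrame(rows)


def compare_gene_expression(
    cohort: ExpressionCohort, gene: str
) -> dict[str, float]:
    """Two-sided Mann–Whitney comparison of one gene between the arms.

    Returns the U statistic and p-value plus per-arm medians and 10th /
    90th percentiles (the display statistics of a box-and-whisker plot).
    """
    tn, er = cohort.gene_values(gene)
    stat, p = mannwhitneyu(tn, er, alternative="two-sided")
    return {
        "u_statistic": float(stat),
        "p_value": float(p),
        "tn_n": int(tn.size),
        "er_n": int(er.size),
        "tn_median": float(np.median(tn)),
        "er_median": float(np.median(er)),
        "tn_p10": float(np.percentile(tn, 10)),
        "tn_p90": float(np.percentile(tn, 90)),
        "er_p10": float(np.percentile(er, 10)),
        "er_p90": float(np.percentile(er, 90)),
    }


def _format_table1(
    meta: list[MetaGeneSetResult], cohort_names: list[str]
) -> pd.DataFrame:
    rows = []
    for m in meta:
        row: dict[str, object] = {"set_name": m.set_name}
        for c in cohort_names:
            row[f"p_{c}"] = m.cohort_pvalues.get(c, float("nan"))
        row["z_combined"] = m.z_combined
        row["p_combined"] = m.p_combined
        row["rank"] = m.rank
        rows.append(row)
    columns = (
        ["set_name"]
        + [f"p_{c}" for c in cohort_names]
        + ["z_combined", "p_combined", "rank"]
    )
    return pd.DataFrame(rows, columns=columns)


def _format_table2(signatures: list[ConsensusSignature]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [s.set_name for s in signatures],
            "n_genes": [len(s.genes) for s in signatures],
            "n_cohorts": [s.max_support for s in signatures],
            "genes": ["[" + " ".join(s.genes) + "]" for s in signatures],
        }
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and (if ``output_dir`` is set) persist tables."""
    t0 = time.perf_counter()
    log: list[str] = [
        f"seed={config.seed} alpha={config.alpha} "
        f"threshold={config.overlap_threshold} weights={config.weight_scheme} "
        f"collapse={config.collapse} gsea={config.gsea}"
    ]

    motif_sets = read_gmt(config.motif_gmt, kind="motif")
    perturbations = read_gmt(config.perturbation_gmt, kind="perturbation")
    log.append(
        f"collections: {len(motif_sets)} motif sets, "
        f"{len(perturbations)} perturbation sets"
    )

    cohorts: list[ExpressionCohort] = []
    for spec in config.cohorts:
        try:
            cohort = build_cohort(
                name=spec.name,
                raw=read_expression(spec.expression),
                probe_map=read_probe_map(spec.probe_map),
                pheno=read_phenotypes(spec.phenotypes),
                patterns=spec.patterns,
                collapse=config.collapse,
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage=preprocess cohort={spec.name!r}: {exc}"
            ) from exc
        cohorts.append(cohort)
        log.append(
            f"cohort {cohort.name}: n={cohort.n} "
            f"(TN={cohort.n_tn}, ER+={cohort.n_er}), "
            f"{len(cohort.genes)} genes after collapse"
        )

    seeds = np.random.SeedSequence(config.seed).spawn(len(cohorts))
    enrichment: dict[str, list] = {}
    for cohort, seed in zip(cohorts, seeds):
        t_c = time.perf_counter()
        try:
            enrichment[cohort.name] = run_gsea(
                cohort, motif_sets, config.gsea, seed=seed
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage=gsea cohort={cohort.name!r}: {exc}"
            ) from exc
        n_pos = sum(1 for r in enrichment[cohort.name] if r.es > 0)
        log.append(
            f"gsea {cohort.name}: {len(enrichment[cohort.name])} sets scored "
            f"({n_pos} TN-enriched), {config.gsea.n_perm} permutations, "
            f"{time.perf_counter() - t_c:.1f}s"
        )

    tn_enriched = {
        name: [r for r in rows if r.es > 0]
        for name, rows in enrichment.items()
    }
    cohort_sizes = {c.name: c.n for c in cohorts}
    meta = combine_cohorts(
        tn_enriched, cohort_sizes, weight_scheme=config.weight_scheme
    )
    gated = gate_and_rank(meta, alpha=config.alpha)
    log.append(f"meta: {len(meta)} sets combined, {len(gated)} pass p<{config.alpha}")

    signatures: list[ConsensusSignature] = []
    for m in gated:
        edges = {
            cohort: next(
                r.leading_edge
                for r in tn_enriched[cohort]
                if r.set_name == m.set_name
            )
            for cohort in m.cohort_pvalues
        }
        edges = {c: e for c, e in edges.items() if e}
        if not edges:
            log.append(f"signature {m.set_name}: all leading edges empty, skipped")
            continue
        signatures.append(consensus_signature(m.set_name, edges))
    log.append(f"signatures: {len(signatures)} consensus signatures built")

    matches: list[PerturbationMatch] = []
    for sig in signatures:
        matches.extend(
            match_signature(sig, perturbations, threshold=config.overlap_threshold)
        )
    table3 = report_down_regulators(matches)
    log.append(
        f"drug match: {sum(m.passes for m in matches)} passing overlaps, "
        f"{table3['perturbation_set'].nunique() if len(table3) else 0} "
        f"down-regulating perturbations"
    )
    log.append(f"total wall time {time.perf_counter() - t0:.1f}s")

    cohort_names = [c.name for c in cohorts]
    result = PipelineResult(
        cohorts=cohorts,
        enrichment=enrichment,
        meta=meta,
        gated=gated,
        signatures=signatures,
        matches=matches,
        table1=_format_table1(gated, cohort_names),
        table2=_format_table2(signatures),
        table3=table3,
        cohort_summary=summarize_cohorts(cohorts),
    )

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.table1.to_csv(outdir / "table1.tsv", sep="\t", index=False)
        result.table2.to_csv(outdir / "table2.tsv", sep="\t", index=False)
        result.table3.to_csv(outdir / "table3.tsv", sep="\t", index=False)
        result.cohort_summary.to_csv(
            outdir / "cohort_summary.tsv", sep="\t", index=False
        )
        for name, rows in enrichment.items():
            pd.DataFrame(
                {
                    "set_name": [r.set_name for r in rows],
                    "es": [r.es for r in rows],
                    "nes": [r.nes for r in rows],
                    "p_nominal": [r.p_nominal for r in rows],
                    "leading_edge": [",".join(r.leading_edge) for r in rows],
                }
            ).to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
        (outdir / "log.txt").write_text("\n".join(log) + "\n")
        result.output_dir = outdir
    return result
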