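"""Cross-cohort combination of enrichment p-values and consensus signatures.

Per-cohort GSEA yields one nominal p-value per (cohort, gene set).  Those
are combined with the Stouffer weighted-Z method,

    z_i = Phi^-1(1 - p_i),    Z = sum(w_i z_i) / sqrt(sum(w_i^2)),
    p_combined = 1 - Phi(Z),

with weights w_i = sqrt(n_i) by default (n_i = total samples of cohort i,
the classical sample-size weighting).  Sets are ranked by ascending
combined p and gated at p < alpha (default .01).

For each surviving set, the per-cohort leading edges are overlaid: a
gene's *support* is the number of cohorts whose leading edge contains it,
and the consensus "promoter motif signature" is the set of genes reaching
the maximum observed support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .gsea import EnrichmentResult

__all__ = [
    "MetaGeneSetResult",
    "ConsensusSignature",
    "stouffer_weighted_z",
    "combine_cohorts",
    "gate_and_rank",
    "consensus_signature",
]


@dataclass(frozen=True)
class MetaGeneSetResult:
    """Combined evidence for one gene set across cohorts."""

    set_name: str
    cohort_pvalues: dict[str, float]
    cohort_weights: dict[str, float]
    z_combined: float
    p_combined: float
    rank: int


@dataclass(frozen=True)
class ConsensusSignature:
    """Genes enriched in the maximum number of cohorts for one set."""

    set_name: str
    support_counts: dict[str, int]
    max_support: int
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


def stouffer_weighted_z(
    pvalues: Sequence[float],
    weights: Sequence[float] | None = None,
    p_floor: float | None = None,
) -> tuple[float, float]:
    """Combine one-sided p-values with the Stouffer weighted-Z method.

    Parameters
    ----------
    pvalues
        One-sided p-values, each in the open interval (0, 1) after
        optional clipping.
    weights
        Positive weights, one per p-value (default: all 1).  Scaling all
        weights by a common factor leaves the result unchanged.
    p_floor
        If given, p-values are clipped into ``[p_floor, 1 - p_floor]``
        first.  Permutation p-values reported as 0 (display rounding)
        would otherwise map to an infinite Z.

    Returns
    -------
    (z_combined, p_combined)
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != p.shape:
        raise ValueError("weights must match p-values in length")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    if p_floor is not None:
        if not 0 < p_floor < 0.5:
            raise ValueError("p_floor must lie in (0, 0.5)")
        p = np.clip(p, p_floor, 1.0 - p_floor)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p-values must lie in the open interval (0, 1)")
    z = norm.isf(p)
    z_combined = float(np.dot(w, z) / math.sqrt(float(np.dot(w, w))))
    return z_combined, float(norm.sf(z_combined))


def cohort_weight(n: int, scheme: str = "sqrt_n") -> float:
    """Stouffer weight of a cohort of total size ``n``."""
    if scheme == "sqrt_n":
        return math.sqrt(n)
    if scheme == "n":
        return float(n)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def combine_cohorts(
    results: Mapping[str, Sequence[EnrichmentResult]],
    cohort_sizes: Mapping[str, int],
    weight_scheme: str = "sqrt_n",
) -> list[MetaGeneSetResult]:
    """Combine per-cohort enrichment p-values set by set.

    ``results`` maps cohort name → that cohort's enrichment results (the
    caller decides which directions to feed in; the pipeline passes only
    TN-enriched sets).  A set absent from some cohorts — filtered by
    size on that platform, say — is combined over the cohorts where it
    is present; the weight normalization shrinks accordingly.  Each
    p-value is clipped at its own cohort's permutation floor
    ``1/(n_perm+1)``.  Output is sorted by ascending combined p, ties
    broken by set name, with 1-based ranks.
    """
    if not results:
        raise ValueError("need at least one cohort")
    missing = [c for c in results if c not in cohort_sizes]
    if missing:
        raise ValueError(f"no cohort size given for {missing}")
    per_set: dict[str, dict[str, EnrichmentResult]] = {}
    for cohort, rows in results.items():
        for r in rows:
            per_set.setdefault(r.set_name, {})[cohort] = r
    combined: list[MetaGeneSetResult] = []
    for set_name, by_cohort in per_set.items():
        cohorts = sorted(by_cohort)
        pvals = []
        weights = {}
        for c in cohorts:
            r = by_cohort[c]
            floor = r.p_floor
            pvals.append(min(max(r.p_nominal, floor), 1.0 - floor))
            weights[c] = cohort_weight(cohort_sizes[c], weight_scheme)
        z, p = stouffer_weighted_z(pvals, [weights[c] for c in cohorts])
        combined.append(
            MetaGeneSetResult(
                set_name=set_name,
                cohort_pvalues={c: by_cohort[c].p_nominal for c in cohorts},
                cohort_weights=weights,
                z_combined=z,
                p_combined=p,
                rank=0,
            )
        )
    combined.sort(key=lambda m: (m.p_combined, m.set_name))
    return [
        MetaGeneSetResult(
            set_name=m.set_name,
            cohort_pvalues=m.cohort_pvalues,
            cohort_weights=m.cohort_weights,
            z_combined=m.z_combined,
            p_combined=m.p_combined,
            rank=i + 1,
        )
        for i, m in enumerate(combined)
    ]


def gate_and_rank(
    meta: Sequence[MetaGeneSetResult], alpha: float = 0.01
) -> list[MetaGeneSetResult]:
    """Keep sets with combined p strictly below ``alpha``, order intact."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return [m for m in meta if m.p_combined < alpha]


def consensus_signature(
    set_name: str, leading_edges: Mapping[str, Sequence[str]]
) -> ConsensusSignature:
    """Overlay per-cohort leading edges into a consensus signature.

    ``leading_edges`` maps cohort name → leading-edge genes of this set
    in that cohort.  A gene's support is the number of cohorts listing
    it; the signature keeps the genes attaining the maximum support,
    sorted lexicographically.
    """
    support: dict[str, int] = {}
    for genes in leading_edges.values():
        for g in dict.fromkeys(x.upper() for x in genes):
            support[g] = support.get(g, 0) + 1
    if not support:
        raise ValueError(
            f"set {set_name!r}: every cohort's leading edge is empty"
        )
    max_support = max(support.values())
    genes = tuple(sorted(g for g, c in support.items() if c == max_support))
    return ConsensusSignature(
        set_name=set_name,
        support_counts=dict(sorted(support.items())),
        max_support=max_support,
        genes=genes,
    )
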