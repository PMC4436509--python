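"""Shared fixtures and the independent enrichment-score oracle."""

from __future__ import annotations

import numpy as np
import pytest

import motifmeta as mm


def brute_force_es(
    metric: np.ndarray, hits: np.ndarray, weight_exponent: float
) -> tuple[float, list[float]]:
    """Direct O(N) walk over the ranked list, written independently of
    the library's vectorized implementation.

    ``metric`` is the ranked (descending) metric, ``hits`` a boolean
    membership flag per position.  Returns (es, running sum) using the
    same sign convention: the extremum of larger magnitude wins, the
    positive one on an exact tie.
    """
    n = len(metric)
    n_hits = int(np.sum(hits))
    denom_hit = sum(abs(m) ** weight_exponent for m, h in zip(metric, hits) if h)
    miss_step = 1.0 / (n - n_hits)
    cur = 0.0
    rs = []
    for m, h in zip(metric, hits):
        if h:
            if denom_hit > 0:
                cur += abs(m) ** weight_exponent / denom_hit
            else:
                cur += 1.0 / n_hits
        else:
            cur -= miss_step
        rs.append(cur)
    hi = max(rs)
    lo = min(rs)
    es = hi if hi >= -lo else lo
    return es, rs


def random_ranked_instance(
    rng: np.random.Generator, max_n: int = 50
) -> tuple[mm.RankedList, list[str], float]:
    """A random (ranked list, gene set, weight) triple for oracle checks."""
    n = int(rng.integers(4, max_n + 1))
    metric = np.sort(rng.normal(0, 1, size=n))[::-1]
    genes = [f"G{i:03d}" for i in range(n)]
    k = int(rng.integers(1, n))  # at least one miss
    member_idx = rng.choice(n, size=k, replace=False)
    members = [genes[i] for i in member_idx]
    w = float(rng.choice([0.0, 1.0, 1.5, 2.0]))
    return mm.RankedList(genes=tuple(genes), metric=metric), members, w


@pytest.fixture(scope="session")
def small_study() -> mm.SimulatedStudy:
    """A three-cohort desk-scale study with two planted modules."""
    config = mm.SimulationConfig(
        cohort_arms=((30, 40), (25, 35), (20, 30)),
        metabric_dialect=(2,),
        n_genes=400,
        n_motif_sets=12,
        n_planted_sets=2,
        set_size_range=(15, 25),
        seed=11,
    )
    return mm.simulate_cohorts(config)


@pytest.fixture(scope="session")
def small_cohorts(small_study) -> list[mm.ExpressionCohort]:
    return [
        mm.build_cohort(c.name, c.raw, c.probe_map, c.phenotypes, c.patterns)
        for c in small_study.cohorts
    ]
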