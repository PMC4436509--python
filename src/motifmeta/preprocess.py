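"""Probe-to-gene collapse and TN / ER+ phenotype classification.

A cohort arrives as a probe × sample matrix plus a per-sample 3-character
IHC status code (ER, PR, HER2).  This module

* drops probes whose identifiers have been withdrawn,
* collapses multiple probes per HUGO symbol — by default taking, for each
  gene and each sample independently, the maximum value over that gene's
  probes (so a gene's profile may be chimeric across probes),
* assigns each sample to the triple-negative (TN) or ER-positive/HER2-
  negative (ERPOS) arm by matching its IHC code against a pattern pair,
  with ``X`` in a pattern matching any character,
* assembles the result into an :class:`ExpressionCohort`, dropping
  samples that match neither pattern or lack a code.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .io import WITHDRAWN, PhenotypeTable, ProbeMap, RawExpression

__all__ = [
    "Label",
    "PhenotypePattern",
    "ExpressionCohort",
    "collapse_probes",
    "classify_samples",
    "build_cohort",
]


class Label(str, Enum):
    """Phenotype arm of a sample."""

    TN = "TN"
    ERPOS = "ERPOS"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class PhenotypePattern:
    """A pair of 3-character IHC patterns selecting the two arms.

    Position 1 is ER status, position 2 PR, position 3 HER2.  ``X``
    matches any character; all other characters match case-sensitively,
    so the METABRIC dialect (``Nn1`` vs ``PX1``, where ``1`` encodes
    HER2−) works without special-casing.
    """

    tn: str = "NNN"
    er: str = "PXN"

    def __post_init__(self) -> None:
        for pattern in (self.tn, self.er):
            if len(pattern) != 3:
                raise ValueError(
                    f"phenotype pattern must have length 3, got {pattern!r}"
                )

    @staticmethod
    def _matches(code: str, pattern: str) -> bool:
        return len(code) == 3 and all(
            p == "X" or p == c for p, c in zip(pattern, code)
        )

    def classify(self, code: str | None) -> Label:
        if code is None:
            return Label.EXCLUDED
        if self._matches(code, self.tn):
            return Label.TN
        if self._matches(code, self.er):
            return Label.ERPOS
        return Label.EXCLUDED


@dataclass
class ExpressionCohort:
    """A collapsed gene × sample matrix restricted to the two arms."""

    name: str
    genes: list[str]
    sample_ids: list[str]
    values: np.ndarray  # gene x sample
    labels: list[Label]  # per sample, only TN / ERPOS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.sample_ids)):
            raise ValueError("matrix shape does not match gene/sample lists")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels do not match samples")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in cohort")
        if any(l not in (Label.TN, Label.ERPOS) for l in self.labels):
            raise ValueError("cohort may only contain TN / ERPOS samples")

    @property
    def tn_mask(self) -> np.ndarray:
        return np.array([l is Label.TN for l in self.labels], dtype=bool)

    @property
    def n_tn(self) -> int:
        return int(self.tn_mask.sum())

    @property
    def n_er(self) -> int:
        return len(self.labels) - self.n_tn

    @property
    def n(self) -> int:
        return len(self.labels)

    def gene_values(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """(TN values, ERPOS values) for one gene."""
        try:
            idx = self.genes.index(gene.upper())
        except ValueError:
            raise KeyError(f"gene {gene!r} not in cohort {self.name!r}") from None
        mask = self.tn_mask
        row = self.values[idx]
        return row[mask], row[~mask]


def collapse_probes(
    raw: RawExpression,
    probe_map: ProbeMap,
    method: str = "per_sample_max",
) -> tuple[list[str], np.ndarray]:
    """Collapse a probe × sample matrix to a gene × sample matrix.

    Withdrawn probes are removed first.  ``per_sample_max`` (default)
    takes, for each gene and each sample independently, the maximum over
    that gene's probes.  ``global_max_mean`` instead keeps the single
    probe with the highest mean expression across samples — the more
    common convention, offered as an escape hatch.

    Returns ``(genes, matrix)`` with genes sorted alphabetically.
    """
    if method not in ("per_sample_max", "global_max_mean"):
        raise ValueError(f"unknown collapse method {method!r}")
    symbols = probe_map.symbols
    unmapped = [p for p in raw.probe_ids if p not in symbols]
    if unmapped:
        raise ValueError(
            f"{len(unmapped)} probes missing from probe map "
            f"(first few: {unmapped[:5]})"
        )
    keep = [i for i, p in enumerate(raw.probe_ids) if symbols[p] != WITHDRAWN]
    if not keep:
        raise ValueError("no probes survive withdrawn-identifier removal")
    frame = pd.DataFrame(
        raw.values[keep],
        index=[symbols[raw.probe_ids[i]] for i in keep],
    )
    if method == "per_sample_max":
        collapsed = frame.groupby(level=0, sort=True).max()
    else:
        order = frame.mean(axis=1).to_numpy()
        pick = (
            pd.Series(order, index=frame.index)
            .groupby(level=0, sort=True)
            .idxmax()
        )
        # idxmax over a non-unique index returns labels; fall back to
        # positional selection to stay unambiguous.
        rows = []
        for gene in pick.index:
            positions = np.flatnonzero(frame.index == gene)
            best = positions[np.argmax(order[positions])]
            rows.append(frame.iloc[best].to_numpy())
        collapsed = pd.DataFrame(rows, index=list(pick.index))
    return list(collapsed.index), collapsed.to_numpy(dtype=float)


def classify_samples(
    pheno: PhenotypeTable, patterns: PhenotypePattern
) -> dict[str, Label]:
    """Label every sample TN / ERPOS / EXCLUDED by its IHC code."""
    return {sid: patterns.classify(code) for sid, code in pheno.codes.items()}


def build_cohort(
    name: str,
    raw: RawExpression,
    probe_map: ProbeMap,
    pheno: PhenotypeTable,
    patterns: PhenotypePattern,
    collapse: str = "per_sample_max",
) -> ExpressionCohort:
    """Collapse probes, classify samples, and drop the EXCLUDED ones."""
    missing = [s for s in raw.sample_ids if s not in pheno.codes]
    if missing:
        raise ValueError(
            f"cohort {name!r}: {len(missing)} expression samples lack a "
            f"phenotype row (first few: {missing[:5]})"
        )
    genes, matrix = collapse_probes(raw, probe_map, method=collapse)
    labels = classify_samples(pheno, patterns)
    keep = [
        i
        for i, s in enumerate(raw.sample_ids)
        if labels[s] is not Label.EXCLUDED
    ]
    kept_labels = [labels[raw.sample_ids[i]] for i in keep]
    n_tn = sum(l is Label.TN for l in kept_labels)
    n_er = len(kept_labels) - n_tn
    if n_tn == 0 or n_er == 0:
        raise ValueError(
            f"cohort {name!r}: empty arm after classification "
            f"(TN={n_tn}, ERPOS={n_er})"
        )
    return ExpressionCohort(
        name=name,
        genes=genes,
        sample_ids=[raw.sample_ids[i] for i in keep],
        values=matrix[:, keep],
        labels=kept_labels,
    )
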