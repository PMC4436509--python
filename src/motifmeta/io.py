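"""Readers and writers for the text formats the pipeline touches.

Formats
-------
* GMT (the MSigDB dialect): one gene set per line, ``name TAB description
  TAB gene TAB gene ...``.  Used for both the transcription-factor-target
  ("motif") collection and the chemical/genetic-perturbation collection.
* Expression matrix: tab-separated, probes (or genes) as rows, samples as
  columns; the first column holds probe identifiers, the first row sample
  identifiers.
* Phenotype table: tab-separated with columns ``sample_id`` and
  ``ihc_code``; the code is a 3-character ER/PR/HER2 status string such as
  ``NNN`` or ``PXN`` and may be empty (sample lacks IHC metadata).
* Probe map: tab-separated with columns ``probe_id``, ``accession`` and
  ``symbol``; a symbol equal to :data:`WITHDRAWN` marks a probe whose
  identifier has been withdrawn from the annotation source.

Gene symbols are uppercased at ingest so every downstream comparison is
case-insensitive via this single normalization point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WITHDRAWN",
    "GeneSet",
    "GeneSetCollection",
    "ProbeMap",
    "RawExpression",
    "PhenotypeTable",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "write_phenotypes",
    "read_probe_map",
    "write_probe_map",
]

#: Sentinel symbol marking a probe whose identifier has been withdrawn.
WITHDRAWN = "WITHDRAWN"


class GmtParseError(ValueError):
    """Raised for a structurally invalid GMT file."""


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, duplicate-free collection of gene symbols.

    Symbols are uppercased on construction; order of first appearance is
    preserved so files round-trip byte-identically.
    """

    name: str
    description: str = ""
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be nonempty")
        upper = [g.upper() for g in self.genes]
        deduped = tuple(dict.fromkeys(upper))
        if len(deduped) != len(upper):
            dupes = sorted({g for g in upper if upper.count(g) > 1})
            warnings.warn(
                f"gene set {self.name!r}: dropped duplicate genes {dupes}",
                stacklevel=2,
            )
        if not deduped:
            raise ValueError(f"gene set {self.name!r} has no genes")
        object.__setattr__(self, "genes", deduped)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.genes


@dataclass(frozen=True)
class GeneSetCollection:
    """A list of gene sets plus the collection's kind.

    ``kind`` distinguishes transcription-factor promoter-motif target
    collections (``"motif"``) from chemical/genetic perturbation
    collections with ``_UP``/``_DN`` pairs (``"perturbation"``).
    """

    sets: tuple[GeneSet, ...]
    kind: str = "motif"

    def __post_init__(self) -> None:
        if self.kind not in ("motif", "perturbation"):
            raise ValueError(f"unknown collection kind {self.kind!r}")
        object.__setattr__(self, "sets", tuple(self.sets))
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names in collection: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass(frozen=True)
class ProbeMap:
    """Probe → (accession/UniGene, HUGO symbol) mapping.

    ``symbol`` equal to :data:`WITHDRAWN` flags a withdrawn identifier;
    such probes are dropped during probe collapse.
    """

    table: pd.DataFrame  # columns: probe_id, accession, symbol

    def __post_init__(self) -> None:
        required = ["probe_id", "accession", "symbol"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"probe map missing columns {missing}")
        if self.table["probe_id"].duplicated().any():
            dupes = self.table.loc[
                self.table["probe_id"].duplicated(), "probe_id"
            ].tolist()
            raise ValueError(f"duplicate probe ids in map: {sorted(set(dupes))}")

    @property
    def symbols(self) -> Mapping[str, str]:
        """probe_id → uppercased symbol (withdrawn marker kept verbatim)."""
        return dict(
            zip(
                self.table["probe_id"],
                [
                    s if s == WITHDRAWN else s.upper()
                    for s in self.table["symbol"]
                ],
            )
        )

    def withdrawn_probes(self) -> list[str]:
        return self.table.loc[
            self.table["symbol"] == WITHDRAWN, "probe_id"
        ].tolist()


@dataclass
class RawExpression:
    """A probe × sample matrix of already-normalized expression values."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate {label} ids")
            if any(not i for i in ids):
                raise ValueError(f"empty {label} id")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.probe_ids, columns=self.sample_ids
        )


@dataclass
class PhenotypeTable:
    """Per-sample IHC status codes, kept verbatim (``None`` = absent).

    Codes are 3-character ER/PR/HER2 strings (e.g. ``"NNN"``, ``"PPN"``,
    ``"Nn1"``).  Interpretation — including wildcard matching and the
    METABRIC ``1``-for-HER2− dialect — is owned by the phenotype
    classifier, not the parser; samples without a code are retained here
    and excluded downstream.
    """

    codes: dict[str, str | None]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes)

    def __len__(self) -> int:
        return len(self.codes)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, kind: str = "motif") -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file into a :class:`GeneSetCollection`.

    Each line must carry at least three tab-separated fields: set name,
    description, and one or more gene symbols.  Symbols are uppercased;
    duplicates within a line are dropped with a warning.
    """
    sets: list[GeneSet] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: no genes listed")
            sets.append(GeneSet(name=name, description=description, genes=tuple(genes)))
    return GeneSetCollection(sets=tuple(sets), kind=kind)


def _sanitize_description(text: str) -> str:
    # GMT reserves tabs as field separators and newlines as record
    # separators; both are replaced by single spaces so files round-trip.
    return text.replace("\t", " ").replace("\n", " ")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT.  ``read_gmt`` inverts this exactly for
    collections whose descriptions contain no tabs or newlines; offending
    characters are replaced by spaces."""
    with open(path, "w", encoding="utf-8") as handle:
        for s in collection:
            desc = _sanitize_description(s.description) or "na"
            handle.write("\t".join([s.name, desc, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression / phenotypes / probe map
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> RawExpression:
    """Read a tab-separated probe × sample matrix (rows = probes)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates or frame.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate probe or sample ids")
    return RawExpression(
        probe_ids=[str(i) for i in frame.index],
        sample_ids=[str(c) for c in frame.columns],
        values=frame.to_numpy(dtype=float),
    )


def write_expression(raw: RawExpression, path: str | Path) -> None:
    raw.to_frame().to_csv(path, sep="\t", index_label="probe_id")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a two-column ``sample_id``/``ihc_code`` table.

    Rows with an empty code are retained with ``None`` — exclusion of
    samples lacking IHC metadata is a classification decision made
    downstream, not a parsing one.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "ihc_code"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if frame["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    codes: dict[str, str | None] = {}
    for sid, code in zip(frame["sample_id"], frame["ihc_code"]):
        codes[sid] = code if code else None
    return PhenotypeTable(codes=codes)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "sample_id": pheno.sample_ids,
            "ihc_code": [pheno.codes[s] or "" for s in pheno.sample_ids],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> ProbeMap:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return ProbeMap(table=frame)


def write_probe_map(probe_map: ProbeMap, path: str | Path) -> None:
    probe_map.table.to_csv(path, sep="\t", index=False)


def check_sample_consistency(raw: RawExpression, pheno: PhenotypeTable) -> None:
    """Cross-check that every expression sample has a phenotype row."""
    missing = [s for s in raw.sample_ids if s not in pheno.codes]
    if missing:
        raise ValueError(
            f"{len(missing)} expression samples missing from phenotype "
            f"table (first few: {missing[:5]})"
        )
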