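"""Match consensus signatures against perturbation gene-set collections.

Perturbation collections (MSigDB c2.cgp style) pair each experiment with
``_UP`` and ``_DN`` sets of genes it raised or lowered.  A perturbation
*covers* a promoter-motif signature when at least half of the
signature's genes appear in the perturbation set — the denominator is
the signature size, not the perturbation set size.  Experiments whose
``_DN`` set covers a signature are candidate down-regulators of the
motif's program, i.e. drug-repurposing leads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import GeneSetCollection
from .meta import ConsensusSignature

__all__ = [
    "PerturbationMatch",
    "parse_direction",
    "match_signature",
    "report_down_regulators",
]


@dataclass(frozen=True)
class PerturbationMatch:
    """Overlap of one signature with one perturbation gene set."""

    signature_name: str
    perturbation_set_name: str
    direction: str | None  # "DN", "UP", or None when the name has no suffix
    overlap_genes: tuple[str, ...]
    overlap_fraction: float
    passes: bool


def parse_direction(set_name: str) -> str | None:
    """Direction encoded in an MSigDB-style set name suffix.

    Returns ``"DN"`` or ``"UP"``, or ``None`` for names without the
    suffix — such sets are never reported as down-regulators.
    """
    if set_name.endswith("_DN"):
        return "DN"
    if set_name.endswith("_UP"):
        return "UP"
    return None


def match_signature(
    sig: ConsensusSignature,
    collection: GeneSetCollection,
    threshold: float = 0.5,
) -> list[PerturbationMatch]:
    """Overlap one signature with every set of a perturbation collection.

    ``overlap_fraction`` = |signature ∩ perturbation set| / |signature|;
    a match passes when the fraction is at least ``threshold``
    (inclusive, so exactly 50% passes at the default).  Matches are
    sorted by descending fraction, ties by set name.
    """
    if len(sig) == 0:
        raise ValueError(f"signature {sig.set_name!r} is empty")
    if collection.kind != "perturbation":
        raise ValueError(
            f"expected a perturbation collection, got kind={collection.kind!r}"
        )
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    sig_genes = set(sig.genes)
    matches = []
    for s in collection:
        overlap = tuple(sorted(sig_genes.intersection(s.genes)))
        fraction = len(overlap) / len(sig.genes)
        matches.append(
            PerturbationMatch(
                signature_name=sig.set_name,
                perturbation_set_name=s.name,
                direction=parse_direction(s.name),
                overlap_genes=overlap,
                overlap_fraction=fraction,
                passes=fraction >= threshold,
            )
        )
    matches.sort(key=lambda m: (-m.overlap_fraction, m.perturbation_set_name))
    return matches


def report_down_regulators(
    matches: Sequence[PerturbationMatch],
) -> pd.DataFrame:
    """Tabulate passing down-regulation matches, grouped by perturbation.

    Keeps only matches that pass the overlap criterion *and* come from a
    ``_DN`` set; ``_UP`` and suffix-less sets are excluded.  One row per
    (perturbation set, signature) with the found genes bracket-listed,
    perturbations ordered by their best overlap fraction.
    """
    kept = [m for m in matches if m.passes and m.direction == "DN"]
    best: dict[str, float] = {}
    for m in kept:
        best[m.perturbation_set_name] = max(
            best.get(m.perturbation_set_name, 0.0), m.overlap_fraction
        )
    kept.sort(
        key=lambda m: (
            -best[m.perturbation_set_name],
            m.perturbation_set_name,
            m.signature_name,
        )
    )
    return pd.DataFrame(
        {
            "perturbation_set": [m.perturbation_set_name for m in kept],
            "signature": [m.signature_name for m in kept],
            "n_found": [len(m.overlap_genes) for m in kept],
            "n_signature": [
                round(len(m.overlap_genes) / m.overlap_fraction)
                if m.overlap_fraction
                else 0
                for m in kept
            ],
            "overlap_fraction": [m.overlap_fraction for m in kept],
            "genes_found": [
                "[" + " ".join(m.overlap_genes) + "]" for m in kept
            ],
        }
    )
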