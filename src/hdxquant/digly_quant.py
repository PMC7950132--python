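"""Per-lysine ubiquitylation occupancy and chain-linkage usage from
peptide-evidence tables.

Trypsin cleaves ubiquitin's C-terminal Gly-Gly off a modified substrate
lysine, leaving a 114.04 Da "digly" remnant — the MS signature of a
ubiquitylation site.  Occupancy of a lysine is the label-free area ratio

    occupancy(K) = Σ area(peptides with digly at K) / Σ area(peptides covering K)

where the denominator counts every covering peptide (acetylated,
digly-modified, or otherwise) because chemical acetylation blocks all
unmodified lysines before digestion.  DiGly positions on ubiquitin itself
report chain linkage (K48, K63, ...).

Evidence tables are :class:`pandas.DataFrame` objects with columns
``sequence, protein_id, start, end, modifications, area, score`` where
``modifications`` holds a list of ``(position, type)`` pairs in 1-based
protein coordinates (see :mod:`hdxquant.io` for the CSV encoding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mass as pmass

__all__ = [
    "EvidenceRecord",
    "SiteOccupancy",
    "MODIFICATION_DELTAS",
    "PROTON_MASS",
    "ubiquitin_sequence",
    "filter_evidence",
    "site_occupancy",
    "linkage_summary",
    "monoisotopic_mass",
    "mz",
]

logger = logging.getLogger(__name__)

#: Monoisotopic mass deltas (Da) of supported modifications.
MODIFICATION_DELTAS = {
    "digly": 114.0429274,  # Gly-Gly remnant: 2 × glycine residue mass
    "acetyl": 42.01057,
    "carbamidomethyl": 57.02146,
}

PROTON_MASS = 1.007276

#: Ubiquitin lysines whose digly marks a chain linkage, plus linear (M1).
LINKAGE_POSITIONS = {1: "M1", 6: "K6", 11: "K11", 27: "K27", 29: "K29",
                     33: "K33", 48: "K48", 63: "K63"}


@dataclass(frozen=True)
class EvidenceRecord:
    """One peptide-spectrum evidence row."""

    sequence: str
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    modifications: tuple  # ((position, type), ...)
    area: float
    score: float  # -10 log P

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be non-negative")
        for pos, _ in self.modifications:
            if not self.start <= pos <= self.end:
                raise ValueError(
                    f"modification at {pos} outside peptide interval "
                    f"[{self.start}, {self.end}]"
                )


def ubiquitin_sequence() -> str:
    """Canonical human ubiquitin (76 residues), shipped with the package."""
    path = resources.files("hdxquant.data") / "ubiquitin_human.fasta"
    with path.open() as handle:
        return str(next(SeqIO.parse(handle, "fasta")).seq)


def filter_evidence(evidence: pd.DataFrame, score_cutoff: float = 15.0) -> pd.DataFrame:
    """Retain evidence rows with score strictly above the cutoff
    (−10 log P > 15 by default); rejections are logged."""
    keep = evidence["score"] > score_cutoff
    n_rej = int((~keep).sum())
    if n_rej:
        logger.info("%d evidence rows rejected at score cutoff > %g", n_rej, score_cutoff)
    return evidence[keep].copy()


def _digly_positions(mods) -> list[int]:
    return [pos for pos, kind in mods if kind == "digly"]


@dataclass(frozen=True)
class SiteOccupancy:
    position: int
    digly_area_sum: float
    total_area_sum: float
    occupancy: float | None  # None when the lysine has no covering evidence
    n_evidence: int


def site_occupancy(evidence: pd.DataFrame, protein_sequence: str) -> pd.DataFrame:
    """Area-ratio ubiquitylation occupancy for every lysine in the protein.

    A peptide covers lysine position p iff ``start <= p <= end``.  Lysines
    with no covering evidence are reported with occupancy NaN (no-coverage),
    distinct from a covered lysine with zero digly area (occupancy 0).
    Records placing a digly on a non-lysine position are rejected and
    logged.
    """
    lys_positions = [i + 1 for i, aa in enumerate(protein_sequence) if aa == "K"]
    valid_rows = []
    for row in evidence.itertuples(index=False):
        bad = [
            p for p in _digly_positions(row.modifications)
            if p > len(protein_sequence) or protein_sequence[p - 1] != "K"
        ]
        if bad:
            logger.warning(
                "evidence row %r rejected: digly at non-lysine position(s) %s",
                row.sequence, bad,
            )
            continue
        valid_rows.append(row)
    out = []
    for p in lys_positions:
        covering = [r for r in valid_rows if r.start <= p <= r.end]
        total = float(sum(r.area for r in covering))
        digly = float(
            sum(r.area for r in covering if p in _digly_positions(r.modifications))
        )
        occ = digly / total if covering and total > 0 else np.nan
        out.append((p, digly, total, occ, len(covering)))
    return pd.DataFrame(
        out,
        columns=["position", "digly_area_sum", "total_area_sum", "occupancy", "n_evidence"],
    )


def linkage_summary(
    evidence: pd.DataFrame, ub_sequence: str | None = None
) -> dict[str, float]:
    """Area fraction of each ubiquitin chain-linkage type.

    Evidence rows are peptides mapped onto ubiquitin; each digly position is
    classified by the lysine it sits on (or M1 for the linear linkage).
    Fractions sum to one over the observed linkages.  DiGly at any other
    ubiquitin position is rejected with a log entry.
    """
    if ub_sequence is None:
        ub_sequence = ubiquitin_sequence()
    areas: dict[str, float] = {}
    for row in evidence.itertuples(index=False):
        for p in _digly_positions(row.modifications):
            if p in LINKAGE_POSITIONS and (p == 1 or ub_sequence[p - 1] == "K"):
                link = LINKAGE_POSITIONS[p]
                areas[link] = areas.get(link, 0.0) + float(row.area)
            else:
                logger.warning(
                    "evidence row %r rejected: digly at ubiquitin position %d is "
                    "not a linkage site", row.sequence, p,
                )
    total = sum(areas.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in sorted(areas.items())}


def monoisotopic_mass(peptide: str, modifications=()) -> float:
    """Monoisotopic peptide mass (Da): residue masses + water + modification
    deltas.  ``modifications`` is an iterable of modification type names (or
    (position, type) pairs, positions ignored here)."""
    try:
        base = pmass.calculate_mass(sequence=peptide)
    except Exception as exc:
        raise ValueError(f"invalid peptide {peptide!r}: {exc}") from exc
    for mod in modifications:
        kind = mod[1] if isinstance(mod, (tuple, list)) else mod
        if kind not in MODIFICATION_DELTAS:
            raise ValueError(f"unknown modification {kind!r}")
        base += MODIFICATION_DELTAS[kind]
    return base


def mz(mass_da: float, charge: int) -> float:
    """m/z of an [M+zH]^z+ ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mass_da + charge * PROTON_MASS) / charge
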