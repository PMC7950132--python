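"""Forward simulation of complete HDX-MS experiments and diGly evidence tables.

The simulator realises the measurement design the analysis pipeline expects:
two (or more) conformational states labeled for 15/30/45/60/120 s in three
technical replicates plus undeuterated controls, observed as peptide-level
mass-envelope centroids with Gaussian instrument noise, after a uniform
global back-exchange loss.  Ground truth (per-residue protection factors,
the back-exchange fraction, noise level) is held in
:class:`GroundTruthSystem`, so every downstream estimate has a known answer.

Random streams are split per (peptide, state, exposure, replicate) from a
single seed, so enlarging the peptide map never reshuffles existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exchange_model import (
    StateDefinition,
    deuterium_fraction,
    exchangeable_amides,
    intrinsic_rates,
    uniform_intrinsic_rates,
)
from .envelope_centroid import DEUTERIUM_MASS_SHIFT, centroid, natural_envelope

__all__ = [
    "GroundTruthSystem",
    "PeptideMap",
    "PeptideEntry",
    "generate_peptide_map",
    "simulate_exchange_dataset",
    "simulate_evidence_table",
    "DEFAULT_TIMEPOINTS",
]

#: Deuteration times (s) of the standard labeling series.
DEFAULT_TIMEPOINTS = (15.0, 30.0, 45.0, 60.0, 120.0)


@dataclass
class GroundTruthSystem:
    """Truth object for one simulated experiment.

    Parameters
    ----------
    sequence : protein sequence (one-letter codes).
    states : conformational states to compare; each carries a per-residue
        log10 protection-factor profile over the same sequence.
    back_exchange_fraction : uniform fraction of incorporated deuterium lost
        after labeling (quench/chromatography), applied multiplicatively.
    centroid_noise_sd : Gaussian sd of the measured centroid, Da.
    timepoints : labeling durations, s, strictly increasing.
    n_replicates : technical replicates per condition.
    disordered_terminal_window : residues at each chain end forced to
        log10_P = 0 so the back-exchange estimator always has fully
        disordered terminal peptides to work from.
    pD, temperature_K : labeling conditions for the intrinsic-rate model.
    uniform_k_int : if set, replaces the sequence-dependent intrinsic rates
        with this uniform rate (1/s) — useful for controlled tests.
    """

    sequence: str
    states: list[StateDefinition]
    back_exchange_fraction: float = 0.25
    centroid_noise_sd: float = 0.02
    timepoints: tuple = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    disordered_terminal_window: int = 10
    pD: float = 8.0
    temperature_K: float = 298.0
    uniform_k_int: float | None = None

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("at least one state is required")
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError("state names must be unique")
        for s in self.states:
            if s.sequence != self.sequence:
                raise ValueError(f"state {s.name!r} sequence differs from system sequence")
        if not 0 <= self.back_exchange_fraction < 1:
            raise ValueError("back_exchange_fraction must lie in [0, 1)")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0 or np.any(tp <= 0) or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be positive and strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def intrinsic_rate_profile(self) -> np.ndarray:
        if self.uniform_k_int is not None:
            return uniform_intrinsic_rates(self.sequence, self.uniform_k_int)
        return intrinsic_rates(self.sequence, pD=self.pD, temperature_K=self.temperature_K)

    def effective_log10_P(self, state: StateDefinition) -> np.ndarray:
        """State profile with the terminal windows clamped to zero protection."""
        profile = state.log10_P_profile.copy()
        w = self.disordered_terminal_window
        if w > 0:
            profile[:w] = 0.0
            if w < len(profile):
                profile[-w:] = 0.0
            else:
                profile[:] = 0.0
        return profile


@dataclass(frozen=True)
class PeptideEntry:
    peptide_id: str
    sequence: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    max_uptake: int


@dataclass
class PeptideMap:
    """Pepsin-style catalog of peptides with residue intervals on the parent
    protein and per-peptide exchangeable-amide counts."""

    protein_sequence: str
    entries: list[PeptideEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.end < e.start:
                raise ValueError(f"{e.peptide_id}: end < start")
            if self.protein_sequence[e.start - 1 : e.end] != e.sequence:
                raise ValueError(f"{e.peptide_id}: sequence does not match protein slice")
            if e.max_uptake != exchangeable_amides(e.sequence):
                raise ValueError(f"{e.peptide_id}: max_uptake inconsistent with sequence")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def coverage_fraction(self) -> float:
        """Fraction of protein residues covered by at least one peptide."""
        covered = np.zeros(len(self.protein_sequence), dtype=bool)
        for e in self.entries:
            covered[e.start - 1 : e.end] = True
        return float(covered.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.peptide_id, e.sequence, e.start, e.end, e.max_uptake)
                for e in self.entries
            ],
            columns=["peptide_id", "sequence", "start", "end", "max_uptake"],
        )


def _peptide_id(start: int, end: int) -> str:
    return f"pep_{start:04d}_{end:04d}"


def generate_peptide_map(
    sequence: str,
    target_length: int = 10,
    overlap: int = 5,
    seed: int | None = None,
    length_jitter: int = 0,
) -> PeptideMap:
    """Tile a protein with overlapping pepsin-like peptides.

    Deterministic for a fixed seed; with ``length_jitter = 0`` the tiling is
    exact (step = target_length − overlap) and the final peptide is anchored
    at the C terminus so every residue is covered.
    """
    if target_length < 3:
        raise ValueError("target_length must be >= 3")
    if overlap >= target_length:
        raise ValueError("overlap must be smaller than target_length")
    if length_jitter < 0 or length_jitter >= target_length - 1:
        raise ValueError("length_jitter must be in [0, target_length-2]")
    n = len(sequence)
    rng = np.random.default_rng(seed)
    step = target_length - overlap
    entries: list[PeptideEntry] = []
    seen: set[tuple[int, int]] = set()

    def add(start: int, end: int) -> None:
        start, end = max(1, start), min(n, end)
        if (start, end) in seen:
            return
        seen.add((start, end))
        pep = sequence[start - 1 : end]
        entries.append(
            PeptideEntry(_peptide_id(start, end), pep, start, end, exchangeable_amides(pep))
        )

    if n <= target_length:
        add(1, n)
        return PeptideMap(sequence, entries)

    start = 1
    while start + target_length - 1 <= n:
        length = target_length + (
            int(rng.integers(-length_jitter, length_jitter + 1)) if length_jitter else 0
        )
        add(start, start + length - 1)
        start += step
    if entries[-1].end < n:
        add(n - target_length + 1, n)
    return PeptideMap(sequence, entries)


def _stream(seed: int, *parts) -> np.random.Generator:
    """Deterministic child generator keyed on string/int parts."""
    key = [int(seed)]
    for p in parts:
        if isinstance(p, str):
            key.append(zlib.crc32(p.encode()) & 0x7FFFFFFF)
        else:
            key.append(int(p) & 0x7FFFFFFF)
    return np.random.default_rng(key)


def _amide_indices(entry: PeptideEntry, sequence: str) -> np.ndarray:
    """0-based protein indices of the peptide's exchangeable amides (first
    peptide residue and prolines excluded)."""
    idx = [
        i
        for i in range(entry.start, entry.end)  # 0-based: start..end-1 skips first residue
        if sequence[i] != "P"
    ]
    return np.asarray(idx, dtype=int)


def simulate_exchange_dataset(
    system: GroundTruthSystem, peptide_map: PeptideMap, seed: int = 0
) -> pd.DataFrame:
    """Simulate a long-format centroid table for every (peptide, state,
    exposure, replicate), plus undeuterated control rows.

    The deuterated centroid is the control centroid plus
    ``DEUTERIUM_MASS_SHIFT × (1 − back_exchange) × Σ per-amide fractions``
    plus Gaussian centroid noise.  Bit-identical for a fixed seed.
    """
    if peptide_map.protein_sequence != system.sequence:
        raise ValueError("peptide map was built on a different sequence")
    k_int = system.intrinsic_rate_profile()
    rows = []
    timepoints = np.asarray(system.timepoints, dtype=float)
    for entry in peptide_map:
        ctrl_centroid = centroid(natural_envelope(entry.sequence))
        amides = _amide_indices(entry, system.sequence)
        for state in system.states:
            log10_P = system.effective_log10_P(state)
            k_obs = k_int[amides] / 10.0 ** log10_P[amides] if amides.size else np.array([])
            for rep in range(1, system.n_replicates + 1):
                noise = float(
                    _stream(seed, entry.peptide_id, state.name, "control", rep).normal(
                        0.0, system.centroid_noise_sd
                    )
                )
                rows.append(
                    (entry.peptide_id, entry.sequence, entry.start, entry.end,
                     entry.max_uptake, state.name, 0.0, rep, ctrl_centroid + noise, True)
                )
            for t in timepoints:
                total = float(np.sum(deuterium_fraction(k_obs, t))) if amides.size else 0.0
                shift = DEUTERIUM_MASS_SHIFT * (1.0 - system.back_exchange_fraction) * total
                for rep in range(1, system.n_replicates + 1):
                    noise = float(
                        _stream(
                            seed, entry.peptide_id, state.name, int(round(t * 1000)), rep
                        ).normal(0.0, system.centroid_noise_sd)
                    )
                    rows.append(
                        (entry.peptide_id, entry.sequence, entry.start, entry.end,
                         entry.max_uptake, state.name, float(t), rep,
                         ctrl_centroid + shift + noise, False)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide_id", "sequence", "start", "end", "max_uptake",
            "state", "exposure_s", "replicate", "centroid_da", "is_control",
        ],
    )


def simulate_evidence_table(
    protein: str,
    site_occupancy: dict,
    n_peptides_per_site: int = 50,
    area_scale: float = 1000.0,
    area_sigma: float = 0.3,
    score_range: tuple = (20.0, 60.0),
    max_flank: int = 10,
    protein_id: str = "protein",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a peptide-evidence table for diGly occupancy quantification.

    For each lysine position in ``site_occupancy`` (1-based, value = true
    ubiquitylated fraction), ``n_peptides_per_site`` covering peptides are
    emitted; ``round(occupancy × n)`` of them carry a digly remnant on that
    lysine and the remainder carry an acetyl (the chemically blocked,
    unmodified form).  Any *other* occupancy-site lysine a peptide happens
    to cover is likewise assigned digly/acetyl at that site's occupancy,
    stratified so the assigned fraction matches to rounding — every covered
    lysine carries a modification state, as after exhaustive acetylation —
    keeping the expected area ratio at each lysine equal to its requested
    occupancy even when sites sit close together.  Areas are lognormal
    around ``area_scale`` (exactly ``area_scale`` when ``area_sigma = 0``;
    the default sigma of 0.3 corresponds to the ~30% coefficient of
    variation typical of label-free peak areas).
    """
    n = len(protein)
    for pos in site_occupancy:
        if not 1 <= pos <= n or protein[pos - 1] != "K":
            raise ValueError(f"occupancy position {pos} is not a lysine in the protein")
        occ = site_occupancy[pos]
        if not 0 <= occ <= 1:
            raise ValueError(f"occupancy at K{pos} must lie in [0, 1]")
    raw = []  # (focal, i, start, end, area, score)
    for pos in sorted(site_occupancy):
        occ = site_occupancy[pos]
        n_digly = int(round(occ * n_peptides_per_site))
        rng = _stream(seed, "evidence", pos)
        for i in range(n_peptides_per_site):
            left = int(rng.integers(3, max_flank + 1))
            right = int(rng.integers(3, max_flank + 1))
            start = max(1, pos - left)
            end = min(n, pos + right)
            area = area_scale * (
                float(np.exp(rng.normal(0.0, area_sigma))) if area_sigma > 0 else 1.0
            )
            score = float(rng.uniform(*score_range))
            raw.append((pos, i < n_digly, start, end, area, score))
    # per-site modification states: focal rows are pre-assigned; rows that
    # merely cover the site get a stratified assignment at its occupancy
    assignments: dict[tuple[int, int], str] = {}
    for q in sorted(site_occupancy):
        cross = [j for j, r in enumerate(raw) if r[0] != q and r[2] <= q <= r[3]]
        k = int(round(site_occupancy[q] * len(cross)))
        for rank, j in enumerate(cross):
            assignments[(j, q)] = "digly" if rank * k // max(len(cross), 1) < (rank + 1) * k // max(len(cross), 1) else "acetyl"
    rows = []
    for j, (pos, is_digly, start, end, area, score) in enumerate(raw):
        mods = []
        for q in sorted(site_occupancy):
            if not start <= q <= end:
                continue
            if q == pos:
                mods.append((q, "digly" if is_digly else "acetyl"))
            else:
                mods.append((q, assignments[(j, q)]))
        rows.append((protein[start - 1 : end], protein_id, start, end, mods, area, score))
    return pd.DataFrame(
        rows,
        columns=["sequence", "protein_id", "start", "end", "modifications", "area", "score"],
    )
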