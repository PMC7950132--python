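"""Residue-level forward model of backbone amide H/D exchange under EX2 conditions.

Each backbone amide hydrogen exchanges with solvent deuterium at an observed
first-order rate ``k_obs = k_int / P``, where ``k_int`` is the intrinsic
(unstructured-chain) rate for that sequence position and ``P >= 1`` is the
protection factor contributed by structure.  The fraction deuterated after a
labeling time ``t`` is ``1 - exp(-k_obs * t)`` — the single-population EX2
limit in which a peptide's isotope envelope shifts smoothly with time.

Intrinsic rates follow the sequence-, pD- and temperature-dependent reference
factors of the poly-DL-alanine calibration (acid-, base- and water-catalysed
terms, each with its own side-chain correction and activation energy).  A
uniform-rate fallback is provided for tests that need kinetics decoupled from
sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResidueExchangeState",
    "StateDefinition",
    "intrinsic_rates",
    "uniform_intrinsic_rates",
    "deuterium_fraction",
    "exchangeable_amides",
    "STANDARD_RESIDUES",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

# Side-chain log10 corrections to the acid- and base-catalysed exchange of a
# backbone amide, relative to poly-DL-alanine.  "lambda" applies to the amide
# of the residue itself, "rho" to the amide of the following residue.  Values
# are the standard reference-table transcription for D2O with ionisable side
# chains in their near-neutral-pD forms; trans proline has no amide hydrogen
# of its own but still perturbs its successor.
#                 acid_lambda acid_rho base_lambda base_rho
_SIDECHAIN = {
    "A": (0.00, 0.00, 0.00, 0.00),
    "C": (-0.54, -0.46, 0.62, 0.55),
    "D": (0.90, 0.58, 0.10, -0.18),
    "E": (-0.90, 0.31, -0.11, -0.15),
    "F": (-0.52, -0.43, -0.24, 0.06),
    "G": (-0.22, 0.22, 0.27, 0.17),
    "H": (0.00, 0.00, -0.10, 0.14),
    "I": (-0.91, -0.59, -0.73, -0.23),
    "K": (-0.56, -0.29, -0.04, 0.12),
    "L": (-0.57, -0.13, -0.58, -0.21),
    "M": (-0.64, -0.28, -0.01, 0.11),
    "N": (-0.58, -0.13, 0.49, 0.32),
    "P": (0.00, -0.19, 0.00, -0.24),
    "Q": (-0.47, -0.27, 0.06, 0.20),
    "R": (-0.59, -0.32, 0.08, 0.22),
    "S": (-0.44, -0.39, 0.37, 0.30),
    "T": (-0.79, -0.47, -0.07, 0.20),
    "V": (-0.74, -0.30, -0.70, -0.14),
    "W": (-0.40, -0.44, -0.41, -0.11),
    "Y": (-0.41, -0.37, -0.27, 0.05),
}

# Chain-terminus corrections: the protonated N-terminal amine acts on the
# second residue's amide (a rho-type term); the deprotonated C-terminal
# carboxylate acts on the last residue's own amide (a lambda-type term).
_NTERM_ACID_RHO = -1.32
_NTERM_BASE_RHO = 1.62
_CTERM_ACID_LAMBDA = 0.96
_CTERM_BASE_LAMBDA = -1.80

# Poly-DL-alanine reference rate constants in D2O at 293 K, log10, per minute
# (acid and base terms are second order in catalyst).
_LOG_KA_REF = 1.62
_LOG_KB_REF = 10.18
_LOG_KW_REF = -1.50

# Arrhenius activation energies, cal/mol.
_EA_ACID = 14_000.0
_EA_BASE = 17_000.0
_EA_WATER = 19_000.0
_R_GAS = 1.987  # cal/(mol K)
_T_REF = 293.0
_PKD = 15.05  # ion product of D2O; held temperature-independent here


@dataclass(frozen=True)
class ResidueExchangeState:
    """Exchange behaviour of one backbone amide in one conformational state.

    ``k_obs = k_int / 10**log10_P``; proline (and the chain's first residue)
    carries no exchangeable backbone amide and is flagged with ``k_int=None``.
    """

    residue_index: int  # 1-based
    amino_acid: str
    k_int: float | None  # 1/s; None where no exchangeable amide
    log10_P: float = 0.0

    def __post_init__(self) -> None:
        if self.log10_P < 0:
            raise ValueError(f"log10_P must be >= 0, got {self.log10_P}")
        if self.k_int is not None and self.k_int < 0:
            raise ValueError(f"k_int must be >= 0, got {self.k_int}")

    @property
    def exchangeable(self) -> bool:
        return self.k_int is not None

    @property
    def k_obs(self) -> float | None:
        """Observed rate (1/s), slowed by the protection factor."""
        if self.k_int is None:
            return None
        return self.k_int / 10.0 ** self.log10_P


@dataclass
class StateDefinition:
    """A conformational state: a protein sequence plus its per-residue
    log10 protection-factor profile."""

    name: str
    sequence: str
    log10_P_profile: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.log10_P_profile is None:
            self.log10_P_profile = np.zeros(len(self.sequence))
        self.log10_P_profile = np.asarray(self.log10_P_profile, dtype=float)
        if len(self.log10_P_profile) != len(self.sequence):
            raise ValueError(
                f"state {self.name!r}: profile length {len(self.log10_P_profile)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if np.any(self.log10_P_profile < 0):
            raise ValueError(f"state {self.name!r}: log10_P must be >= 0 everywhere")


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_RESIDUES:
            raise ValueError(f"unknown residue code {aa!r} at position {i + 1}")


def intrinsic_rates(
    sequence: str, pD: float = 8.0, temperature_K: float = 298.0
) -> np.ndarray:
    """Per-residue intrinsic exchange rates (1/s) for an unstructured chain.

    Position ``i`` (0-based array index) holds the rate of residue ``i+1``'s
    backbone amide.  The first residue (free amine, no amide) and prolines are
    returned as NaN.  Rates combine acid-, base- and water-catalysed terms,
    each scaled by the side chains flanking the amide and Arrhenius-corrected
    from the 293 K reference.
    """
    _validate_sequence(sequence)
    d_conc = 10.0 ** (-pD)
    od_conc = 10.0 ** (pD - _PKD)

    arr_acid = math.exp(-_EA_ACID / _R_GAS * (1.0 / temperature_K - 1.0 / _T_REF))
    arr_base = math.exp(-_EA_BASE / _R_GAS * (1.0 / temperature_K - 1.0 / _T_REF))
    arr_water = math.exp(-_EA_WATER / _R_GAS * (1.0 / temperature_K - 1.0 / _T_REF))

    ka = 10.0 ** _LOG_KA_REF * arr_acid
    kb = 10.0 ** _LOG_KB_REF * arr_base
    kw = 10.0 ** _LOG_KW_REF * arr_water

    n = len(sequence)
    rates = np.full(n, np.nan)
    for i in range(1, n):  # residue i+1 in 1-based terms; residue 1 has no amide
        aa = sequence[i]
        if aa == "P":
            continue
        prev = sequence[i - 1]
        acid = _SIDECHAIN[aa][0] + _SIDECHAIN[prev][1]
        base = _SIDECHAIN[aa][2] + _SIDECHAIN[prev][3]
        if i == 1:
            acid += _NTERM_ACID_RHO
            base += _NTERM_BASE_RHO
        if i == n - 1:
            acid += _CTERM_ACID_LAMBDA
            base += _CTERM_BASE_LAMBDA
        k_min = (
            ka * 10.0 ** acid * d_conc
            + kb * 10.0 ** base * od_conc
            + kw * 10.0 ** base
        )
        rates[i] = k_min / 60.0  # per minute -> per second
    return rates


def uniform_intrinsic_rates(sequence: str, k_int: float = 1.0) -> np.ndarray:
    """Sequence-independent fallback: every exchangeable amide gets ``k_int``
    (1/s); first residue and prolines are NaN as in :func:`intrinsic_rates`."""
    _validate_sequence(sequence)
    if k_int < 0:
        raise ValueError("k_int must be >= 0")
    rates = np.full(len(sequence), np.nan)
    for i in range(1, len(sequence)):
        if sequence[i] != "P":
            rates[i] = k_int
    return rates


def deuterium_fraction(k_obs, t):
    """Deuterated fraction of one amide after labeling time ``t`` (s):
    ``1 - exp(-k_obs * t)``.  Accepts scalars or arrays; NaN rates propagate."""
    k_obs = np.asarray(k_obs, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(k_obs[~np.isnan(k_obs)] < 0):
        raise ValueError("k_obs must be >= 0")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = -np.expm1(-k_obs * t)
    if out.ndim == 0:
        return float(out)
    return out


def exchangeable_amides(peptide: str) -> int:
    """Maximum number of deuterons a peptide can report.

    Convention: the first residue's amine is excluded (it back-exchanges
    during analysis) and prolines beyond position 1 lack an amide hydrogen.
    """
    _validate_sequence(peptide)
    return len(peptide) - 1 - peptide[1:].count("P")
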