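"""Isotope-envelope synthesis and mass-envelope centroids.

Deuterium uptake is measured as the shift of the intensity-weighted mean mass
(centroid) of a peptide's isotope envelope relative to its undeuterated
control, divided by the H→D mass difference.  This module builds natural
(undeuterated) envelopes from elemental composition, convolves on a
Poisson-binomial deuteron-count distribution given per-amide deuteration
fractions, and computes centroids.

Envelopes are aggregated stick spectra: one stick per extra-neutron count,
which is sufficient because the centroid — not peak shape — is the
observable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from pyteomics import mass as pmass

__all__ = [
    "DEUTERIUM_MASS_SHIFT",
    "IsotopeEnvelope",
    "natural_envelope",
    "deuterate_envelope",
    "centroid",
    "uptake_from_centroids",
]

#: Mass difference between deuterium and protium, Da (2H - 1H).
DEUTERIUM_MASS_SHIFT = 1.00628

#: Spacing between adjacent aggregated isotope peaks (13C - 12C), Da.
_NEUTRON_SPACING = 1.0033548

_ABUNDANCE_FLOOR = 1e-10


@dataclass
class IsotopeEnvelope:
    """A normalized stick spectrum: strictly increasing masses (Da) with
    non-negative intensities summing to one.  ``charge`` enables m/z views
    but all arithmetic is on neutral masses."""

    masses: np.ndarray
    intensities: np.ndarray
    charge: int | None = None

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.masses.size == 0:
            raise ValueError("envelope must contain at least one peak")
        if self.masses.shape != self.intensities.shape:
            raise ValueError("masses and intensities must have equal length")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        total = self.intensities.sum()
        if total <= 0:
            raise ValueError("total intensity must be positive")
        order = np.argsort(self.masses, kind="stable")
        masses = self.masses[order]
        intensities = self.intensities[order] / total
        # merge coincident sticks so masses are strictly increasing
        uniq, inverse = np.unique(masses, return_inverse=True)
        if uniq.size != masses.size:
            merged = np.zeros_like(uniq)
            np.add.at(merged, inverse, intensities)
            masses, intensities = uniq, merged
        self.masses = masses
        self.intensities = intensities
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def mz(self) -> np.ndarray:
        if self.charge is None:
            raise ValueError("envelope has no charge assigned")
        return (self.masses + self.charge * 1.007276) / self.charge

    def to_csv(self, path) -> None:
        """Dump as two-column CSV (mass, intensity) for inspection."""
        np.savetxt(
            path,
            np.column_stack([self.masses, self.intensities]),
            delimiter=",",
            header="mass_da,intensity",
            comments="",
        )


def _element_isotope_pattern(element: str, count: int) -> np.ndarray:
    """Abundance over extra-neutron number for ``count`` atoms of one element."""
    isotopes = sorted(
        (m, ab) for m, (_, ab) in pmass.nist_mass[element].items() if m != 0 and ab > 0
    )
    base = isotopes[0][0]
    width = isotopes[-1][0] - base + 1
    single = np.zeros(width)
    for m, ab in isotopes:
        single[m - base] = ab
    pattern = np.array([1.0])
    # exponentiation by squaring over polynomial convolution
    power = single
    k = count
    while k:
        if k & 1:
            pattern = np.convolve(pattern, power)
        k >>= 1
        if k:
            power = np.convolve(power, power)
    return pattern


@lru_cache(maxsize=512)
def _composition_pattern(comp_items: tuple) -> np.ndarray:
    pattern = np.array([1.0])
    for element, count in comp_items:
        pattern = np.convolve(pattern, _element_isotope_pattern(element, count))
    pattern = pattern[: max(1, int(np.searchsorted(pattern.cumsum(), 1 - _ABUNDANCE_FLOOR) + 1))]
    return pattern / pattern.sum()


def natural_envelope(peptide: str, charge: int | None = None) -> IsotopeEnvelope:
    """Undeuterated isotope envelope of a peptide (free termini).

    The monoisotopic stick sits at the peptide's monoisotopic mass; heavier
    sticks follow at one aggregated-neutron spacing.
    """
    try:
        comp = pmass.Composition(sequence=peptide)
        mono = pmass.calculate_mass(sequence=peptide)
    except Exception as exc:  # pyteomics raises its own parser errors
        raise ValueError(f"invalid peptide {peptide!r}: {exc}") from exc
    pattern = _composition_pattern(tuple(sorted(comp.items())))
    masses = mono + _NEUTRON_SPACING * np.arange(pattern.size)
    return IsotopeEnvelope(masses=masses, intensities=pattern, charge=charge)


def deuteron_count_distribution(per_amide_fractions) -> np.ndarray:
    """Exact Poisson-binomial pmf of the number of retained deuterons given
    independent per-amide deuteration probabilities."""
    fractions = np.asarray(per_amide_fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("per-amide fractions must lie in [0, 1]")
    pmf = np.array([1.0])
    for f in fractions:
        pmf = np.convolve(pmf, [1.0 - f, f])
    return pmf


def deuterate_envelope(
    env: IsotopeEnvelope, per_amide_fractions
) -> IsotopeEnvelope:
    """Convolve a deuteron-count distribution onto a natural envelope.

    The output centroid exceeds the input centroid by exactly
    ``sum(fractions) * DEUTERIUM_MASS_SHIFT``.
    """
    pmf = deuteron_count_distribution(per_amide_fractions)
    masses = (env.masses[None, :] + DEUTERIUM_MASS_SHIFT * np.arange(pmf.size)[:, None]).ravel()
    intensities = (pmf[:, None] * env.intensities[None, :]).ravel()
    return IsotopeEnvelope(masses=masses, intensities=intensities, charge=env.charge)


def centroid(env: IsotopeEnvelope) -> float:
    """Intensity-weighted mean mass (Da) of an envelope."""
    return float(np.dot(env.masses, env.intensities))


def uptake_from_centroids(deuterated_centroid: float, control_centroid: float) -> float:
    """Deuterons incorporated, from the centroid shift versus the undeuterated
    control.  May be slightly negative under noise; reported as-is (correction
    and clipping happen downstream)."""
    if not (np.isfinite(deuterated_centroid) and np.isfinite(control_centroid)):
        raise ValueError("centroids must be finite")
    return (deuterated_centroid - control_centroid) / DEUTERIUM_MASS_SHIFT
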