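"""From centroid tables to back-exchange-corrected uptake curves.

Pipeline: centroid differencing against undeuterated controls → global
back-exchange estimation from disordered terminal peptides → multiplicative
correction → per-(peptide, state, time) means ± SEM over technical
replicates → single-exponential fits for display.

A centroid table is a long-format :class:`pandas.DataFrame` with columns
``peptide_id, sequence, start, end, max_uptake, state, exposure_s,
replicate, centroid_da, is_control`` (see :mod:`hdxquant.synthetic_data`
and :mod:`hdxquant.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .envelope_centroid import DEUTERIUM_MASS_SHIFT

__all__ = [
    "UptakeCurve",
    "ExponentialFit",
    "compute_raw_uptake",
    "estimate_back_exchange",
    "correct_uptake",
    "build_uptake_curves",
    "fit_exponential",
    "CENTROID_COLUMNS",
]

logger = logging.getLogger(__name__)

CENTROID_COLUMNS = (
    "peptide_id", "sequence", "start", "end", "max_uptake",
    "state", "exposure_s", "replicate", "centroid_da", "is_control",
)


@dataclass
class ExponentialFit:
    """Single-exponential uptake fit D(t) = A (1 − e^{−kt})."""

    amplitude: float  # deuterons, within [0, max_uptake]
    rate: float | None  # 1/s; None when unidentifiable (e.g. flat-zero curve)
    rss: float
    message: str = "ok"


@dataclass
class UptakeCurve:
    """Uptake time course of one peptide in one state.

    ``sem`` entries are NaN where fewer than two replicates exist.  After
    correction, means are clipped into [0, max_uptake] with a warning.
    """

    peptide_id: str
    state: str
    start: int
    end: int
    max_uptake: int
    timepoints: np.ndarray  # s, sorted
    mean_uptake: np.ndarray  # deuterons
    sem: np.ndarray  # deuterons; NaN if <2 replicates
    replicate_uptake: list  # list (per timepoint) of replicate arrays
    corrected: bool = False
    fit: ExponentialFit | None = None


def validate_centroid_table(table: pd.DataFrame) -> None:
    missing = [c for c in CENTROID_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"centroid table lacks mandatory columns: {missing}")


def compute_raw_uptake(table: pd.DataFrame) -> pd.DataFrame:
    """Convert centroids to raw deuteron counts by differencing against the
    mean undeuterated control of each (peptide, state).

    The undeuterated reference is pooled over all of a peptide's control
    rows (the control carries no deuterium, so it is state-independent);
    pooling lets control noise cancel exactly in state-versus-state
    differences.  A (peptide, state) cell that contributed no control row
    of its own is still excluded with a logged reason.  Output adds an
    ``uptake`` column (may be slightly negative from noise — correction
    clips later).
    """
    validate_centroid_table(table)
    controls = (
        table[table["is_control"]]
        .groupby("peptide_id")["centroid_da"]
        .mean()
        .rename("control_centroid")
    )
    has_own_control = set(
        table.loc[table["is_control"], ["peptide_id", "state"]]
        .drop_duplicates()
        .itertuples(index=False, name=None)
    )
    deut = table[~table["is_control"]].copy()
    deut = deut.join(controls, on="peptide_id")
    own = pd.Series(
        list(zip(deut["peptide_id"], deut["state"])), index=deut.index
    ).isin(has_own_control)
    dropped = deut["control_centroid"].isna() | ~own
    if dropped.any():
        for pid, state in (
            deut.loc[dropped, ["peptide_id", "state"]].drop_duplicates().itertuples(index=False)
        ):
            logger.warning(
                "peptide %s state %s excluded: no undeuterated control row", pid, state
            )
        deut = deut[~dropped]
    deut["uptake"] = (deut["centroid_da"] - deut["control_centroid"]) / DEUTERIUM_MASS_SHIFT
    return deut.drop(columns=["centroid_da", "control_centroid"])


def estimate_back_exchange(
    uptake: pd.DataFrame,
    protein_length: int,
    terminal_window: int = 10,
) -> float:
    """Estimate the global back-exchange fraction from disordered termini.

    Peptides lying wholly within ``terminal_window`` residues of either
    protein end are assumed fully exchanged by the longest timepoint; the
    factor is one minus their mean fractional-of-maximum uptake there,
    clamped into [0, 0.9].
    """
    if "uptake" not in uptake.columns:
        raise ValueError("expected raw-uptake records (run compute_raw_uptake first)")
    t_max = uptake["exposure_s"].max()
    sel = uptake[
        (uptake["exposure_s"] == t_max)
        & (
            (uptake["end"] <= terminal_window)
            | (uptake["start"] > protein_length - terminal_window)
        )
        & (uptake["max_uptake"] > 0)
    ]
    if sel.empty:
        raise ValueError(
            f"no peptide lies wholly within {terminal_window} residues of a protein "
            "end; supply an explicit back-exchange factor instead"
        )
    per_peptide = (
        sel.assign(frac=sel["uptake"] / sel["max_uptake"])
        .groupby(["peptide_id", "state"])["frac"]
        .mean()
    )
    factor = 1.0 - float(per_peptide.mean())
    return float(np.clip(factor, 0.0, 0.9))


def correct_uptake(raw, factor: float, max_uptake):
    """Back-exchange correction: divide by (1 − factor) so fully disordered
    reference peptides read 100% of their maximum, then clip to
    [0, max_uptake].  Accepts scalars or arrays."""
    if not 0.0 <= factor < 1.0:
        raise ValueError(f"back-exchange factor must lie in [0, 1), got {factor}")
    corrected = np.asarray(raw, dtype=float) / (1.0 - factor)
    out = np.clip(corrected, 0.0, max_uptake)
    if np.ndim(raw) == 0:
        return float(out)
    return out


def correct_uptake_table(
    uptake: pd.DataFrame, factor: float, clip: bool = False
) -> pd.DataFrame:
    """Apply the back-exchange correction row-wise to an uptake table.

    Replicate-level values are left unclipped by default: the correction is
    then a global scalar division, so downstream test statistics are
    identical to those on raw uptake.  Clipping into [0, max_uptake] is
    applied to curve means at build time (or here with ``clip=True``).
    """
    if not 0.0 <= factor < 1.0:
        raise ValueError(f"back-exchange factor must lie in [0, 1), got {factor}")
    out = uptake.copy()
    if clip:
        out["uptake"] = correct_uptake(
            out["uptake"].to_numpy(), factor, out["max_uptake"].to_numpy()
        )
    else:
        out["uptake"] = out["uptake"].to_numpy() / (1.0 - factor)
    out.attrs["back_exchange_factor"] = factor
    out.attrs["corrected"] = True
    return out


def build_uptake_curves(uptake: pd.DataFrame) -> list[UptakeCurve]:
    """Aggregate replicate uptake records into per-(peptide, state) curves
    with mean ± SEM (sd/√n over technical replicates)."""
    corrected = bool(uptake.attrs.get("corrected", False))
    curves: list[UptakeCurve] = []
    n_clipped = 0
    for (pid, state), grp in uptake.groupby(["peptide_id", "state"], sort=True):
        times = np.sort(grp["exposure_s"].unique())
        means, sems, reps = [], [], []
        max_uptake = int(grp.iloc[0]["max_uptake"])
        for t in times:
            vals = grp.loc[grp["exposure_s"] == t, "uptake"].to_numpy()
            m = vals.mean()
            if corrected and not 0.0 <= m <= max_uptake:
                n_clipped += 1
                m = float(np.clip(m, 0.0, max_uptake))
            means.append(m)
            sems.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) >= 2 else np.nan)
            reps.append(vals)
        first = grp.iloc[0]
        curves.append(
            UptakeCurve(
                peptide_id=pid,
                state=state,
                start=int(first["start"]),
                end=int(first["end"]),
                max_uptake=int(first["max_uptake"]),
                timepoints=times.astype(float),
                mean_uptake=np.asarray(means),
                sem=np.asarray(sems),
                replicate_uptake=reps,
                corrected=corrected,
            )
        )
    if n_clipped:
        logger.warning("%d curve means clipped into [0, max_uptake]", n_clipped)
    return curves


def fit_exponential(curve: UptakeCurve) -> ExponentialFit:
    """Least-squares fit of D(t) = A (1 − e^{−kt}) to a curve's means.

    Requires ≥3 timepoints.  A is bounded by [0, max_uptake]; k > 0.  An
    all-zero curve yields A = 0 with the rate flagged unidentifiable.
    Non-convergence is reported in the fit message, never silently
    defaulted.
    """
    t = curve.timepoints
    y = curve.mean_uptake
    if t.size < 3:
        return ExponentialFit(np.nan, None, np.nan, "need >= 3 timepoints")
    if np.allclose(y, 0.0):
        return ExponentialFit(0.0, None, 0.0, "flat-zero curve; rate unidentifiable")

    def model(tt, A, k):
        return A * -np.expm1(-k * tt)

    a0 = min(max(y.max(), 1e-6), curve.max_uptake or np.inf)
    k0 = 1.0 / max(t[len(t) // 2], 1e-9)
    upper_a = curve.max_uptake if curve.max_uptake > 0 else np.inf
    try:
        popt, _ = curve_fit(
            model, t, y, p0=[a0, k0],
            bounds=([0.0, 1e-12], [upper_a, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError) as exc:
        return ExponentialFit(np.nan, None, np.nan, f"fit failed: {exc}")
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    return ExponentialFit(float(popt[0]), float(popt[1]), rss)


def fit_all(curves: list[UptakeCurve]) -> None:
    """Attach exponential fits to curves in place."""
    for c in curves:
        c.fit = fit_exponential(c)
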