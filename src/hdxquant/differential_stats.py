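"""Peptide-quality filtering and state-versus-state differential exchange.

Identification-quality filters retain a peptide only if its search score,
fragment density, mass error, retention-time reproducibility and
run-to-run observation all pass (score ≥ 6.5, products per amino acid
≥ 0.2, MH+ error ≤ 5 ppm, retention-time sd ≤ 5%, seen in ≥ 2 of 3 runs).

State comparison runs a two-way ANOVA (state × exposure) on replicate
uptake values plus a two-sample t-test at each timepoint; a peptide
is called differential only when the ANOVA state effect and at least one
per-timepoint t-test are both below alpha, with the direction taken from
the sign of the uptake difference at the significant timepoints.  Both
p-value families are reported so alternative composite rules can be
audited.  No multiple-testing correction is applied by default; a
Benjamini–Hochberg option is exposed.

Peptide-level verdicts are projected to residues by consensus over the
significant peptides covering each residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multitest import multipletests

from .synthetic_data import PeptideMap
from .uptake_pipeline import UptakeCurve

__all__ = [
    "PeptideIdentification",
    "DifferentialResult",
    "FILTER_THRESHOLDS",
    "filter_peptides",
    "compare_states",
    "residue_level_map",
]

logger = logging.getLogger(__name__)

#: Identification-quality thresholds (inclusive boundaries).
FILTER_THRESHOLDS = {
    "min_score": 6.5,
    "min_products_per_aa": 0.2,
    "max_mh_error_ppm": 5.0,
    "max_rt_sd_percent": 5.0,
    "min_runs_observed": 2,
}


@dataclass(frozen=True)
class PeptideIdentification:
    """Quality metrics of one identified peptide."""

    peptide_id: str
    score: float
    products_per_aa: float
    mh_error_ppm: float
    rt_sd_percent: float
    runs_observed: int

    def __post_init__(self) -> None:
        for name in ("score", "products_per_aa", "mh_error_ppm", "rt_sd_percent", "runs_observed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def filter_peptides(
    identifications: list[PeptideIdentification],
    thresholds: dict | None = None,
) -> tuple[list[PeptideIdentification], list[tuple[str, list[str]]]]:
    """Apply the identification-quality filters.

    Returns the retained subset and a rejection log of
    ``(peptide_id, [failed rules])``.  Boundary values pass (the cutoffs are
    minimum/maximum acceptable values).
    """
    th = dict(FILTER_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    retained: list[PeptideIdentification] = []
    rejections: list[tuple[str, list[str]]] = []
    for ident in identifications:
        failed = []
        if ident.score < th["min_score"]:
            failed.append(f"score {ident.score} < {th['min_score']}")
        if ident.products_per_aa < th["min_products_per_aa"]:
            failed.append(
                f"products_per_aa {ident.products_per_aa} < {th['min_products_per_aa']}"
            )
        if ident.mh_error_ppm > th["max_mh_error_ppm"]:
            failed.append(f"mh_error_ppm {ident.mh_error_ppm} > {th['max_mh_error_ppm']}")
        if ident.rt_sd_percent > th["max_rt_sd_percent"]:
            failed.append(f"rt_sd_percent {ident.rt_sd_percent} > {th['max_rt_sd_percent']}")
        if ident.runs_observed < th["min_runs_observed"]:
            failed.append(f"runs_observed {ident.runs_observed} < {th['min_runs_observed']}")
        if failed:
            rejections.append((ident.peptide_id, failed))
            logger.info("peptide %s rejected: %s", ident.peptide_id, "; ".join(failed))
        else:
            retained.append(ident)
    return retained, rejections


@dataclass
class DifferentialResult:
    """Outcome of comparing one peptide's uptake between two states."""

    peptide_id: str
    state_pair: tuple[str, str]
    start: int
    end: int
    anova_p: float
    timepoints: np.ndarray
    t_p_values: np.ndarray  # Welch t-test per timepoint
    delta_uptake: np.ndarray  # state B − state A, deuterons
    verdict: str  # increased | decreased | not-significant


def _two_way_anova_state_p(long: pd.DataFrame) -> float:
    """p-value of the state main effect in a two-way (state × time) ANOVA.

    Falls back to a one-way ANOVA when only a single exposure is present,
    and returns 1.0 for degenerate data with no residual variance."""
    if long["uptake"].nunique() == 1:
        return 1.0
    formula = (
        "uptake ~ C(state) * C(exposure_s)"
        if long["exposure_s"].nunique() > 1
        else "uptake ~ C(state)"
    )
    model = ols(formula, data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p = float(table.loc["C(state)", "PR(>F)"])
    return p if np.isfinite(p) else 1.0


def compare_states(
    curves_a: list[UptakeCurve],
    curves_b: list[UptakeCurve],
    alpha: float = 0.05,
    fdr: bool = False,
    t_variant: str = "student",
) -> list[DifferentialResult]:
    """Compare replicate uptake between two states for every shared peptide.

    Verdict is ``increased``/``decreased`` only when the ANOVA state-effect
    p < alpha AND at least one per-timepoint t-test p < alpha; the
    direction is the sign of the mean uptake difference (B − A) over the
    significant timepoints.  With ``fdr=True`` the t-test family per peptide
    is Benjamini–Hochberg adjusted before the rule is applied.

    ``t_variant`` selects the two-sample test: ``"student"`` (pooled
    variance, default — exactly calibrated for the three technical
    replicates of a shared protocol) or ``"welch"`` (unequal variance,
    conservative at such small n).
    """
    if t_variant not in ("student", "welch"):
        raise ValueError("t_variant must be 'student' or 'welch'")
    by_id_a = {c.peptide_id: c for c in curves_a}
    by_id_b = {c.peptide_id: c for c in curves_b}
    results: list[DifferentialResult] = []
    for pid in sorted(set(by_id_a) & set(by_id_b)):
        a, b = by_id_a[pid], by_id_b[pid]
        if not np.array_equal(a.timepoints, b.timepoints):
            logger.warning("peptide %s skipped: timepoints differ between states", pid)
            continue
        rows = []
        for t, va, vb in zip(a.timepoints, a.replicate_uptake, b.replicate_uptake):
            rows += [(a.state, t, v) for v in va] + [(b.state, t, v) for v in vb]
        long = pd.DataFrame(rows, columns=["state", "exposure_s", "uptake"])
        anova_p = _two_way_anova_state_p(long)
        t_ps, deltas = [], []
        for va, vb in zip(a.replicate_uptake, b.replicate_uptake):
            deltas.append(np.mean(vb) - np.mean(va))
            if len(va) >= 2 and len(vb) >= 2:
                if np.ptp(va) == 0 and np.ptp(vb) == 0:
                    p = 1.0 if np.mean(va) == np.mean(vb) else 0.0
                else:
                    p = float(
                        stats.ttest_ind(vb, va, equal_var=(t_variant == "student")).pvalue
                    )
            else:
                p = np.nan
            t_ps.append(p)
        t_ps = np.asarray(t_ps)
        deltas = np.asarray(deltas)
        eff_ps = t_ps
        if fdr and np.isfinite(t_ps).any():
            finite = np.isfinite(t_ps)
            adj = np.full_like(t_ps, np.nan)
            adj[finite] = multipletests(t_ps[finite], method="fdr_bh")[1]
            eff_ps = adj
        sig_t = np.isfinite(eff_ps) & (eff_ps < alpha)
        verdict = "not-significant"
        if anova_p < alpha and sig_t.any():
            direction = float(np.mean(deltas[sig_t]))
            if direction > 0:
                verdict = "increased"
            elif direction < 0:
                verdict = "decreased"
        results.append(
            DifferentialResult(
                peptide_id=pid,
                state_pair=(a.state, b.state),
                start=a.start,
                end=a.end,
                anova_p=anova_p,
                timepoints=a.timepoints.copy(),
                t_p_values=t_ps,
                delta_uptake=deltas,
                verdict=verdict,
            )
        )
    return results


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Flatten differential results to a wide table for CSV export."""
    rows = []
    for r in results:
        row = {
            "peptide_id": r.peptide_id,
            "start": r.start,
            "end": r.end,
            "state_a": r.state_pair[0],
            "state_b": r.state_pair[1],
            "anova_p": r.anova_p,
            "verdict": r.verdict,
        }
        for t, p, d in zip(r.timepoints, r.t_p_values, r.delta_uptake):
            row[f"t_p_{t:g}s"] = p
            row[f"delta_{t:g}s"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def residue_level_map(
    results: list[DifferentialResult], peptide_map: PeptideMap
) -> pd.DataFrame:
    """Project peptide verdicts onto residues by consensus.

    Each residue is classified by majority among the significant peptides
    covering it; ties between increased and decreased are flagged
    ``ambiguous``; covered residues with no significant peptide are
    ``not-significant``; residues no peptide covers are ``no-coverage``.
    """
    n = len(peptide_map.protein_sequence)
    covered = np.zeros(n, dtype=bool)
    inc = np.zeros(n, dtype=int)
    dec = np.zeros(n, dtype=int)
    by_id = {e.peptide_id: e for e in peptide_map}
    for r in results:
        entry = by_id.get(r.peptide_id)
        if entry is None:
            logger.warning("result for %s references a peptide absent from the map", r.peptide_id)
            continue
        sl = slice(entry.start - 1, entry.end)
        covered[sl] = True
        if r.verdict == "increased":
            inc[sl] += 1
        elif r.verdict == "decreased":
            dec[sl] += 1
    classification = np.where(covered, "not-significant", "no-coverage").astype(object)
    classification[(inc > dec)] = "increased"
    classification[(dec > inc)] = "decreased"
    classification[(inc > 0) & (inc == dec)] = "ambiguous"
    return pd.DataFrame(
        {
            "residue": np.arange(1, n + 1),
            "amino_acid": list(peptide_map.protein_sequence),
            "n_increased": inc,
            "n_decreased": dec,
            "classification": classification,
        }
    )
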