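"""Centroid tables to corrected uptake curves: differencing, back-exchange,
aggregation, exponential fits."""

import logging

import numpy as np
import pandas as pd
import pytest

from hdxquant import GroundTruthSystem, StateDefinition, generate_peptide_map
from hdxquant.envelope_centroid import DEUTERIUM_MASS_SHIFT
from hdxquant.synthetic_data import simulate_exchange_dataset
from hdxquant.uptake_pipeline import (
    UptakeCurve,
    build_uptake_curves,
    compute_raw_uptake,
    correct_uptake,
    correct_uptake_table,
    estimate_back_exchange,
    fit_exponential,
)

from conftest import random_sequence


def _centroid_row(pid, state, t, rep, centroid, is_control, start=1, end=10, max_uptake=9):
    return dict(
        peptide_id=pid, sequence="A" * (end - start + 1), start=start, end=end,
        max_uptake=max_uptake, state=state, exposure_s=t, replicate=rep,
        centroid_da=centroid, is_control=is_control,
    )


def _uptake_records(peptides, t_max=120.0):
    """Build raw-uptake records for back-exchange tests.

    ``peptides``: list of (pid, start, end, max_uptake, uptake_at_tmax).
    """
    rows = []
    for pid, start, end, max_uptake, uptake in peptides:
        rows.append(dict(peptide_id=pid, sequence="A" * (end - start + 1), start=start,
                         end=end, max_uptake=max_uptake, state="s", exposure_s=t_max,
                         replicate=1, is_control=False, uptake=uptake))
    return pd.DataFrame(rows)


class TestComputeRawUptake:
    def test_equal_centroids_give_zero_uptake(self):
        table = pd.DataFrame([
            _centroid_row("p1", "s", 0.0, 1, 800.0, True),
            _centroid_row("p1", "s", 60.0, 1, 800.0, False),
        ])
        raw = compute_raw_uptake(table)
        assert raw["uptake"].iloc[0] == 0.0

    def test_shift_converts_to_deuterons(self):
        table = pd.DataFrame([
            _centroid_row("p1", "s", 0.0, 1, 800.0, True),
            _centroid_row("p1", "s", 60.0, 1, 800.0 + 3 * DEUTERIUM_MASS_SHIFT, False),
        ])
        assert compute_raw_uptake(table)["uptake"].iloc[0] == pytest.approx(3.0)

    def test_missing_control_excludes_peptide_with_log(self, caplog):
        table = pd.DataFrame([
            _centroid_row("p1", "s", 0.0, 1, 800.0, True),
            _centroid_row("p1", "s", 60.0, 1, 801.0, False),
            _centroid_row("p2", "s", 60.0, 1, 900.0, False),
        ])
        with caplog.at_level(logging.WARNING, logger="hdxquant.uptake_pipeline"):
            raw = compute_raw_uptake(table)
        assert set(raw["peptide_id"]) == {"p1"}
        assert any("p2" in rec.message for rec in caplog.records)

    def test_missing_column_is_hard_failure(self):
        with pytest.raises(ValueError, match="centroid table lacks"):
            compute_raw_uptake(pd.DataFrame({"peptide_id": ["p1"]}))


class TestEstimateBackExchange:
    def test_terminal_peptides_at_75_percent_give_25(self):
        recs = _uptake_records([(f"p{i}", 1, 8, 7, 0.75 * 7) for i in range(5)])
        assert estimate_back_exchange(recs, protein_length=100) == pytest.approx(0.25)

    def test_full_exchange_gives_zero(self):
        recs = _uptake_records([("p1", 93, 100, 7, 7.0)])
        assert estimate_back_exchange(recs, protein_length=100) == pytest.approx(0.0)

    def test_two_terminal_peptides_average(self):
        recs = _uptake_records([("p1", 1, 8, 10, 7.0), ("p2", 93, 100, 10, 8.0)])
        assert estimate_back_exchange(recs, protein_length=100) == pytest.approx(0.25)

    def test_no_terminal_peptides_is_an_error(self):
        recs = _uptake_records([("p1", 40, 50, 9, 5.0)])
        with pytest.raises(ValueError, match="explicit back-exchange"):
            estimate_back_exchange(recs, protein_length=100)

    def test_clamped_to_valid_range(self):
        recs = _uptake_records([("p1", 1, 8, 7, -3.0)])
        assert estimate_back_exchange(recs, protein_length=100) == 0.9

    def test_recovers_simulator_truth_noiseless_exactly(self):
        seq = random_sequence(60, seed=8)
        system = GroundTruthSystem(
            sequence=seq,
            states=[StateDefinition("s", seq)],  # fully disordered
            back_exchange_fraction=0.25,
            centroid_noise_sd=0.0,
            uniform_k_int=5.0,  # saturates well before 120 s
        )
        pmap = generate_peptide_map(seq, 10, 5)
        raw = compute_raw_uptake(simulate_exchange_dataset(system, pmap, seed=0))
        assert estimate_back_exchange(raw, len(seq)) == pytest.approx(0.25, abs=1e-12)

    def test_recovers_truth_with_noise_within_two_percent(self):
        # 20 disordered terminal peptides, 3 replicates, 0.02 Da noise
        seq = random_sequence(30, seed=8)
        system = GroundTruthSystem(
            sequence=seq,
            states=[StateDefinition(f"s{i}", seq) for i in range(10)],
            back_exchange_fraction=0.25,
            centroid_noise_sd=0.02,
            uniform_k_int=5.0,
            disordered_terminal_window=15,
        )
        pmap = generate_peptide_map(seq, 15, 0)  # two peptides, both terminal
        raw = compute_raw_uptake(simulate_exchange_dataset(system, pmap, seed=3))
        est = estimate_back_exchange(raw, len(seq), terminal_window=15)
        assert est == pytest.approx(0.25, abs=0.02)


class TestCorrectUptake:
    def test_division_convention(self):
        assert correct_uptake(3.0, 0.25, 10) == pytest.approx(4.0)

    def test_zero_factor_is_identity(self):
        for x in (0.0, 2.5, 7.0):
            assert correct_uptake(x, 0.0, 8) == x

    def test_clipping_at_max_uptake_and_zero(self):
        assert correct_uptake(9.0, 0.25, 10) == 10.0
        assert correct_uptake(-0.4, 0.25, 10) == 0.0

    def test_factor_of_one_or_more_rejected(self):
        with pytest.raises(ValueError):
            correct_uptake(3.0, 1.0, 10)

    def test_round_trip_against_simulator_ground_truth(self):
        seq = random_sequence(50, seed=12)
        profile = np.zeros(50)
        profile[15:35] = 1.5
        make = lambda bx: GroundTruthSystem(
            sequence=seq, states=[StateDefinition("s", seq, profile.copy())],
            back_exchange_fraction=bx, centroid_noise_sd=0.0,
        )
        pmap = generate_peptide_map(seq, 10, 5)
        truth = compute_raw_uptake(simulate_exchange_dataset(make(0.0), pmap, seed=0))
        observed = compute_raw_uptake(simulate_exchange_dataset(make(0.30), pmap, seed=0))
        corrected = correct_uptake_table(observed, 0.30)
        merged = truth.merge(
            corrected, on=["peptide_id", "state", "exposure_s", "replicate"],
            suffixes=("_true", "_corr"),
        )
        assert np.allclose(merged["uptake_true"], merged["uptake_corr"], atol=1e-9)


class TestBuildUptakeCurves:
    def _table(self, values_by_time, pid="p1", max_uptake=9):
        rows = []
        for t, vals in values_by_time.items():
            for rep, v in enumerate(vals, start=1):
                rows.append(dict(peptide_id=pid, sequence="A" * 10, start=1, end=10,
                                 max_uptake=max_uptake, state="s", exposure_s=t,
                                 replicate=rep, is_control=False, uptake=v))
        return pd.DataFrame(rows)

    def test_identical_replicates_have_zero_sem(self):
        curves = build_uptake_curves(self._table({60.0: [4.0, 4.0, 4.0]}))
        assert curves[0].mean_uptake[0] == 4.0 and curves[0].sem[0] == 0.0

    def test_textbook_sem(self):
        curves = build_uptake_curves(self._table({60.0: [3.0, 4.0, 5.0]}))
        assert curves[0].sem[0] == pytest.approx(1 / np.sqrt(3), abs=1e-4)

    def test_single_replicate_has_no_sem(self):
        curves = build_uptake_curves(self._table({60.0: [4.0]}))
        assert np.isnan(curves[0].sem[0])

    def test_means_and_sems_match_brute_force_on_random_table(self):
        rng = np.random.default_rng(5)
        values = {t: list(rng.normal(3, 0.5, 3)) for t in (15.0, 30.0, 45.0, 60.0, 120.0)}
        curve = build_uptake_curves(self._table(values))[0]
        assert np.all(np.diff(curve.timepoints) > 0)
        for i, t in enumerate(curve.timepoints):
            vals = np.array(values[t])
            assert curve.mean_uptake[i] == pytest.approx(vals.mean())
            assert curve.sem[i] == pytest.approx(vals.std(ddof=1) / np.sqrt(3))

    def test_corrected_mean_clipped_with_warning(self, caplog):
        table = self._table({60.0: [9.5, 9.6, 9.7]}, max_uptake=9)
        table.attrs["corrected"] = True
        with caplog.at_level(logging.WARNING, logger="hdxquant.uptake_pipeline"):
            curves = build_uptake_curves(table)
        assert curves[0].mean_uptake[0] == 9.0
        assert any("clipped" in rec.message for rec in caplog.records)


class TestFitExponential:
    def _curve(self, t, y, max_uptake=10):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        return UptakeCurve("p", "s", 1, 11, max_uptake, t, y,
                           np.full_like(t, np.nan), [np.array([v]) for v in y])

    def test_noiseless_parameter_recovery(self):
        t = np.array([15.0, 30.0, 45.0, 60.0, 120.0])
        y = 5.0 * -np.expm1(-0.05 * t)
        fit = fit_exponential(self._curve(t, y))
        assert fit.amplitude == pytest.approx(5.0, abs=1e-6)
        assert fit.rate == pytest.approx(0.05, abs=1e-6)

    def test_flat_zero_curve_flags_unidentifiable_rate(self):
        fit = fit_exponential(self._curve([15, 30, 45], [0, 0, 0]))
        assert fit.amplitude == 0.0 and fit.rate is None

    def test_too_few_timepoints_reported(self):
        fit = fit_exponential(self._curve([15, 30], [1, 2]))
        assert fit.rate is None and "timepoints" in fit.message

    def test_amplitude_recovery_under_noise(self):
        # 200 Monte-Carlo draws at replicate-mean noise 0.1 deuterons
        rng = np.random.default_rng(17)
        t = np.array([15.0, 30.0, 45.0, 60.0, 120.0])
        truth = 5.0 * -np.expm1(-0.05 * t)
        amps = []
        for _ in range(200):
            fit = fit_exponential(self._curve(t, truth + rng.normal(0, 0.1, t.size)))
            assert fit.rate is not None
            amps.append(fit.amplitude)
        assert np.mean(np.abs(np.array(amps) - 5.0) <= 0.3) > 0.95
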