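import numpy as np
import pytest

import fhnsmr.experiments as exp
from fhnsmr.experiments import (
    SweepSpec,
    default_delay_grid,
    default_noise_grid,
    derive_seed,
    estimate_intrinsic_period,
    export_raster,
    find_local_extrema,
    load_raster,
    modal_isi,
    predicted_resonance_count,
    run_condition,
    sweep,
)
from fhnsmr.model import ModelParams, SimControl, Trajectory
from fhnsmr.network import NetworkParams
from fhnsmr.ordinal import complexity_of_isi

DT = 0.01


def pulse_trajectory(intervals, dt=DT):
    """Synthetic mean field with spikes separated by the given intervals."""
    times = np.concatenate([[1.0], 1.0 + np.cumsum(intervals)])
    idx = np.round(times / dt).astype(int)
    n = idx[-1] + 200
    X = np.full(n, -1.0)
    for i in idx:
        X[i : i + 3] = 1.0
    t = np.arange(n) * dt
    return Trajectory(t=t, X=X, dt=dt)


def stub_simulate_factory(interval_fn):
    """Build a simulate() replacement mapping (model, seed) -> ISI pattern."""

    def fake_simulate(J, model, control):
        intervals = interval_fn(model, control.seed)
        if intervals is None:
            t = np.arange(1000) * DT
            return Trajectory(t=t, X=np.full(1000, -1.0), dt=DT)
        return pulse_trajectory(intervals)

    return fake_simulate


class TestRunCondition:
    def test_composition_matches_direct_complexity(self, monkeypatch):
        pattern = np.resize([4.0, 10.0], 60)
        monkeypatch.setattr(
            exp, "simulate", stub_simulate_factory(lambda m, s: pattern)
        )
        J = np.zeros((2, 2))
        summary, series = run_condition(
            J, ModelParams(), SimControl(t_total=50.0, t_transient=1.0), L_target=50
        )
        assert len(series) == 50
        direct = complexity_of_isi(series.intervals, d=3)
        assert summary.C == pytest.approx(direct.C)
        assert summary.H == pytest.approx(direct.H)

    def test_silent_condition_yields_no_firing_convention(self, monkeypatch):
        monkeypatch.setattr(exp, "simulate", stub_simulate_factory(lambda m, s: None))
        summary, series = run_condition(
            np.zeros((2, 2)),
            ModelParams(D=0.0),
            SimControl(t_total=50.0, t_transient=1.0),
            L_target=10,
            max_realizations=3,
        )
        assert summary.no_firing
        assert summary.C == 0.0 and summary.H == 1.0
        assert len(series) == 0

    def test_repeat_runs_are_identical(self, monkeypatch):
        def noisy(model, seed):
            rng = np.random.default_rng(seed)
            return rng.uniform(2.0, 6.0, size=40)

        monkeypatch.setattr(exp, "simulate", stub_simulate_factory(noisy))
        args = (
            np.zeros((2, 2)),
            ModelParams(),
            SimControl(t_total=50.0, t_transient=1.0, seed=3),
        )
        a, _ = run_condition(*args, L_target=60)
        b, _ = run_condition(*args, L_target=60)
        assert a.C == b.C and a.H == b.H


class TestSweep:
    def _spec(self, values, **kw):
        return SweepSpec(
            control="D",
            values=values,
            net=NetworkParams(N=10, k=4, p=0.1, seed=0),
            model=ModelParams(),
            sim=SimControl(t_total=50.0, t_transient=1.0),
            L_target=40,
            max_realizations=3,
            **kw,
        )

    @staticmethod
    def _d_dependent(model, seed):
        # structure degrades with D: D<0.05 alternating, D>=0.05 random-ish
        if model.D >= 0.1:
            return None  # silent
        if model.D >= 0.05:
            return np.random.default_rng(seed).uniform(2.0, 6.0, 50)
        return np.resize([4.0, 10.0], 50)

    def test_grid_extension_does_not_change_existing_points(self, monkeypatch):
        monkeypatch.setattr(exp, "simulate", stub_simulate_factory(self._d_dependent))
        full = sweep(self._spec((0.01, 0.05, 0.1)))
        sub = sweep(self._spec((0.01, 0.1)))
        for D in (0.01, 0.1):
            row_full = full.table[full.table["D"] == D].iloc[0]
            row_sub = sub.table[sub.table["D"] == D].iloc[0]
            assert row_full["C"] == row_sub["C"]
            assert row_full["H"] == row_sub["H"]

    def test_no_firing_convention_propagates_into_curve(self, monkeypatch):
        monkeypatch.setattr(exp, "simulate", stub_simulate_factory(self._d_dependent))
        curve = sweep(self._spec((0.01, 0.05, 0.1)))
        silent = curve.table[curve.table["D"] == 0.1].iloc[0]
        assert bool(silent["no_firing"])
        assert silent["C"] == 0.0 and silent["H"] == 1.0

    def test_detected_extrema_lie_on_the_grid(self, monkeypatch):
        monkeypatch.setattr(exp, "simulate", stub_simulate_factory(self._d_dependent))
        curve = sweep(self._spec((0.01, 0.05, 0.1)))
        assert set(curve.maxima) <= set(curve.values)
        assert set(curve.minima) <= set(curve.values)

    def test_unsorted_or_unknown_controls_rejected(self):
        with pytest.raises(ValueError):
            self._spec((0.1, 0.05))
        with pytest.raises(ValueError):
            SweepSpec(control="zeta", values=(1.0, 2.0))


class TestFindLocalExtrema:
    def test_monotone_curve_has_no_extrema(self):
        maxima, minima = find_local_extrema(np.arange(10.0), prominence=0.0)
        assert maxima.size == 0

    def test_two_peak_curve(self):
        maxima, _ = find_local_extrema(np.array([0.0, 1.0, 0.0, 2.0, 0.0]), prominence=0.0)
        assert list(maxima) == [1, 3]

    def test_flat_curve_has_no_extrema(self):
        maxima, minima = find_local_extrema(np.ones(10), prominence=0.05)
        assert maxima.size == 0 and minima.size == 0

    def test_matches_neighbor_scan_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            v = rng.normal(size=30)
            maxima, minima = find_local_extrema(v, prominence=0.0)
            oracle_max = [
                i for i in range(1, 29) if v[i] > v[i - 1] and v[i] > v[i + 1]
            ]
            oracle_min = [
                i for i in range(1, 29) if v[i] < v[i - 1] and v[i] < v[i + 1]
            ]
            assert list(maxima) == oracle_max
            assert list(minima) == oracle_min

    def test_prominence_filters_shallow_wiggles(self):
        v = np.array([0.0, 0.02, 0.0, 1.0, 0.0])
        maxima, _ = find_local_extrema(v, prominence=0.05)
        assert list(maxima) == [3]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            find_local_extrema(np.array([1.0, 2.0]))


class TestIntrinsicPeriod:
    def test_injected_uniform_train_recovers_spacing_exactly(self):
        assert modal_isi(np.full(500, 3.45)) == pytest.approx(3.45)

    def test_signal_must_be_off(self):
        with pytest.raises(ValueError):
            estimate_intrinsic_period(
                np.zeros((2, 2)), ModelParams(A=0.14, D=0.1), SimControl()
            )

    def test_silent_network_raises(self, monkeypatch):
        monkeypatch.setattr(exp, "simulate", stub_simulate_factory(lambda m, s: None))
        with pytest.raises(RuntimeError):
            estimate_intrinsic_period(
                np.zeros((2, 2)),
                ModelParams(A=0.0, D=0.0),
                SimControl(t_total=50.0, t_transient=1.0),
                L_target=10,
                max_realizations=2,
            )


class TestResonanceCount:
    def test_reference_operating_point_predicts_quadruple_resonance(self):
        assert predicted_resonance_count(Te=14.0, T0=3.45) == 4

    def test_drive_faster_than_intrinsic_period_gives_zero(self):
        assert predicted_resonance_count(Te=5.0, T0=10.0) == 0

    def test_matches_floor_division_oracle_off_boundaries(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            Te = rng.uniform(0.5, 50.0)
            T0 = rng.uniform(0.5, 20.0)
            if abs(Te / T0 - round(Te / T0)) < 1e-9:
                continue
            assert predicted_resonance_count(Te, T0) == int(Te // T0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            predicted_resonance_count(0.0, 3.45)


class TestRasterExport:
    def _traj(self):
        raster = np.array([[0.1, 0.2, 0.3], [-0.1, -0.2, -0.3]])
        return Trajectory(
            t=np.array([0.0, 0.5, 1.0]),
            X=raster.mean(axis=0),
            dt=0.5,
            raster=raster,
            raster_t=np.array([0.0, 0.5, 1.0]),
        )

    def test_round_trip(self, tmp_path):
        traj = self._traj()
        path = tmp_path / "raster.tsv"
        export_raster(traj, path)
        times, matrix = load_raster(path)
        assert np.allclose(times, traj.raster_t)
        assert np.allclose(matrix, traj.raster)

    def test_missing_raster_rejected(self, tmp_path):
        traj = Trajectory(t=np.array([0.0]), X=np.array([0.0]), dt=1.0)
        with pytest.raises(ValueError):
            export_raster(traj, tmp_path / "r.tsv")


class TestGridsAndSeeds:
    def test_noise_grid_contains_landmark_intensities(self):
        grid = default_noise_grid()
        for D in (0.001, 0.02, 0.04, 0.065, 0.08, 0.14):
            assert np.any(np.isclose(grid, D))
        assert grid.min() <= 5.1e-4 and grid.max() >= 0.2 - 1e-12

    def test_delay_grid_contains_drive_period_multiples(self):
        grid = default_delay_grid()
        for tau in (14, 28, 42, 56, 70, 84, 98):
            assert np.any(np.isclose(grid, tau))

    def test_derive_seed_is_stable_and_bounded(self):
        a = derive_seed(1, "D", 0.04, 0)
        assert a == derive_seed(1, "D", 0.04, 0)
        assert 0 <= a < 2**31
        assert a != derive_seed(1, "D", 0.04, 1)
        assert a != derive_seed(2, "D", 0.04, 0)
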