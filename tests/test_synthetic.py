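import numpy as np
import pandas as pd
import pytest

from endoflow.calibration import CalibrationConstants, calibrate
from endoflow.segmentation import CellLabelMap, extract_traces
from endoflow.synth import (
    KD,
    SCRAMBLE,
    ConditionConfig,
    PhasePlan,
    SaturationError,
    TraceGroundTruth,
    condition_preset,
    synth_condition,
    synth_monolayer,
    synth_movie,
    synth_polar_series,
    synth_trace,
    synth_velocity_field,
    true_calcium,
)


class TestSynthTrace:
    def test_flat_identity_case(self):
        truth = TraceGroundTruth()
        tr = synth_trace(truth)
        flow = tr.f[tr.phase == "flow"]
        assert np.allclose(flow, flow[0])

    def test_roundtrip_through_calibration(self):
        truth = TraceGroundTruth(spike_onsets=(100.0,), spike_durations=(5.0,),
                                 spike_amplitudes=(10.0,))
        tr = synth_trace(truth)
        ca = calibrate(tr, CalibrationConstants(fmin=truth.fmin, fmax=truth.fmax,
                                                kd=truth.kd))
        assert np.abs(ca.ca - true_calcium(truth)).max() < 1e-9

    def test_seed_determinism(self):
        truth = TraceGroundTruth(spike_onsets=(50.0,), spike_durations=(8.0,),
                                 spike_amplitudes=(5.0,), noise_sd=0.3, seed=77)
        a = synth_trace(truth)
        b = synth_trace(truth)
        assert np.array_equal(a.f, b.f)

    def test_saturating_spike_rejected(self):
        truth = TraceGroundTruth(spike_onsets=(100.0,), spike_durations=(5.0,),
                                 spike_amplitudes=(1e12,))
        with pytest.raises(SaturationError, match="spike"):
            synth_trace(truth)

    def test_calibration_phases_approach_levels(self):
        tr = synth_trace(TraceGroundTruth())
        iono = tr.f[tr.phase == "ionomycin"]
        edta = tr.f[tr.phase == "edta"]
        assert iono[-1] == pytest.approx(600.0, rel=1e-6)
        assert edta[-1] == pytest.approx(100.0, rel=1e-6)

    def test_multiplicative_bleach_attenuates(self):
        truth = TraceGroundTruth(bleach_coeffs=(1.0, -2e-4, 0.0, 0.0, -100.0))
        tr = synth_trace(truth)
        flow = tr.f[tr.phase == "flow"]
        assert flow[-1] < flow[0]


class TestSynthCondition:
    def test_no_responders(self):
        cfg = ConditionConfig("null", 20, 0.0, 2.0, 8.0, 1.0, 4.0, 1.0, 120.0)
        traces, cells, spikes = synth_condition(cfg, seed=0)
        assert cells.n_spikes.sum() == 0
        assert len(spikes) == 0

    def test_all_responders(self):
        cfg = ConditionConfig("all", 50, 1.0, 2.0, 8.0, 1.0, 4.0, 1.0, 120.0)
        _, cells, _ = synth_condition(cfg, seed=0)
        assert cells.responder.all()

    def test_amplitude_mean_matches_config(self):
        # sampling check against the preset's own parameters (2 SEM band)
        cfg = condition_preset("scramble", 200)
        _, _, spikes = synth_condition(cfg, seed=3)
        sem = spikes.amplitude_nM.std() / np.sqrt(len(spikes))
        assert abs(spikes.amplitude_nM.mean() - cfg.amplitude_mean) < 2 * sem

    def test_population_recovery_within_3se(self):
        # truth-table means track the configured means for n >= 300 cells
        cfg = condition_preset("scramble", 300)
        _, cells, spikes = synth_condition(cfg, seed=5)
        for col, target in (("amplitude_nM", cfg.amplitude_mean),
                            ("duration_s", cfg.duration_mean)):
            se = spikes[col].std() / np.sqrt(len(spikes))
            assert abs(spikes[col].mean() - target) < 3 * se
        p = cells.responder.mean()
        assert abs(p - cfg.responder_prob) < 3 * np.sqrt(
            cfg.responder_prob * (1 - cfg.responder_prob) / len(cells))

    def test_determinism(self):
        cfg = condition_preset("kd", 10)
        a = synth_condition(cfg, seed=4)
        b = synth_condition(cfg, seed=4)
        assert all(np.array_equal(x.f, y.f) for x, y in zip(a[0], b[0]))
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_presets_carry_published_statistics(self):
        assert SCRAMBLE.n_cells == 347 and KD.n_cells == 339
        assert SCRAMBLE.amplitude_mean == 4.1 and KD.amplitude_mean == 7.8
        assert SCRAMBLE.amplitude_sd == pytest.approx(0.3 * np.sqrt(347))


class TestSynthMovie:
    def test_constant_cell_recovered(self):
        labels = np.zeros((8, 8), np.int32)
        labels[2:5, 2:5] = 1
        lab = CellLabelMap(labels)
        tr = synth_trace(TraceGroundTruth())
        movie = synth_movie(lab, [tr_with_id(tr, 1)])
        (rec,) = extract_traces(movie, lab)
        assert np.allclose(rec.f, tr.f)

    def test_two_cells_distinct(self):
        labels = np.zeros((8, 8), np.int32)
        labels[0:3, 0:3] = 1
        labels[5:8, 5:8] = 2
        lab = CellLabelMap(labels)
        t1 = synth_trace(TraceGroundTruth(baseline_ca=100.0))
        t2 = synth_trace(TraceGroundTruth(baseline_ca=200.0))
        movie = synth_movie(lab, {1: tr_with_id(t1, 1), 2: tr_with_id(t2, 2)})
        r1, r2 = extract_traces(movie, lab)
        assert not np.allclose(r1.f, r2.f)
        assert np.allclose(r1.f, t1.f)

    def test_noise_clt(self, rng):
        labels = np.zeros((20, 20), np.int32)
        labels[:, :] = 1
        lab = CellLabelMap(labels)
        tr = synth_trace(TraceGroundTruth())
        movie = synth_movie(lab, [tr_with_id(tr, 1)], noise_sd=2.0, seed=9)
        (rec,) = extract_traces(movie, lab)
        resid = rec.f - tr.f
        assert resid.std() == pytest.approx(2.0 / 20.0, rel=0.25)

    def test_missing_trace_listed(self):
        labels = np.zeros((4, 4), np.int32)
        labels[0, 0] = 1
        labels[3, 3] = 2
        with pytest.raises(ValueError, match=r"\[2\]"):
            synth_movie(CellLabelMap(labels), {1: synth_trace(TraceGroundTruth())})


def tr_with_id(tr, cid):
    tr.cell_id = cid
    return tr


class TestSynthMonolayer:
    def test_zero_gap_full_coverage(self):
        from endoflow.morphometry import junction_coverage

        m = synth_monolayer(9, elongation=3.0, gap_fraction=0.0, seed=1)
        _, uncovered = junction_coverage(m.junction_image, m.border_mask)
        assert uncovered == 0.0

    def test_zero_orientation_recovered(self):
        from endoflow.morphometry import cell_shape_metrics

        m = synth_monolayer(9, elongation=4.0, orientation_deg=0.0, seed=2)
        shapes = cell_shape_metrics(m.labels)
        assert max(s.orientation_deg for s in shapes) < 2.0

    def test_elongation_recovered_within_5pct(self):
        from endoflow.morphometry import cell_shape_metrics

        m = synth_monolayer(9, elongation=4.0, orientation_deg=0.0, seed=3)
        shapes = cell_shape_metrics(m.labels)
        for s in shapes:
            assert s.elongation_factor == pytest.approx(4.0, rel=0.05)

    def test_gap_fraction_rejected(self):
        with pytest.raises(ValueError):
            synth_monolayer(4, gap_fraction=1.0)


class TestSynthPolarSeries:
    def test_limits(self):
        t = np.array([0.0, 10.0, 1e6])
        frame, truth = synth_polar_series(30.0, t, n_cells=5, noise=0.0)
        series = frame.groupby("time_min").downstream_fraction.mean()
        assert series.loc[0.0] == pytest.approx(truth["d0"])
        assert series.loc[1e6] == pytest.approx(truth["d_inf"])

    def test_noiseless_fit_recovers_tau(self):
        from endoflow.morphometry import fit_repolarization

        t = np.linspace(0, 90, 10)
        frame, truth = synth_polar_series(30.0, t, n_cells=3, noise=0.0)
        series = frame.groupby("time_min").downstream_fraction.mean()
        tau, d0, d_inf = fit_repolarization(series.index.values, series.values)
        assert tau == pytest.approx(30.0, rel=1e-6)


class TestSynthVelocityField:
    def test_unit_inputs(self):
        _, truth = synth_velocity_field(1.0, 1.0, 1.0, viscosity=1.0)
        assert np.all(truth.tau == 6.0)

    def test_linearity_in_viscosity(self):
        _, t1 = synth_velocity_field(0.2, 0.5, 0.04, viscosity=0.0078)
        _, t2 = synth_velocity_field(0.2, 0.5, 0.04, viscosity=2 * 0.0078)
        assert np.allclose(t2.tau, 2 * t1.tau)

    def test_chamber_worked_example(self):
        # mu=0.0078 dyn*s/cm^2, Q=0.15 cm^3/s, b=0.5 cm, h=0.04 cm -> 8.775
        _, truth = synth_velocity_field(0.15, 0.5, 0.04, viscosity=0.0078)
        assert truth.tau[0, 0] == pytest.approx(8.775)

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            synth_velocity_field(1.0, 0.0, 1.0)
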