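import numpy as np
import pytest

from fmsf import analyze_trace, correlation_with_normality_gate
from fmsf.synthetic import (
    OscillatorSpec,
    TraceSpec,
    default_oscillators,
    simulate_cohort,
    simulate_trace,
)


class TestOscillatorSpec:
    def test_frequency_must_match_band(self):
        with pytest.raises(ValueError, match="outside"):
            OscillatorSpec("endo", 0.1, 0.01)
        with pytest.raises(ValueError, match="outside"):
            OscillatorSpec("myo", 0.3, 0.01)
        OscillatorSpec("myo", 0.15, 0.01)  # right edge is included

    def test_unknown_band(self):
        with pytest.raises(ValueError, match="unknown band"):
            OscillatorSpec("respiratory", 0.3, 0.01)


class TestSimulateTrace:
    def test_single_myogenic_oscillator_ground_truth(self):
        spec = TraceSpec(oscillators=(OscillatorSpec("myo", 0.10, 0.01),),
                         noise_sd=0.0, seed=1)
        trace, truth = simulate_trace(spec)
        assert truth.expected_fm_rest == pytest.approx(50.0, rel=1e-3)
        report = analyze_trace(trace)
        assert report["fm"] == pytest.approx(truth.expected_fm_rest, rel=0.02)

    def test_silent_spec_gives_constant_trace(self):
        spec = TraceSpec(oscillators=(), noise_sd=0.0, seed=0)
        trace, truth = simulate_trace(spec)
        assert np.ptp(trace.intensities) == 0.0
        assert truth.expected_fm_rest == 0.0
        assert analyze_trace(trace)["fm"] <= 1e-6

    def test_seed_determinism(self):
        t1, _ = simulate_trace(TraceSpec(seed=5))
        t2, _ = simulate_trace(TraceSpec(seed=5))
        t3, _ = simulate_trace(TraceSpec(seed=6))
        np.testing.assert_array_equal(t1.intensities, t2.intensities)
        assert not np.array_equal(t1.intensities, t3.intensities)

    def test_full_protocol_morphology(self, full_porh_trace):
        trace, _ = full_porh_trace
        m = trace.marks
        assert m is not None and m.occlusion_duration_s == pytest.approx(180.0)
        v = trace.intensities / np.mean(trace.intensities[:int(25 * 170)])
        i_occ_end = int(25 * 359)
        i_min = int(25 * 385)
        assert v[i_occ_end] > 1.05          # ischemic rise under the cuff
        assert v[i_min] < 0.95              # hyperemic undershoot below baseline
        assert v[-1] > v[i_min]             # reperfusion recovery

    def test_scalar_gain_squares_reperfusion_fm(self):
        base = TraceSpec.full_porh(reperfusion_oscillator_gain=1.0, seed=2)
        boosted = TraceSpec.full_porh(reperfusion_oscillator_gain=1.8, seed=2)
        _, t0 = simulate_trace(base)
        _, t1 = simulate_trace(boosted)
        assert t1.expected_fm_reperfusion == pytest.approx(
            1.8 ** 2 * t0.expected_fm_reperfusion, rel=1e-9)

    def test_per_band_gain_shifts_pie_toward_myogenic(self, full_porh_trace):
        _, truth = full_porh_trace
        assert truth.expected_pie_reperfusion["myo"] > truth.expected_pie_rest["myo"]

    def test_end_to_end_gain_recovery(self):
        spec = TraceSpec.full_porh(reperfusion_oscillator_gain=1.5, noise_sd=0.0,
                                   seed=3)
        trace, truth = simulate_trace(spec)
        report = analyze_trace(trace)
        assert report["fm_r"] == pytest.approx(truth.expected_fm_reperfusion,
                                               rel=0.05)

    def test_named_baselines_absorbed_by_quadratic(self):
        for shape in ("ascending", "descending", "ascending-to-plateau",
                      "parabolic"):
            spec = TraceSpec(baseline=shape,
                             oscillators=(OscillatorSpec("myo", 0.10, 0.01),),
                             noise_sd=0.0, seed=4)
            trace, truth = simulate_trace(spec)
            report = analyze_trace(trace)
            assert report["fm"] == pytest.approx(truth.expected_fm_rest,
                                                 rel=0.03), shape

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            TraceSpec(duration_s=-1)
        with pytest.raises(ValueError, match="occlusion"):
            TraceSpec(protocol="full_porh", duration_s=200.0)
        with pytest.raises(ValueError, match="baseline"):
            TraceSpec(baseline="sigmoid")


class TestSimulateCohort:
    def test_determinism_and_shape(self):
        t1, p1 = simulate_cohort(n=20, planted_disturbed=2, seed=3)
        t2, p2 = simulate_cohort(n=20, planted_disturbed=2, seed=3)
        assert t1.equals(t2) and p1 == p2
        assert len(t1) == 20
        assert set(p1) <= set(t1["subject_id"])

    def test_zero_noise_age_relationship_is_exact(self):
        table, _ = simulate_cohort(n=30, noise={"fm_noise_sd": 0.0}, seed=4)
        res = correlation_with_normality_gate(table["age"], table["fm"])
        assert res.r == pytest.approx(-1.0, abs=1e-12)

    def test_reperfusion_exceeds_rest(self):
        table, _ = simulate_cohort(n=35, seed=5)
        assert (table["fm_r"] > table["fm"]).all()
        assert (table["pie_myo_r"] > table["pie_myo"]).mean() > 0.9

    def test_repeats_share_covariates(self):
        table, _ = simulate_cohort(n=10, seed=6, n_repeats=2)
        assert len(table) == 20
        by_subject = table.groupby("subject_id")
        assert (by_subject["age"].nunique() == 1).all()
        assert (by_subject["fm"].nunique() == 2).all()

    def test_planted_count_validated(self):
        with pytest.raises(ValueError, match="n/4"):
            simulate_cohort(n=12, planted_disturbed=3)
        with pytest.raises(ValueError, match="n >= 4"):
            simulate_cohort(n=3)
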