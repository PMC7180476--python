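"""Matching stage, refinement scan, and the composed detector."""

import numpy as np
import pytest

import gaitdtw as g
from gaitdtw.detector import detect_steps, refine_detection_dtw, refine_detection_pearson
from gaitdtw.templates import resample_linear

from conftest import random_series


def embed(template_samples, at, total, amp=1.0, offset=0.0, noise=None, rng=None, noise_sd=0.0):
    """Quiet baseline with a (scaled) template instance spliced in at `at`."""
    sig = np.zeros(total)
    if rng is not None:
        sig += rng.normal(0, 0.3, total)  # quiescent but non-constant baseline
    body = amp * np.asarray(template_samples) + offset
    if noise_sd and rng is not None:
        body = body + rng.normal(0, noise_sd, body.size)
    sig[at : at + body.size] = body
    return g.GaitSignal(samples=sig, sampling_rate_hz=100.0, trial_id="t")


class TestCorrelationProfile:
    def test_exact_affine_copy_scores_one(self, s5_template, rng):
        sig = embed(s5_template.samples, 100, 300, amp=35.0, offset=-4.0, rng=rng)
        profile = g.correlation_profile(sig, s5_template)
        assert profile.size == 300 - 63 + 1
        assert profile[100] == pytest.approx(1.0, abs=1e-12)

    def test_constant_signal_degenerate(self, s5_template):
        sig = g.GaitSignal(samples=np.full(200, 3.0))
        with pytest.warns(UserWarning, match="zero-variance"):
            profile = g.correlation_profile(sig, s5_template)
        assert np.all(profile == 0.0)

    def test_matches_naive_two_pass_pearson(self, s5_template, rng):
        sig = g.GaitSignal(samples=rng.normal(size=250))
        profile = g.correlation_profile(sig, s5_template)
        t = s5_template.samples
        for pos in range(0, profile.size, 17):
            w = sig.samples[pos : pos + t.size]
            expected = float(np.corrcoef(w, t)[0, 1])
            assert profile[pos] == pytest.approx(expected, abs=1e-10)

    def test_template_longer_than_signal(self, s5_template):
        sig = g.GaitSignal(samples=np.arange(10.0))
        with pytest.raises(g.ValidationError):
            g.correlation_profile(sig, s5_template)


class TestDetectSteps:
    def test_single_instance_detected(self, s5_template, default_config, rng):
        sig = embed(s5_template.samples, 80, 300, amp=50.0, rng=rng)
        lib = g.TemplateLibrary(templates=[s5_template])
        (d,) = detect_steps(sig, lib, default_config)
        assert (d.ic, d.fc) == (80, 80 + 62)
        assert d.correlation == pytest.approx(1.0, abs=1e-6)
        assert not d.refined and d.dtw_cost is None

    def test_two_separated_instances(self, s5_template, default_config, rng):
        sig = embed(s5_template.samples, 50, 400, amp=40.0, rng=rng)
        sig.samples[250 : 250 + 63] = 40.0 * s5_template.samples
        dets = detect_steps(sig, g.TemplateLibrary(templates=[s5_template]), default_config)
        assert [d.ic for d in dets] == [50, 250]

    def test_greedy_keeps_higher_correlation_on_overlap(self, s5_template, default_config, rng):
        # one clean copy, one degraded copy overlapping it by half a length
        clean = 40.0 * s5_template.samples
        degraded = 40.0 * s5_template.samples + rng.normal(0, 6.0, 63)
        sig = np.zeros(300) + rng.normal(0, 0.3, 300)
        sig[130 : 130 + 63] = degraded
        sig[100 : 100 + 63] = clean  # overwrites the first half of the degraded copy
        dets = detect_steps(g.GaitSignal(samples=sig), g.TemplateLibrary(templates=[s5_template]),
                            default_config)
        assert any(d.ic == 100 for d in dets)
        for a, b in zip(dets, dets[1:]):
            assert a.fc < b.ic  # hard non-overlap

    def test_detections_never_overlap_on_cohort(self, small_cohort, default_config, s5_template):
        lib = g.TemplateLibrary(templates=[s5_template])
        for sig, _ in small_cohort.trials:
            dets = detect_steps(sig, lib, default_config)
            for a, b in zip(dets, dets[1:]):
                assert a.fc < b.ic


class TestRefinementDtw:
    def make_case(self, s5_template, rng, perturb=(5, -5)):
        truth = (120, 120 + 62)
        sig = embed(s5_template.samples, truth[0], 400, amp=30.0, offset=2.0, rng=rng)
        det = g.Detection(ic=truth[0] + perturb[0], fc=truth[1] + perturb[1],
                          template_id=s5_template.template_id, correlation=0.9)
        return sig, det, truth

    def test_z_zero_only_populates_cost(self, s5_template, default_config, rng):
        sig, det, _ = self.make_case(s5_template, rng, perturb=(0, 0))
        cfg = g.DetectorConfig(z=0)
        out = refine_detection_dtw(sig, det, s5_template, cfg)
        assert (out.ic, out.fc) == (det.ic, det.fc)
        assert out.refined and out.dtw_cost is not None

    def test_recovers_true_boundaries_exactly(self, s5_template, default_config, rng):
        sig, det, truth = self.make_case(s5_template, rng)
        out = refine_detection_dtw(sig, det, s5_template, default_config)
        assert (out.ic, out.fc) == truth
        assert out.dtw_cost == pytest.approx(0.0, abs=1e-12)

    def test_cost_not_worse_than_unshifted(self, s5_template, default_config, rng):
        sig, det, _ = self.make_case(s5_template, rng, perturb=(3, 2))
        at_zero = refine_detection_dtw(sig, det, s5_template, g.DetectorConfig(z=0))
        refined = refine_detection_dtw(sig, det, s5_template, default_config)
        assert refined.dtw_cost <= at_zero.dtw_cost + 1e-12

    def test_boundaries_move_at_most_z(self, s5_template, rng):
        sig, det, _ = self.make_case(s5_template, rng, perturb=(4, 4))
        for z in (1, 3, 7):
            out = refine_detection_dtw(sig, det, s5_template, g.DetectorConfig(z=z))
            assert abs(out.ic - det.ic) <= z and abs(out.fc - det.fc) <= z

    def test_all_lags_invalid(self, s5_template):
        sig = g.GaitSignal(samples=np.arange(10.0))
        det = g.Detection(ic=0, fc=9, template_id=s5_template.template_id, correlation=0.8)
        with pytest.raises(g.RefinementInfeasibleError):
            refine_detection_dtw(sig, det, s5_template, g.DetectorConfig(z=0))


class TestRefinementPearson:
    def test_z_zero_unchanged(self, s5_template, rng):
        sig = embed(s5_template.samples, 100, 300, amp=25.0, rng=rng)
        det = g.Detection(ic=100, fc=162, template_id=s5_template.template_id, correlation=0.9)
        out = refine_detection_pearson(sig, det, s5_template, g.DetectorConfig(z=0))
        assert (out.ic, out.fc) == (100, 162)

    def test_linear_rescaling_recovered_by_both_criteria(self, s5_template, default_config, rng):
        # instance built by exact linear resampling to 70 samples
        body = resample_linear(s5_template.samples, 70)
        sig = embed(body, 90, 400, amp=30.0, rng=rng)
        det = g.Detection(ic=94, fc=94 + 62, template_id=s5_template.template_id, correlation=0.9)
        out_p = refine_detection_pearson(sig, det, s5_template, default_config)
        out_d = refine_detection_dtw(sig, det, s5_template, default_config)
        truth = (90, 90 + 69)
        err_p = abs(out_p.ic - truth[0]) + abs(out_p.fc - truth[1])
        err_d = abs(out_d.ic - truth[0]) + abs(out_d.fc - truth[1])
        assert err_p <= 2 and err_d <= 2


class TestDetectAndRefine:
    def test_criterion_none_equals_detect_steps(self, small_cohort, default_config, s5_template):
        lib = g.TemplateLibrary(templates=[s5_template])
        sig, _ = small_cohort.trials[0]
        assert g.detect_and_refine(sig, lib, default_config, "none") == detect_steps(
            sig, lib, default_config
        )

    def test_deterministic(self, small_cohort, default_config, s5_template):
        lib = g.TemplateLibrary(templates=[s5_template])
        sig, _ = small_cohort.trials[0]
        a = g.detect_and_refine(sig, lib, default_config, "dtw")
        b = g.detect_and_refine(sig, lib, default_config, "dtw")
        assert a == b

    def test_low_noise_cohort_full_recall(self, small_cohort, default_config, s5_template):
        lib = g.TemplateLibrary(templates=[s5_template])
        per = [(g.detect_and_refine(sig, lib, default_config, "dtw"), anns)
               for sig, anns in small_cohort.trials]
        report = g.evaluate_cohort(per)
        assert report.recall == 1.0

    def test_unknown_criterion(self, small_cohort, default_config, s5_template):
        lib = g.TemplateLibrary(templates=[s5_template])
        with pytest.raises(g.ValidationError):
            g.detect_and_refine(small_cohort.trials[0][0], lib, default_config, "euclid")
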