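"""Tests of the beat-reduction pipeline: detection, segmentation,
outlier screening, averaging, resampling and lead fusion."""

import numpy as np
import pytest

import bruganet as bn
from bruganet.beats import (BeatMatrix, InsufficientBeatsError,
                            MissingLeadError, QCFailureError, average_beats,
                            fuse_leads, reject_outlier_beats, resample_to_grid,
                            segment_beats)
from bruganet.synth import render_beat
from conftest import match_peaks


def _single_lead_record(seed, noise_sd=0.01, duration=30.0, rr_mean=1000.0,
                        rr_sd=0.0, dialect="mortara"):
    spec = bn.CohortSpec(n=1, duration_s=duration, rr_mean=rr_mean,
                         rr_sd=rr_sd, noise_sd=noise_sd, wander_amp=0.03,
                         powerline_amp=0.01, artifact_beat_rate=0.0,
                         dialect=dialect, seed=0)
    morph = bn.default_morphology(leads=("L2",))
    return bn.synthesize_record(spec, morph, patient_seed=seed)


class TestDetectRPeaks:
    def test_clean_60bpm_finds_every_beat_within_10ms(self):
        rec, truth = _single_lead_record(seed=3)
        peaks = bn.detect_r_peaks(rec)
        planted = truth["r_peak_indices"]
        assert len(peaks) == len(planted) == 30
        offsets_ms = np.abs(peaks - planted) / rec.fs * 1000.0
        assert offsets_ms.max() <= 10.0

    def test_flat_signal_raises(self):
        rec = bn.ECGRecord(signals={"L2": np.zeros(20000)}, fs=1000.0,
                           resolution_uV=1.0)
        with pytest.raises(InsufficientBeatsError):
            bn.detect_r_peaks(rec, lead="L2")

    def test_strictly_increasing_with_refractory(self, small_cohort):
        _, records, _, _ = small_cohort
        for rec in records[:4]:
            peaks = bn.detect_r_peaks(rec)
            gaps = np.diff(peaks)
            assert np.all(gaps > 0)
            assert np.all(gaps >= 0.25 * rec.fs)

    def test_auto_lead_prefers_dominant_r(self, small_cohort):
        _, records, _, _ = small_cohort
        from bruganet.beats import _fiducial_lead
        assert _fiducial_lead(records[0]) in ("L2", "V5", "V6")


class TestSegmentBeats:
    @pytest.mark.parametrize("dialect,fs,n_win,r_idx",
                             [("claris", 2000.0, 1500, 600),
                              ("mortara", 1000.0, 750, 300)])
    def test_window_arithmetic_per_dialect(self, dialect, fs, n_win, r_idx):
        rec, truth = _single_lead_record(seed=1, duration=15.0,
                                         dialect=dialect)
        mat = segment_beats(rec, truth["r_peak_indices"], "L2")
        assert mat.beats.shape[1] == n_win
        assert mat.r_index == r_idx

    def test_peak_too_close_to_edge_dropped(self):
        rec, truth = _single_lead_record(seed=2, duration=15.0)
        peaks = np.concatenate(([int(0.1 * rec.fs)], truth["r_peak_indices"]))
        mat = segment_beats(rec, peaks, "L2")
        assert mat.n_beats == len(truth["r_peak_indices"])
        assert int(0.1 * rec.fs) not in mat.peak_indices

    def test_baseline_median_subtracted(self):
        fs = 1000.0
        x = np.zeros(8000) + 0.5          # constant offset
        rec = bn.ECGRecord(signals={"L2": x}, fs=fs, resolution_uV=1.0)
        mat = segment_beats(rec, np.array([2000, 3000, 4000]), "L2")
        np.testing.assert_allclose(mat.beats, 0.0, atol=1e-12)


class TestOutlierRejection:
    def _matrix(self, beats):
        return BeatMatrix(lead="L2", beats=np.asarray(beats), r_index=300,
                          fs=1000.0, peak_indices=np.arange(len(beats)))

    def test_inverted_beats_rejected_exactly(self):
        tpl = render_beat(bn.default_morphology(leads=("L2",)), "L2", 1000.0)
        beats = [tpl.copy() for _ in range(20)] + [-tpl, -tpl]
        kept, mask, degraded = reject_outlier_beats(self._matrix(beats))
        assert mask.tolist() == [True] * 20 + [False, False]
        assert kept.n_beats == 20 and not degraded

    def test_amplitude_outlier_rejected_despite_perfect_correlation(self):
        tpl = render_beat(bn.default_morphology(leads=("L2",)), "L2", 1000.0)
        beats = [tpl.copy() for _ in range(10)] + [3.0 * tpl]
        _, mask, _ = reject_outlier_beats(self._matrix(beats))
        assert mask.tolist() == [True] * 10 + [False]

    def test_all_identical_beats_all_kept(self):
        tpl = render_beat(bn.default_morphology(leads=("L2",)), "L2", 1000.0)
        _, mask, degraded = reject_outlier_beats(self._matrix([tpl] * 5))
        assert mask.all() and not degraded

    def test_keep_three_rule_with_warning_flag(self):
        rng = np.random.default_rng(0)
        beats = rng.normal(0, 1, (5, 400))    # mutually uncorrelated
        kept, mask, degraded = reject_outlier_beats(self._matrix(beats))
        assert degraded and mask.sum() == 3 and kept.n_beats == 3

    def test_planted_artifacts_recovered(self):
        spec = bn.CohortSpec(n=1, duration_s=45.0, rr_mean=850.0, rr_sd=20.0,
                             noise_sd=0.01, artifact_beat_rate=0.1,
                             dialect="mortara", seed=0)
        morph = bn.default_morphology()
        false_rejections = 0
        for seed in range(6):
            rec, truth = bn.synthesize_record(spec, morph, patient_seed=seed)
            peaks = truth["r_peak_indices"]
            mat = segment_beats(rec, peaks, "V2")
            _, mask, _ = reject_outlier_beats(mat)
            art = set(truth["artifact_beat_indices"].tolist())
            planted = [k for k, p in enumerate(peaks)
                       if p in set(mat.peak_indices.tolist()) and k in art]
            rejected = {k for k, (p, ok) in
                        enumerate(zip(peaks, np.isin(peaks, mat.peak_indices)))
                        }
            # every planted artifact among segmented beats must be rejected
            seg_pos = {p: i for i, p in enumerate(mat.peak_indices)}
            for k in planted:
                assert not mask[seg_pos[peaks[k]]]
            false_rejections += int((~mask).sum() - len(planted))
        assert false_rejections <= 6   # at most ~1 per record


class TestAveraging:
    def test_noise_reduction_follows_inverse_sqrt_n(self):
        tpl = render_beat(bn.default_morphology(leads=("L2",)), "L2", 1000.0)
        rng = np.random.default_rng(5)
        sigma, N = 0.1, 64
        resid_sds = []
        for _ in range(50):
            beats = tpl + rng.normal(0, sigma, (N, len(tpl)))
            avg, n = average_beats(BeatMatrix("L2", beats, 300, 1000.0,
                                              np.arange(N)))
            assert n == N
            resid_sds.append(np.std(avg - tpl))
        expected = sigma / np.sqrt(N)
        assert np.mean(resid_sds) == pytest.approx(expected, rel=0.3)

    def test_single_beat_identity(self):
        beat = np.sin(np.linspace(0, 3, 400))
        avg, n = average_beats(BeatMatrix("L2", beat[None, :], 300, 1000.0,
                                          np.array([0])))
        np.testing.assert_array_equal(avg, beat)
        assert n == 1

    def test_two_beats_exact_mean(self):
        a, b = np.ones(100), np.full(100, 3.0)
        avg, _ = average_beats(BeatMatrix("L2", np.vstack([a, b]), 50, 1000.0,
                                          np.array([0, 1])))
        np.testing.assert_array_equal(avg, np.full(100, 2.0))


class TestResampling:
    @pytest.mark.parametrize("fs,n_in", [(2000.0, 1500), (1000.0, 750),
                                         (500.0, 375)])
    def test_native_grids_map_to_150_samples(self, fs, n_in):
        out = resample_to_grid(np.zeros(n_in), fs)
        assert len(out) == 150

    def test_passband_sinusoid_amplitude_preserved(self):
        fs = 2000.0
        t = np.arange(1500) / fs
        beat = np.sin(2 * np.pi * 5.0 * t)
        out = resample_to_grid(beat, fs)
        t_grid = np.arange(150) / 200.0
        np.testing.assert_allclose(out, np.sin(2 * np.pi * 5.0 * t_grid),
                                   atol=0.01)

    def test_r_fiducial_maps_to_sample_60(self):
        fs = 1000.0
        beat = np.zeros(750)
        beat[300] = 1.0                   # R spike at 300 ms
        out = resample_to_grid(beat, fs)
        assert np.argmax(out) == 60

    def test_upsampling_refused_unless_explicit(self):
        with pytest.raises(ValueError, match="upsampling"):
            resample_to_grid(np.zeros(113), 150.0)
        out = resample_to_grid(np.zeros(113), 150.0, allow_upsample=True)
        assert len(out) == 150


class TestFusion:
    def _reps(self, leads):
        return {lead: bn.RepresentativeBeat(lead=lead,
                                            samples=np.full(150, float(j)))
                for j, lead in enumerate(leads)}

    def test_nine_leads_give_1350_with_boundaries(self):
        fused = fuse_leads(self._reps(bn.CANONICAL_LEADS))
        assert len(fused.vector) == 1350
        assert fused.lead_boundaries == tuple(range(150, 1350, 150))

    def test_order_from_leadset_not_map_insertion(self):
        reps = self._reps(bn.CANONICAL_LEADS)
        shuffled = {k: reps[k] for k in reversed(bn.CANONICAL_LEADS)}
        np.testing.assert_array_equal(fuse_leads(reps).vector,
                                      fuse_leads(shuffled).vector)

    def test_twelve_lead_configuration(self):
        leads = bn.CANONICAL_LEADS + ("X1", "X2", "X3")
        fused = fuse_leads(self._reps(leads), leadset=leads)
        assert len(fused.vector) == 1800

    def test_missing_lead_named_in_error(self):
        reps = self._reps(bn.CANONICAL_LEADS[:-1])
        with pytest.raises(MissingLeadError, match="V6"):
            fuse_leads(reps)


class TestPreprocessRecord:
    def test_fused_segments_match_rendered_templates(self, clean_spec):
        morph = bn.default_morphology()
        rec, _ = bn.synthesize_record(clean_spec, morph, patient_seed=9)
        fused = bn.preprocess_record(rec)
        for lead in ("L2", "V1", "V5"):
            tpl = resample_to_grid(render_beat(morph, lead, rec.fs), rec.fs)
            tpl = tpl - np.median(tpl[:int(0.08 * 200)])
            assert np.max(np.abs(fused.segment(lead) - tpl)) < 0.02

    def test_translation_equivariance_by_one_period(self):
        spec = bn.CohortSpec(n=1, duration_s=25.0, rr_mean=1000.0, rr_sd=0.0,
                             noise_sd=0.0, wander_amp=0.0, powerline_amp=0.0,
                             artifact_beat_rate=0.0, dialect="mortara", seed=0)
        morph = bn.default_morphology()
        rec, _ = bn.synthesize_record(spec, morph, patient_seed=4)
        shift = int(rec.fs)     # exactly one RR period
        shifted = bn.ECGRecord(
            signals={l: rec[l][shift:] for l in rec.leads}, fs=rec.fs,
            resolution_uV=rec.resolution_uV, dialect=rec.dialect)
        f0 = bn.preprocess_record(rec)
        f1 = bn.preprocess_record(shifted)
        np.testing.assert_allclose(f0.vector, f1.vector, atol=1e-9)

    def test_cross_platform_fused_traces_agree(self):
        morph = bn.default_morphology(st_shape="coved", st_elevation=0.3)
        traces = {}
        for dialect in ("claris", "mortara"):
            spec = bn.CohortSpec(n=1, duration_s=25.0, rr_sd=30.0,
                                 noise_sd=0.0, wander_amp=0.0,
                                 powerline_amp=0.0, artifact_beat_rate=0.0,
                                 dialect=dialect, seed=0)
            rec, _ = bn.synthesize_record(spec, morph, patient_seed=77)
            traces[dialect] = bn.preprocess_record(rec).vector
        diff = traces["claris"] - traces["mortara"]
        # worst case bounded by half-sample fiducial alignment at the
        # coarser rate times the maximal QRS slope; see methods note
        assert np.max(np.abs(diff)) < 0.05
        assert np.sqrt(np.mean(diff**2)) < 0.01

    def test_qc_failure_refused_with_reasons(self):
        rec, _ = _single_lead_record(seed=1, duration=5.0)
        with pytest.raises(QCFailureError, match="duration"):
            bn.preprocess_record(rec)

    def test_transformer_matches_functional_pipeline(self, small_cohort):
        _, records, _, _ = small_cohort
        X_fn, _ = bn.preprocess_cohort(records[:3])
        X_tr = bn.RepresentativeBeatTransformer().fit(records[:3]) \
            .transform(records[:3])
        np.testing.assert_array_equal(X_fn, X_tr)
        assert X_tr.shape == (3, 1350)
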