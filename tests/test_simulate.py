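import numpy as np
import pytest

from hemianet.behavior import classify_responders, load_cohort, responder_counts
from hemianet.connectivity import epoch_spectra, imaginary_coherence
from hemianet.graph import characteristic_path_length, proportional_threshold
from hemianet.preprocess import segment
from hemianet.recording import RegionRecording
from hemianet.simulate import (
    CohortDesign,
    CohortEffects,
    CouplingSpec,
    DEFAULT_EFFECTS,
    GroundTruth,
    MixingSpec,
    OscillatorSpec,
    make_coupled_pair,
    quarter_cycle_lag,
    simulate_cohort,
    simulate_subject,
    time_effect_detection_rate,
)
from hemianet.stats import pearson

FS = 250.0
ALPHA1 = OscillatorSpec.for_band("Alpha1")
LAG = quarter_cycle_lag(ALPHA1.center_hz)


def _pair_icoh(x, y, band="Alpha1", fs=FS):
    rec = RegionRecording(np.vstack([x, y]), fs, ["x", "y"])
    return imaginary_coherence(epoch_spectra(segment(rec)), band).values[0, 1]


class TestSpecs:
    def test_oscillator_center_must_lie_in_band(self):
        with pytest.raises(ValueError, match="outside"):
            OscillatorSpec("Alpha1", center_hz=12.0, bandwidth_hz=2.0)
        with pytest.raises(ValueError, match="bandwidth"):
            OscillatorSpec("Alpha1", center_hz=9.0, bandwidth_hz=0.0)

    def test_coupling_validation(self):
        with pytest.raises(ValueError, match="distinct"):
            CouplingSpec("a", "a", "Alpha1", 0.5, LAG)
        with pytest.raises(ValueError, match="strength"):
            CouplingSpec("a", "b", "Alpha1", 1.5, LAG)
        with pytest.raises(ValueError, match="volume conduction"):
            CouplingSpec("a", "b", "Alpha1", 0.5, 0.0)

    def test_mixing_identity(self):
        m = MixingSpec.identity(4)
        assert m.is_identity
        leak = MixingSpec.uniform_leakage(4, 0.3)
        assert not leak.is_identity
        assert np.allclose(leak.matrix.sum(axis=1), 1.0)


class TestMakeCoupledPair:
    def test_zero_strength_pair_stays_at_noise_floor(self):
        c = CouplingSpec("x", "y", "Alpha1", 0.0, LAG)
        x, y, _ = make_coupled_pair(ALPHA1, c, snr=4.0, duration_s=300.0,
                                    fs=FS, seed=0)
        assert _pair_icoh(x, y) < 0.1  # 199-epoch noise floor is ~0.05

    def test_full_strength_noiseless_near_one(self):
        c = CouplingSpec("x", "y", "Alpha1", 1.0, LAG)
        x, y, _ = make_coupled_pair(ALPHA1, c, snr=np.inf, duration_s=300.0,
                                    fs=FS, seed=1)
        assert _pair_icoh(x, y) > 0.9

    def test_deterministic_under_seed(self):
        c = CouplingSpec("x", "y", "Alpha1", 0.6, LAG)
        a = make_coupled_pair(ALPHA1, c, seed=3)
        b = make_coupled_pair(ALPHA1, c, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_nyquist_guard(self):
        c = CouplingSpec("x", "y", "Beta2", 0.5,
                         quarter_cycle_lag(26.0))
        with pytest.raises(ValueError, match="Nyquist"):
            make_coupled_pair(OscillatorSpec.for_band("Beta2"), c, fs=50.0)

    def test_lag_rounding_to_zero_rejected(self):
        c = CouplingSpec("x", "y", "Alpha1", 0.5, 1e-5)
        with pytest.raises(ValueError, match="rounds to 0"):
            make_coupled_pair(ALPHA1, c, fs=FS)

    def test_ground_truth_records_parameters(self):
        c = CouplingSpec("x", "y", "Alpha1", 0.6, LAG)
        _, _, truth = make_coupled_pair(ALPHA1, c, snr=7.0, seed=5)
        assert truth.couplings == [c]
        assert truth.snr == 7.0
        assert truth.seed == 5


class TestSimulateSubject:
    def test_independent_regions_all_below_floor(self):
        truth = GroundTruth(couplings=[], mixing=MixingSpec.identity(4),
                            seed=2, snr=4.0)
        rec = simulate_subject(list("abcd"), truth, duration_s=300.0, fs=FS)
        vals = imaginary_coherence(epoch_spectra(segment(rec)), "Alpha1").values
        assert vals[np.triu_indices(4, 1)].max() < 0.1

    def test_mixing_fools_msc_but_not_icoh(self):
        from hemianet.connectivity import magnitude_squared_coherence

        mix = MixingSpec(np.array([[1.0, 0.6, 0, 0], [0.6, 1.0, 0, 0],
                                   [0, 0, 1.0, 0], [0, 0, 0, 1.0]]))
        truth = GroundTruth(couplings=[], mixing=mix, seed=4, snr=4.0)
        rec = simulate_subject(list("abcd"), truth, duration_s=300.0, fs=FS)
        spectra = epoch_spectra(segment(rec))
        msc = magnitude_squared_coherence(spectra, "Alpha1")
        ic = imaginary_coherence(spectra, "Alpha1")
        iu = np.triu_indices(4, 1)
        assert msc.values[0, 1] > 0.5
        assert ic.values[iu].max() < 0.1

    def test_injected_coupling_has_maximal_band_icoh(self):
        regions = [f"R{i}" for i in range(10)]
        c = CouplingSpec("R6", "R7", "Alpha1", 0.8, LAG)
        truth = GroundTruth(couplings=[c], mixing=MixingSpec.identity(10),
                            seed=5, snr=4.0)
        rec = simulate_subject(regions, truth, duration_s=300.0, fs=FS)
        vals = imaginary_coherence(epoch_spectra(segment(rec)), "Alpha1").values
        iu = np.triu_indices(10, 1)
        best = vals[iu].argmax()
        assert (regions[iu[0][best]], regions[iu[1][best]]) == ("R6", "R7")

    def test_deterministic_under_seed(self):
        truth = GroundTruth(couplings=[], mixing=MixingSpec.identity(3),
                            seed=9, snr=4.0)
        a = simulate_subject(list("abc"), truth, duration_s=10.0, fs=FS)
        b = simulate_subject(list("abc"), truth, duration_s=10.0, fs=FS)
        assert np.array_equal(a.data, b.data)

    def test_duplicate_regions_rejected(self):
        truth = GroundTruth(couplings=[], mixing=MixingSpec.identity(2),
                            seed=0, snr=4.0)
        with pytest.raises(ValueError, match="duplicate"):
            simulate_subject(["a", "a"], truth, duration_s=10.0, fs=FS)

    def test_unknown_coupling_region_rejected(self):
        c = CouplingSpec("a", "z", "Alpha1", 0.5, LAG)
        truth = GroundTruth(couplings=[c], mixing=MixingSpec.identity(2),
                            seed=0, snr=4.0)
        with pytest.raises(ValueError, match="unknown region"):
            simulate_subject(["a", "b"], truth, duration_s=10.0, fs=FS)


class TestCouplingMonotonicity:
    def test_icoh_monotone_in_strength(self):
        # mean estimated icoh over a small seed batch, strictly increasing
        strengths = [0.0, 0.2, 0.4, 0.6, 0.8]
        means = []
        for s in strengths:
            c = CouplingSpec("x", "y", "Alpha1", s, LAG)
            vals = []
            for seed in range(3):
                x, y, _ = make_coupled_pair(ALPHA1, c, snr=4.0,
                                            duration_s=120.0, fs=FS,
                                            seed=seed)
                vals.append(_pair_icoh(x, y))
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestSimulateCohort:
    def test_determinism(self):
        design = CohortDesign(n_per_group=2, duration_s=10.0, fs=FS)
        a = simulate_cohort(design, seed=11, render_eeg=True)
        b = simulate_cohort(design, seed=11, render_eeg=True)
        assert a.behavior.equals(b.behavior)
        assert a.metrics.equals(b.metrics)
        for key in a.recordings:
            assert np.array_equal(a.recordings[key].data,
                                  b.recordings[key].data)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            CohortDesign(n_per_group=1)

    def test_null_cohort_without_noise_has_no_responders(self):
        design = CohortDesign(n_per_group=3, effects=CohortEffects(),
                              fov_noise_pct=0.0)
        res = simulate_cohort(design, seed=1, render_eeg=False)
        labels = classify_responders(load_cohort(res.behavior))
        assert responder_counts(labels) == (0, 9)

    def test_behavior_table_feeds_behavior_module(self):
        res = simulate_cohort(CohortDesign(n_per_group=2), seed=5,
                              render_eeg=False)
        records = load_cohort(res.behavior)
        assert len(records) == 6
        assert {r.group_name for r in records} == {"Sham", "AC", "ACDC"}

    def test_time_effect_detection_rate_exceeds_half(self):
        # injected strength effect of 1.5 within-subject SD at follow-up in
        # the treated group; analytic noncentral-F power at n=8 is ~0.69
        rate = time_effect_detection_rate(n_cohorts=60, seed=0)
        assert rate > 0.5

    def test_fov_cpl_association_sign_recovered(self):
        # the injected latent recovery trades local redundancy for long-range
        # shortcuts, so FOV gain must correlate negatively with alpha CPL
        design = CohortDesign(n_per_group=8, duration_s=60.0, fs=FS,
                              timepoints=("pre", "post"),
                              effects=DEFAULT_EFFECTS)
        signs = []
        for seed in range(5):
            res = simulate_cohort(design, seed=seed, render_eeg=True)
            beh = res.behavior.set_index("id")
            pct = 100 * (beh["fov_post"] - beh["fov_pre"]) / beh["fov_pre"]
            cpls = {}
            for (sid, tp), rec in res.recordings.items():
                if tp != "post":
                    continue
                mat = imaginary_coherence(
                    epoch_spectra(segment(rec)), "Alpha1")
                g = proportional_threshold(mat, 0.30)
                cpls[sid] = characteristic_path_length(g).cpl
            sids = sorted(cpls)
            r, _ = pearson(pct.loc[sids].to_numpy(),
                           np.array([cpls[s] for s in sids]))
            signs.append(r < 0)
        assert all(signs)
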