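import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats as sstats

from eegsep.pe import PEParams, permutation_entropy_batch, wilcoxon_rank_sum
from eegsep.preprocessing import MONTAGE_19, segment_epochs
from eegsep.synthetic import (
    CohortSpec,
    EFFECT_CHANNELS,
    ES,
    PNES,
    generate_cohort,
    generate_subject,
    read_cohort,
    subject_seeds,
    write_cohort,
)


class TestCohortSpec:
    def test_defaults_match_study_geometry(self):
        spec = CohortSpec()
        assert spec.n_subjects == 36
        assert spec.epochs_per_subject == 214
        assert spec.epoch_samples == 512

    def test_non_integer_epoch_samples_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            CohortSpec(sampling_rate=256.0, epoch_seconds=0.3)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError, match="effect_size"):
            CohortSpec(effect_size=-1.0)

    @pytest.mark.parametrize("field,value", [
        ("n_subjects_per_class", 0), ("epochs_per_subject", 0),
        ("n_channels", 0), ("n_channels", 25),
    ])
    def test_bad_counts_rejected(self, field, value):
        with pytest.raises(ValueError):
            CohortSpec(**{field: value})


class TestGenerateSubject:
    def test_determinism(self, tiny_spec):
        a = generate_subject(tiny_spec, ES, 42)
        b = generate_subject(tiny_spec, ES, 42)
        assert np.array_equal(a.data, b.data)

    def test_length_epoch_ready(self, tiny_spec):
        rec = generate_subject(tiny_spec, PNES, 1)
        assert rec.n_samples == tiny_spec.epochs_per_subject * 512
        assert rec.artifact_mask is None

    def test_invalid_class_rejected(self, tiny_spec):
        with pytest.raises(ValueError, match="class_label"):
            generate_subject(tiny_spec, "CTL", 1)

    def test_band_limited_content(self, tiny_spec):
        rec = generate_subject(tiny_spec, PNES, 3)
        f, pxx = sps.welch(rec.data[0], fs=rec.sampling_rate, nperseg=1024)
        inband = pxx[(f >= 0.5) & (f <= 32)].sum()
        total = pxx.sum()
        # strictly band-limited synthesis; remainder is Welch window leakage
        assert inband / total > 0.95

    def test_alpha_peak_present(self, tiny_spec):
        rec = generate_subject(tiny_spec, PNES, 5)
        f, pxx = sps.welch(rec.data[0], fs=rec.sampling_rate, nperseg=2048)
        alpha = pxx[(f >= 8) & (f <= 12)].mean()
        neighbors = pxx[(f >= 16) & (f <= 24)].mean()
        assert alpha > 3 * neighbors

    def test_microvolt_scale(self, tiny_spec):
        rec = generate_subject(tiny_spec, PNES, 9)
        rms = np.sqrt(np.mean(rec.data ** 2, axis=1))
        assert np.all((rms > 5) & (rms < 20))

    def test_delta_zero_identical_law_same_seed(self):
        spec = CohortSpec(n_subjects_per_class=2, epochs_per_subject=4,
                          effect_size=0.0, seed=1)
        a = generate_subject(spec, ES, 42)
        b = generate_subject(spec, PNES, 42)
        assert np.array_equal(a.data, b.data)

    def test_effect_confined_to_designated_channels(self, tiny_spec):
        es = generate_subject(tiny_spec, ES, 42)
        spec0 = CohortSpec(**{**tiny_spec.__dict__, "effect_size": 0.0})
        base = generate_subject(spec0, ES, 42)
        diff = np.abs(es.data - base.data).max(axis=1)
        for i, name in enumerate(MONTAGE_19):
            if name in EFFECT_CHANNELS:
                assert diff[i] > 1.0, name
            else:
                assert diff[i] < 1e-9, name

    def test_continuous_mode_geometry(self):
        spec = CohortSpec(n_subjects_per_class=1, epochs_per_subject=4,
                          seed=0)
        rec = generate_subject(spec, PNES, 7, continuous=True,
                               artifact_fraction=0.25)
        assert rec.duration == pytest.approx(1200.0)
        assert rec.artifact_mask is not None
        n_slots = rec.n_samples // 512
        bad_slots = rec.artifact_mask.reshape(n_slots, 512).any(axis=1).sum()
        assert bad_slots == round(0.25 * n_slots)
        ep = segment_epochs(rec, max_epochs=4)
        assert ep.n_epochs == 4


class TestGenerateCohort:
    def test_default_spec_subject_count(self):
        seeds = subject_seeds(CohortSpec())
        assert seeds.size == 36

    def test_two_subjects_minimum(self):
        spec = CohortSpec(n_subjects_per_class=1, epochs_per_subject=2, seed=3)
        cohort = generate_cohort(spec)
        assert len(cohort) == 2
        assert {c for _, c, _ in cohort} == {ES, PNES}

    def test_balanced_and_reproducible(self, tiny_spec):
        a = generate_cohort(tiny_spec)
        b = generate_cohort(tiny_spec)
        assert [s[0] for s in a] == [s[0] for s in b]
        assert sum(1 for _, c, _ in a if c == ES) == 2
        for (_, _, ra), (_, _, rb) in zip(a, b):
            assert np.array_equal(ra.data, rb.data)


class TestClassEffect:
    def test_pe_higher_in_es_designated_channels_delta2(self):
        """Monte-Carlo check: mean order-3 PE of designated channels is
        higher under the class effect, Wilcoxon p < 0.05 (18 vs 18)."""
        spec = CohortSpec(n_subjects_per_class=18, epochs_per_subject=2,
                          effect_size=2.0, seed=77)
        idx = [MONTAGE_19.index(c) for c in EFFECT_CHANNELS]
        cohort = generate_cohort(spec)
        vals = {ES: [], PNES: []}
        for _, cls, rec in cohort:
            pe = permutation_entropy_batch(rec.data[idx], PEParams())
            vals[cls].append(pe.mean())
        res = wilcoxon_rank_sum(vals[ES], vals[PNES])
        assert np.mean(vals[ES]) > np.mean(vals[PNES])
        assert res.p_value < 0.05

    def test_effect_monotone_in_delta(self):
        """Designated-channel PE class difference is non-decreasing in
        delta, averaged over seeds."""
        idx = [MONTAGE_19.index(c) for c in EFFECT_CHANNELS]
        gaps = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            diffs = []
            for seed in range(10):
                spec = CohortSpec(n_subjects_per_class=1,
                                  epochs_per_subject=2,
                                  effect_size=delta, seed=seed)
                sseeds = subject_seeds(spec)
                es = generate_subject(spec, ES, int(sseeds[0]))
                pn = generate_subject(spec, PNES, int(sseeds[1]))
                pe_es = permutation_entropy_batch(es.data[idx]).mean()
                pe_pn = permutation_entropy_batch(pn.data[idx]).mean()
                diffs.append(pe_es - pe_pn)
            gaps.append(np.mean(diffs))
        tol = 0.01  # Monte-Carlo noise allowance
        assert all(g2 >= g1 - tol for g1, g2 in zip(gaps, gaps[1:])), gaps
        assert gaps[-1] > gaps[0]

    def test_delta_zero_rejection_at_nominal_rate(self):
        """Under delta=0 the classes share one generative law: a two-sample
        test rejects at roughly the nominal alpha over repeated seeds."""
        rejections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = CohortSpec(n_subjects_per_class=10, epochs_per_subject=2,
                              effect_size=0.0, seed=seed)
            stat = {ES: [], PNES: []}
            for _, cls, rec in generate_cohort(spec):
                stat[cls].append(float(np.var(rec.data)))
            p = wilcoxon_rank_sum(stat[ES], stat[PNES]).p_value
            rejections += p < 0.05
        # Binomial(20, 0.05): P(X >= 5) ~ 0.0026
        assert rejections <= 4


class TestCohortIO:
    def test_write_read_roundtrip_txt(self, tmp_path):
        spec = CohortSpec(n_subjects_per_class=1, epochs_per_subject=2,
                          n_channels=4, seed=2)
        manifest = write_cohort(spec, tmp_path)
        cohort = read_cohort(manifest)
        fresh = generate_cohort(spec)
        assert [s[:2] for s in cohort] == [s[:2] for s in fresh]
        for (_, _, ra), (_, _, rb) in zip(cohort, fresh):
            assert np.allclose(ra.data, rb.data, atol=1e-5)

    def test_write_read_roundtrip_edf(self, tmp_path):
        spec = CohortSpec(n_subjects_per_class=1, epochs_per_subject=2,
                          n_channels=3, seed=2)
        manifest = write_cohort(spec, tmp_path, fmt="edf")
        cohort = read_cohort(manifest)
        fresh = generate_cohort(spec)
        for (_, _, ra), (_, _, rb) in zip(cohort, fresh):
            scale = np.abs(rb.data).max()
            assert np.allclose(ra.data, rb.data, atol=2e-3 * scale)
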