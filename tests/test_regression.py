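import numpy as np
import pytest

from arspl.core import SOURCE_LEADS, TARGET_PRECORDIAL_LEADS
from arspl.metrics import rmse
from arspl.regression import (PatternMismatchError, SingularDesignError,
                              UnderdeterminedError, apply_lr,
                              derive_limb_leads, fit_lr, synthesize,
                              synthesize_lr, train, train_arspl,
                              train_global_lr)
from arspl.segmentation import segment
from arspl.synthetic import SynthSpec, generate


def _normal_equations_oracle(source, targets):
    """Literal (XᵀX)⁻¹XᵀR estimator, kept independent of the implementation."""
    x = np.column_stack([np.ones(source.shape[0]), source])
    return np.linalg.inv(x.T @ x) @ x.T @ targets


class TestFitLr:
    def test_exact_recovery_of_noiseless_coefficients(self):
        rng = np.random.default_rng(1)
        src = rng.normal(size=(100, 3))
        coef = np.array([10.0, 0.5, -0.2, 1.1])
        tgt = np.column_stack([np.ones(100), src]) @ coef
        b = fit_lr(src, tgt)
        assert np.max(np.abs(b[:, 0] - coef)) <= 1e-8

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            src = rng.normal(size=(50, 3))
            coef = rng.normal(size=(4, 2))
            tgt = np.column_stack([np.ones(50), src]) @ coef \
                + rng.normal(0, 5.0, size=(50, 2))
            b = fit_lr(src, tgt)
            oracle = _normal_equations_oracle(src, tgt)
            assert np.max(np.abs(b - oracle)) <= 1e-10 * max(1.0, np.abs(oracle).max())

    def test_residual_optimality_against_perturbations(self):
        rng = np.random.default_rng(3)
        src = rng.normal(size=(200, 3))
        tgt = rng.normal(size=(200, 4))
        b = fit_lr(src, tgt)
        x = np.column_stack([np.ones(200), src])
        best = np.linalg.norm(x @ b - tgt)
        for _ in range(100):
            other = b + rng.normal(0, 0.01, size=b.shape)
            assert best <= np.linalg.norm(x @ other - tgt) + 1e-12

    def test_underdetermined_rejected(self):
        with pytest.raises(UnderdeterminedError):
            fit_lr(np.zeros((3, 3)), np.zeros((3, 1)))

    def test_collinear_design_rejected(self):
        src = np.ones((50, 3))  # every column collinear with the intercept
        with pytest.raises(SingularDesignError):
            fit_lr(src, np.zeros((50, 1)))


class TestApplyLr:
    def test_zero_matrix_gives_zero_output(self):
        src = np.random.default_rng(0).normal(size=(30, 3))
        assert np.all(apply_lr(src, np.zeros((4, 5))) == 0.0)

    def test_identity_coefficient_selects_lead(self):
        src = np.random.default_rng(1).normal(size=(30, 3))
        b = np.zeros((4, 1))
        b[1, 0] = 1.0
        assert np.allclose(apply_lr(src, b)[:, 0], src[:, 0])

    def test_fit_apply_round_trip(self):
        rng = np.random.default_rng(4)
        src = rng.normal(size=(80, 3))
        coef = rng.normal(size=(4, 5))
        tgt = np.column_stack([np.ones(80), src]) @ coef
        assert np.max(np.abs(apply_lr(src, fit_lr(src, tgt)) - tgt)) <= 1e-8

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_lr(np.zeros((10, 2)), np.zeros((4, 5)))


class TestLimbLeads:
    @pytest.mark.parametrize("i, ii, expected", [
        (0.0, 0.0, {"III": 0.0, "aVR": 0.0, "aVL": 0.0, "aVF": 0.0}),
        (1.0, 1.0, {"III": 0.0, "aVR": -1.0, "aVL": 0.5, "aVF": 0.5}),
        (0.5, 1.0, {"III": 0.5, "aVR": -0.75, "aVL": 0.0, "aVF": 0.75}),
    ])
    def test_constant_lead_identities(self, i, ii, expected):
        out = derive_limb_leads(np.full(5, i), np.full(5, ii))
        for name, v in expected.items():
            assert np.allclose(out[name], v)

    def test_einthoven_and_goldberger_closure(self):
        rng = np.random.default_rng(5)
        i, ii = rng.normal(size=1000), rng.normal(size=1000)
        out = derive_limb_leads(i, ii)
        assert np.max(np.abs(i - ii + out["III"])) <= 1e-9
        assert np.max(np.abs(out["aVR"] + out["aVL"] + out["aVF"])) <= 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            derive_limb_leads(np.zeros(5), np.zeros(6))


class TestTrainArspl:
    def test_regional_matrices_recovered_exactly(self, cfg, aligned_subject):
        spec, record, truth, _ = aligned_subject
        models = train(record, cfg, peaks=truth, preprocess=False)
        for region, attr in (("stt", "b_stt"), ("rp", "b_rp"), ("qrs", "b_qrs")):
            err = np.max(np.abs(getattr(models, attr) - spec.region_matrices[region]))
            assert err <= 1e-6

    def test_ht_matrix_equals_complete_sequence_fit(self, cfg, aligned_subject):
        _, record, truth, _ = aligned_subject
        models = train(record, cfg, peaks=truth, preprocess=False)
        full_fit = fit_lr(record.matrix(SOURCE_LEADS),
                          record.matrix(TARGET_PRECORDIAL_LEADS))
        assert np.max(np.abs(models.b_ht - full_fit)) == 0.0

    def test_single_global_law_collapses_all_matrices(self, cfg):
        mats = {r: np.full((4, 5), 0.0) for r in ("stt", "rp", "qrs", "ht")}
        coef = np.array([[5.0], [0.4], [-0.3], [0.8]]) @ np.ones((1, 5))
        for r in mats:
            mats[r] = coef.copy()
        spec = SynthSpec(duration_s=12.0, seed=13, region_matrices=mats)
        record, truth, _ = generate(spec)
        models = train(record, cfg, peaks=truth, preprocess=False)
        for attr in ("b_stt", "b_rp", "b_qrs", "b_ht"):
            assert np.max(np.abs(getattr(models, attr) - coef)) <= 1e-8

    def test_pattern_mismatch_rejected(self, cfg, aligned_subject):
        from arspl.core import RegionBoundaries
        _, record, truth, tb = aligned_subject
        seg = segment(record, tb, truth)
        shifted = RegionBoundaries(tb.b_se + 1, tb.b_te + 1, tb.b_qs + 1,
                                   tb.n_samples)
        other = segment(record, shifted, truth)
        with pytest.raises(PatternMismatchError):
            train_arspl(seg, other, record.matrix(SOURCE_LEADS),
                        record.matrix(TARGET_PRECORDIAL_LEADS))


class TestSynthesize:
    def test_exact_reconstruction_on_aligned_subject(self, cfg, aligned_subject):
        _, record, truth, _ = aligned_subject
        models = train(record, cfg, peaks=truth, preprocess=False)
        syn = synthesize(record.subset(SOURCE_LEADS), models, cfg,
                         peaks=truth, preprocess=False)
        for lead in TARGET_PRECORDIAL_LEADS:
            assert rmse(syn.leads[lead], record.leads[lead]) <= 1e-6

    def test_piecewise_beats_global_lr_on_every_lead(self, cfg, aligned_subject):
        _, record, truth, _ = aligned_subject
        models = train(record, cfg, peaks=truth, preprocess=False)
        b_lr = train_global_lr(record, cfg, preprocess=False)
        syn = synthesize(record.subset(SOURCE_LEADS), models, cfg,
                         peaks=truth, preprocess=False)
        syn_lr = synthesize_lr(record.subset(SOURCE_LEADS), b_lr, cfg,
                               preprocess=False)
        for lead in TARGET_PRECORDIAL_LEADS:
            e_pw = rmse(syn.leads[lead], record.leads[lead])
            e_lr = rmse(syn_lr.leads[lead], record.leads[lead])
            assert e_pw <= e_lr

    def test_zero_models_give_zero_precordials(self, cfg, clean_subject):
        from arspl.core import RegionModels
        _, record, truth, _ = clean_subject
        zero = RegionModels(*(np.zeros((4, 5)) for _ in range(4)),
                            target_leads=TARGET_PRECORDIAL_LEADS)
        syn = synthesize(record.subset(SOURCE_LEADS), zero, cfg,
                         peaks=truth, preprocess=False)
        for lead in TARGET_PRECORDIAL_LEADS:
            assert np.all(syn.leads[lead] == 0.0)

    def test_source_leads_pass_through_and_closure(self, cfg, clean_subject):
        _, record, truth, _ = clean_subject
        models = train(record, cfg, peaks=truth, preprocess=False)
        syn = synthesize(record.subset(SOURCE_LEADS), models, cfg,
                         peaks=truth, preprocess=False)
        assert set(syn.leads) == {"I", "II", "III", "aVR", "aVL", "aVF",
                                  "V1", "V2", "V3", "V4", "V5", "V6"}
        for lead in SOURCE_LEADS:
            assert np.array_equal(syn.leads[lead], record.leads[lead])
        i, ii, iii = syn.leads["I"], syn.leads["II"], syn.leads["III"]
        assert np.max(np.abs(i - ii + iii)) <= 1e-9
        avr, avl, avf = syn.leads["aVR"], syn.leads["aVL"], syn.leads["aVF"]
        assert np.max(np.abs(avr + avl + avf)) <= 1e-9
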