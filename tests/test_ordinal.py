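import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from qcscore import ordinal
from qcscore.ordinal import (
    FitError,
    ModelSpec,
    _OrdinalCore,
    build_design,
    fit,
    interaction_test,
    loglik,
    odds_ratios,
)
from qcscore.ratings import RatingDataset
from qcscore.simulate import RaterProfile, SimulationConfig, generate


def dense_loglik(y, X, groups, tau, beta, sigma, grid=10_001, span=10.0):
    """Brute-force trapezoid integration over the random intercept."""
    z = np.linspace(-span, span, grid)
    phi = np.exp(-0.5 * z**2) / math.sqrt(2 * math.pi)
    taue = np.concatenate([[-np.inf], tau, [np.inf]])
    total = 0.0
    for g in np.unique(groups):
        mask = groups == g
        eta = X[mask] @ beta
        probs = np.stack(
            [
                expit(taue[yy + 1] - e - sigma * z) - expit(taue[yy] - e - sigma * z)
                for yy, e in zip(y[mask], eta)
            ]
        )
        total += math.log(np.trapezoid(probs.prod(axis=0) * phi, z))
    return total


@pytest.fixture
def tiny_mixed_dataset():
    cfg = SimulationConfig(
        n_images=3,
        slice_levels={"mid": 1},
        contour_types=("lv_endo",),
        phases=("ED",),
        pathology_counts={"healthy": 3},
        raters=(RaterProfile("A"), RaterProfile("B")),
        factor_effects={},
        method_interactions={},
        beta_method=0.3,
        sigma_image=1.5,
        thresholds=(-2.0, -1.0, 0.5),
        seed=5,
    )
    return generate(cfg)


class TestLoglik:
    @pytest.mark.parametrize("sigma", [0.3, 1.3, 3.0])
    def test_quadrature_matches_dense_integration(self, tiny_mixed_dataset, sigma):
        spec = ModelSpec(fixed_effects=("method", "rater"))
        tau = np.array([-2.2, -0.9, 0.6])
        beta = np.array([0.25, -0.1])
        value = loglik(
            spec,
            {"thresholds": tau, "beta": beta, "sigma_u": sigma},
            tiny_mixed_dataset,
        )
        y, X, _, groups, _ = build_design(tiny_mixed_dataset, spec)
        oracle = dense_loglik(y, X, groups, tau, beta, sigma)
        assert value == pytest.approx(oracle, abs=1e-8)

    def test_sigma_zero_collapses_to_plain_ordered_logit(self, tiny_mixed_dataset):
        spec = ModelSpec(fixed_effects=("method", "rater"))
        tau = np.array([-2.0, -1.0, 0.5])
        beta = np.array([0.3, -0.2])
        mixed_at_zero = loglik(
            spec, {"thresholds": tau, "beta": beta, "sigma_u": 0.0}, tiny_mixed_dataset
        )
        y, X, _, groups, q = build_design(tiny_mixed_dataset, spec)
        taue = np.concatenate([[-np.inf], tau, [np.inf]])
        eta = X @ beta
        term_by_term = float(
            np.log(expit(taue[y + 1] - eta) - expit(taue[y] - eta)).sum()
        )
        assert mixed_at_zero == pytest.approx(term_by_term, abs=1e-10)

    def test_invalid_thresholds_signalled(self, tiny_mixed_dataset):
        spec = ModelSpec(fixed_effects=("method",))
        with pytest.raises(ValueError, match="ascending"):
            loglik(
                spec,
                {"thresholds": [0.5, -1.0, 1.0], "beta": [0.0], "sigma_u": 1.0},
                tiny_mixed_dataset,
            )

    def test_location_shift_compensated_by_intercept(self, tiny_mixed_dataset):
        # an intercept column absorbing a constant threshold shift leaves the
        # likelihood unchanged (location identifiability structure)
        spec = ModelSpec(fixed_effects=("method",))
        y, X, _, groups, q = build_design(tiny_mixed_dataset, spec)
        X1 = np.column_stack([np.ones(len(y)), X])
        core = _OrdinalCore(y, X1, groups, q, random=True)
        tau = np.array([-2.0, -1.0, 0.5])
        beta = np.array([0.0, 0.3])
        shift = 0.9
        v0, _ = core.loglik_adaptive(tau, beta, 1.2)
        v1, _ = core.loglik_adaptive(tau + shift, np.array([shift, 0.3]), 1.2)
        assert v0 == pytest.approx(v1, abs=1e-9)


class TestFit:
    def test_sigma_zero_matches_independent_ordered_logit(self, small_null_config):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        ds = generate(
            dataclasses.replace(small_null_config, sigma_image=0.0, beta_method=0.4),
            seed=7,
        )
        spec = ModelSpec(fixed_effects=("method", "rater"), random_intercept=None)
        mine = fit(spec, ds)
        y, X, names, _, _ = build_design(ds, spec)
        ref = OrderedModel(pd.Series(y), pd.DataFrame(X, columns=names), distr="logit").fit(
            method="bfgs", disp=False, gtol=1e-10
        )
        ref_beta = ref.params[: len(names)].to_numpy()
        ref_cuts = ref.params[len(names):].to_numpy().copy()
        ref_cuts[1:] = np.exp(ref_cuts[1:])
        ref_cuts = np.cumsum(ref_cuts)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-6)
        np.testing.assert_allclose(mine.beta.to_numpy(), ref_beta, atol=1e-4)
        np.testing.assert_allclose(mine.thresholds, ref_cuts, atol=1e-4)

    def test_mixed_fit_recovers_generating_effect(self, small_null_config):
        cfg = dataclasses.replace(
            small_null_config,
            n_images=150,
            pathology_counts={"healthy": 150},
            beta_method=0.5,
            sigma_image=1.0,
        )
        ds = generate(cfg, seed=13)
        res = fit(ModelSpec(fixed_effects=("method", "rater")), ds)
        assert res.converged
        term = "method[automated]"
        assert abs(res.beta[term] - 0.5) < 4 * res.se(term)
        assert 0.5 < res.sigma_u < 1.6
        # thresholds strictly increasing, vcov symmetric PSD
        assert (np.diff(res.thresholds) > 0).all()
        vc = res.vcov.to_numpy()
        np.testing.assert_allclose(vc, vc.T, atol=1e-10)
        assert (np.linalg.eigvalsh(vc) > -1e-8).all()

    def test_category_relabel_flips_coefficients(self, small_null_config):
        ds = generate(
            dataclasses.replace(small_null_config, beta_method=0.6), seed=3
        )
        flipped_frame = ds.df.copy()
        flipped_frame["score"] = 5 - flipped_frame["score"]
        flipped = RatingDataset(flipped_frame)
        spec = ModelSpec(fixed_effects=("method", "rater"))
        a = fit(spec, ds)
        b = fit(spec, flipped)
        np.testing.assert_allclose(
            b.beta.to_numpy(), -a.beta.to_numpy(), atol=1e-3
        )
        np.testing.assert_allclose(
            b.thresholds, -a.thresholds[::-1], atol=1e-3
        )
        assert b.sigma_u == pytest.approx(a.sigma_u, abs=1e-3)

    def test_single_score_category_rejected(self, tiny_dataset):
        frame = tiny_dataset.df.copy()
        frame["score"] = 4
        with pytest.raises(FitError, match="two observed"):
            fit(ModelSpec(fixed_effects=("method",)), RatingDataset(frame))

    def test_collinear_design_rejected(self, small_null_config):
        ds = generate(small_null_config, seed=1)
        spec = ModelSpec(fixed_effects=("method", "method"))
        with pytest.raises(FitError, match="rank deficient"):
            fit(spec, ds)


class TestOddsRatios:
    @staticmethod
    def _fake_fit(beta, se):
        spec = ModelSpec(fixed_effects=("method",))
        vcov = pd.DataFrame(
            [[se**2]], index=["method[automated]"], columns=["method[automated]"]
        )
        return ordinal.ModelFit(
            thresholds=np.array([-2.0, -1.0, 0.0]),
            beta=pd.Series({"method[automated]": beta}),
            sigma_u=1.0,
            loglik=0.0,
            vcov=vcov,
            converged=True,
            n_obs=10,
            n_groups=2,
            spec=spec,
        )

    def test_null_effect_closed_form(self):
        table = odds_ratios(self._fake_fit(0.0, 0.1))
        row = table.loc["method[automated]"]
        assert row["or"] == 1.0
        assert row["ci_low"] == pytest.approx(math.exp(-1.96 * 0.1), abs=1e-3)
        assert row["ci_high"] == pytest.approx(math.exp(1.96 * 0.1), abs=1e-3)

    def test_degenerate_se_gives_point_interval(self):
        row = odds_ratios(self._fake_fit(math.log(2.0), 0.0)).loc["method[automated]"]
        assert row["or"] == pytest.approx(2.0)
        assert row["ci_low"] == row["ci_high"] == pytest.approx(2.0)

    def test_interval_symmetric_on_log_scale(self):
        row = odds_ratios(self._fake_fit(0.7, 0.23)).loc["method[automated]"]
        assert math.log(row["ci_low"]) + math.log(row["ci_high"]) == pytest.approx(
            2 * row["beta"], abs=1e-12
        )

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError):
            odds_ratios(self._fake_fit(0.0, 0.1), ["method[alien]"])


class TestInteractions:
    def test_empty_interaction_block_is_null_test(self, small_null_config):
        # single-phase data: the method x phase block adds zero columns
        ds = generate(small_null_config, seed=2)
        spec = ModelSpec(fixed_effects=("method", "rater", "phase"))
        single_phase = RatingDataset(ds.df[ds.df["phase"] == "ED"])
        lrt = interaction_test(spec, single_phase, ("method", "phase"))
        assert lrt.df == 0
        assert lrt.statistic == pytest.approx(0.0, abs=1e-6)
        assert lrt.pvalue == 1.0

    def test_detects_generated_interaction(self, small_null_config):
        cfg = dataclasses.replace(
            small_null_config,
            n_images=120,
            pathology_counts={"healthy": 120},
            slice_levels={"mid": 2, "basal": 1},
            beta_method=0.3,
            factor_effects={"slice_level": {"basal": -0.5}},
            method_interactions={"slice_level": {"basal": -1.5}},
        )
        ds = generate(cfg, seed=6)
        spec = ModelSpec(fixed_effects=("method", "rater", "slice_level"))
        lrt = interaction_test(spec, ds, ("method", "slice_level"))
        assert lrt.df == 1
        assert lrt.pvalue < 0.05
        term = "method[automated]:slice_level[basal]"
        assert lrt.fit_full.beta[term] < 0

    def test_interaction_factor_must_be_fixed_effect(self, tiny_dataset):
        spec = ModelSpec(fixed_effects=("method",))
        with pytest.raises(FitError, match="fixed effect"):
            interaction_test(spec, tiny_dataset, ("method", "rater"))
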