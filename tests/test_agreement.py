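import math

import numpy as np
import pytest

from qcscore.agreement import (
    AgreementEstimate,
    DegenerateAgreementError,
    SubjectCountMatrix,
    ac2,
    agreement_from_dataset,
    benchmark,
    build_counts,
    compare_coefficients,
    identity_weights,
    linear_weights,
    ordinal_weights,
    quadratic_weights,
    weights,
)
from qcscore.ratings import RatingDataset
from qcscore.simulate import generate_known_agreement

from conftest import make_frame


# --------------------------------------------------------------------------
# independent brute-force transliteration of the estimator (no shared code)
def brute_force_ac2(r, w, fpc=0.0):
    n, q = len(r), len(r[0])
    ri = [sum(row) for row in r]
    multi = [i for i in range(n) if ri[i] >= 2]
    nprime = len(multi)
    pa_i = [0.0] * n
    for i in range(n):
        if ri[i] < 2:
            continue
        total = 0.0
        for k in range(q):
            rstar = sum(w[k][l] * r[i][l] for l in range(q))
            total += r[i][k] * (rstar - 1.0) / (ri[i] * (ri[i] - 1.0))
        pa_i[i] = total
    pa = sum(pa_i[i] for i in multi) / nprime
    pi = [sum(r[i][k] / ri[i] for i in range(n)) / n for k in range(q)]
    tw = sum(sum(row) for row in w)
    pe = tw / (q * (q - 1)) * sum(p * (1.0 - p) for p in pi)
    coef = (pa - pe) / (1.0 - pe)
    kappa = [
        (n / nprime) * (pa_i[i] - pe) / (1.0 - pe) if ri[i] >= 2 else 0.0
        for i in range(n)
    ]
    pe_i = [
        tw / (q * (q - 1)) * sum((r[i][k] / ri[i]) * (1.0 - pi[k]) for k in range(q))
        for i in range(n)
    ]
    kstar = [kappa[i] - 2.0 * (1.0 - coef) * (pe_i[i] - pe) / (1.0 - pe) for i in range(n)]
    var = (
        (1.0 - fpc) / (n * (n - 1.0)) * sum((x - coef) ** 2 for x in kstar)
        if n > 1
        else 0.0
    )
    return pa, pe, coef, math.sqrt(max(var, 0.0))


def random_count_matrix(rng, n, q, max_raters=4):
    r = np.zeros((n, q), dtype=np.int64)
    for i in range(n):
        k = int(rng.integers(1, max_raters + 1)) if i else 2  # guarantee one multi
        probs = rng.dirichlet(np.ones(q))
        r[i] = rng.multinomial(k, probs)
    return r


def assert_matches_brute_force(r, wm, tol=1e-12):
    counts = SubjectCountMatrix(
        r=r,
        categories=tuple(range(1, r.shape[1] + 1)),
        subject_ids=np.arange(len(r)).astype(str),
        n_raters=int(r.sum(axis=1).max()),
    )
    est = ac2(counts, wm)
    pa, pe, coef, se = brute_force_ac2(r.tolist(), wm.w.tolist())
    assert est.pa == pytest.approx(pa, abs=tol)
    assert est.pe == pytest.approx(pe, abs=tol)
    assert est.coefficient == pytest.approx(coef, abs=tol)
    assert est.se == pytest.approx(se, abs=tol)


# --------------------------------------------------------------------------
class TestWeights:
    def test_binary_scale_has_identity_weights(self):
        assert np.allclose(ordinal_weights(2).w, np.eye(2))

    def test_three_category_values(self):
        w = ordinal_weights(3).w
        assert w[0, 1] == pytest.approx(2 / 3)
        assert w[0, 2] == 0.0

    def test_four_category_values(self):
        w = ordinal_weights(4).w
        assert w[0, 1] == pytest.approx(5 / 6)
        assert w[0, 2] == pytest.approx(1 / 2)
        assert w[0, 3] == 0.0

    @pytest.mark.parametrize("family", ["identity", "ordinal", "linear", "quadratic"])
    @pytest.mark.parametrize("q", [2, 3, 4, 5])
    def test_invariants(self, family, q):
        wm = weights(q, family)
        assert np.allclose(wm.w, wm.w.T)
        assert np.allclose(np.diag(wm.w), 1.0)
        assert wm.w.min() >= 0 and wm.w.max() <= 1
        assert wm.w[0, q - 1] == pytest.approx(0.0 if family != "identity" else 0.0)

    def test_q_below_two_rejected(self):
        with pytest.raises(ValueError):
            ordinal_weights(1)


class TestCounts:
    def test_two_subjects_all_category_one(self):
        rows = [
            ("s0", 0, "mid", "lv_endo", "ED", "manual", r, 1, "healthy")
            for r in ("A", "B")
        ] + [
            ("s1", 0, "mid", "lv_endo", "ED", "manual", r, 1, "healthy")
            for r in ("A", "B")
        ]
        ds = RatingDataset(make_frame(rows), categories=(1, 2))
        counts = build_counts(ds)
        assert counts.r.tolist() == [[2, 0], [2, 0]]

    def test_missing_rater_leaves_singleton_row(self):
        rows = [
            ("s0", 0, "mid", "lv_endo", "ED", "manual", "A", 1, "healthy"),
            ("s0", 0, "mid", "lv_endo", "ED", "manual", "B", 2, "healthy"),
            ("s1", 0, "mid", "lv_endo", "ED", "manual", "A", 2, "healthy"),
        ]
        counts = build_counts(RatingDataset(make_frame(rows), categories=(1, 2)))
        assert sorted(counts.row_sums.tolist()) == [1, 2]
        assert counts.n_multi == 1

    def test_perfect_fixture_has_single_cell_rows(self):
        ds = generate_known_agreement(4, 30, 4, "perfect", seed=3)
        counts = build_counts(ds)
        assert ((counts.r > 0).sum(axis=1) == 1).all()
        assert (counts.r.max(axis=1) == 4).all()


class TestAC2:
    def test_perfect_agreement_is_exactly_one(self):
        ds = generate_known_agreement(4, 40, 4, "perfect", seed=6)
        for family in ("identity", "ordinal", "quadratic"):
            est = agreement_from_dataset(ds, family=family)
            assert est.pa == 1.0
            assert est.coefficient == 1.0

    def test_two_rater_hand_case(self):
        # subject A: both raters category 1; subject B: split 1/2
        r = np.array([[2, 0], [1, 1]])
        counts = SubjectCountMatrix(
            r=r, categories=(1, 2), subject_ids=np.array(["A", "B"]), n_raters=2
        )
        est = ac2(counts, identity_weights(2))
        assert est.pa == pytest.approx(0.5)
        assert est.pe == pytest.approx(0.375)
        assert est.coefficient == pytest.approx(0.2)

    def test_independent_uniform_is_chance_level(self):
        ds = generate_known_agreement(4, 5000, 4, "independent-uniform", seed=11)
        est = agreement_from_dataset(ds, family="ordinal")
        assert abs(est.coefficient) < 3 * est.se

    def test_brute_force_equivalence_on_random_instances(self, rng):
        families = ["identity", "ordinal", "linear", "quadratic"]
        checked = 0
        while checked < 100:
            n = int(rng.integers(2, 11))
            q = int(rng.integers(2, 6))
            r = random_count_matrix(rng, n, q)
            wm = weights(q, families[checked % 4])
            pi = (r / r.sum(axis=1, keepdims=True)).sum(axis=0) / n
            pe = wm.total / (q * (q - 1)) * float((pi * (1 - pi)).sum())
            if 1 - pe < 1e-6:
                continue
            assert_matches_brute_force(r, wm)
            checked += 1

    def test_identity_weights_reduce_to_unweighted_coefficient(self, rng):
        # independent unweighted (AC1-style) computation
        r = random_count_matrix(rng, 25, 4)
        ri = r.sum(axis=1)
        multi = ri >= 2
        pa = np.mean(
            [
                (row * (row - 1)).sum() / (k * (k - 1))
                for row, k in zip(r[multi], ri[multi])
            ]
        )
        pi = (r / ri[:, None]).sum(axis=0) / len(r)
        pe = float((pi * (1 - pi)).sum()) / (4 - 1)
        expected = (pa - pe) / (1 - pe)
        counts = SubjectCountMatrix(
            r=r, categories=(1, 2, 3, 4),
            subject_ids=np.arange(len(r)).astype(str), n_raters=int(ri.max()),
        )
        assert ac2(counts, identity_weights(4)).coefficient == pytest.approx(
            expected, abs=1e-12
        )

    def test_rater_label_permutation_invariance(self):
        ds = generate_known_agreement(4, 60, 3, "independent-uniform", seed=7)
        est = agreement_from_dataset(ds)
        relabeled = ds.df.copy()
        relabeled["rater_id"] = relabeled["rater_id"].map(
            {"r0": "r2", "r1": "r0", "r2": "r1"}
        )
        est2 = agreement_from_dataset(RatingDataset(relabeled, categories=ds.categories))
        assert est2.coefficient == pytest.approx(est.coefficient, abs=1e-14)
        assert est2.se == pytest.approx(est.se, abs=1e-14)
        assert est2.ci == pytest.approx(est.ci, abs=1e-14)

    def test_degenerate_chance_agreement_signalled(self):
        # saturating weights (all cells 1) with uniform margins drive the
        # chance term to exactly 1, leaving the coefficient undefined
        from qcscore.agreement import WeightMatrix

        saturating = WeightMatrix(q=2, w=np.ones((2, 2)), family="identity")
        counts = SubjectCountMatrix(
            r=np.array([[1, 1], [1, 1]]),
            categories=(1, 2),
            subject_ids=np.array(["a", "b"]),
            n_raters=2,
        )
        with pytest.raises(DegenerateAgreementError):
            ac2(counts, saturating)


class TestBenchmark:
    def test_published_point_and_ci_give_certain_top_interval(self):
        est = AgreementEstimate.from_point_ci(0.937, (0.935, 0.939))
        result = benchmark(est)
        assert round(100 * result.memberships["very good"]) == 100
        assert result.label == "very good"
        assert sum(result.memberships.values()) == pytest.approx(1.0, abs=1e-9)

    def test_mid_scale_estimate_lands_on_substantial(self):
        est = AgreementEstimate.from_point_ci(0.70, (0.70 - 1.96 * 0.05, 0.70 + 1.96 * 0.05))
        result = benchmark(est)
        assert result.memberships["very good"] == pytest.approx(0.02275, abs=1e-4)
        assert result.cumulative["substantial"] == pytest.approx(0.9772, abs=1e-3)
        assert result.label == "substantial"

    def test_zero_se_is_point_mass(self):
        est = AgreementEstimate(
            coefficient=0.5, pa=np.nan, pe=np.nan, se=0.0, ci=(0.5, 0.5),
            ci_level=0.95, n_subjects=10, n_raters=2,
        )
        result = benchmark(est)
        assert result.memberships["moderate"] == 1.0
        assert result.label == "moderate"


class TestComparison:
    def test_identical_estimates_are_indistinguishable(self):
        est = AgreementEstimate.from_point_ci(0.9, (0.88, 0.92))
        comp = compare_coefficients(est, est)
        assert comp.z == 0.0
        assert comp.pvalue == 1.0

    def test_published_cis_reproduce_small_pvalue(self):
        auto = AgreementEstimate.from_point_ci(0.940, (0.937, 0.943))
        manual = AgreementEstimate.from_point_ci(0.934, (0.931, 0.937))
        comp = compare_coefficients(auto, manual, mode="independent")
        assert round(comp.pvalue, 3) == 0.006

    def test_paired_mode_on_identical_ratings(self):
        ds = generate_known_agreement(4, 80, 3, "independent-uniform", seed=9)
        a = agreement_from_dataset(ds)
        b = agreement_from_dataset(ds)
        comp = compare_coefficients(a, b, mode="paired")
        assert comp.z == 0.0
        assert comp.pvalue == 1.0

    def test_paired_mode_rejects_unaligned_subjects(self):
        a = agreement_from_dataset(generate_known_agreement(4, 50, 3, "perfect", seed=1))
        b = agreement_from_dataset(generate_known_agreement(4, 40, 3, "perfect", seed=2))
        with pytest.raises(ValueError, match="same subjects"):
            compare_coefficients(a, b, mode="paired")
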