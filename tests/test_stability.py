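import numpy as np
import pandas as pd
import pytest

from rgstab import (
    Scale,
    bestkeeper,
    delta_ct,
    genorm,
    normfinder,
    to_relative_quantity,
)
from rgstab.errors import DomainError
from rgstab.stability import _m_values, _pairwise_variation_matrix

from conftest import make_matrix


def quantity(values, groups=None):
    return to_relative_quantity(make_matrix(values, groups=groups), base=2)


def sd(x):
    return float(np.std(np.asarray(x, dtype=float), ddof=1))


THREE_GENES = {
    "g1": [30.0, 31.0, 30.0, 31.0],
    "g2": [28.0, 29.0, 28.0, 29.0],
    "g3": [25.0, 25.0, 26.0, 26.0],
}


class TestGeNorm:
    def test_three_gene_hand_computation(self):
        res = genorm(quantity(THREE_GENES))
        # pairwise log2-ratio SDs computed by hand: V12=0, V13=V23=0.8165
        v13 = sd([0 - 0, -1 - 0, 0 + 1, -1 + 1])
        assert res.m_value["g3"] == pytest.approx(v13, rel=1e-12)
        assert res.exclusion_order[0] == "g3"
        assert res.m_value["g1"] == res.m_value["g2"] == pytest.approx(0.0)

    def test_all_constant_all_zero(self):
        res = genorm(quantity({"g1": [30, 30], "g2": [28, 28], "g3": [25, 25]}))
        assert (res.m_value == 0).all()
        # documented tie-break: lexicographically last removed first
        assert res.exclusion_order == ["g3", "g2", "g1"]

    def test_two_most_stable_share_min_m(self, rng):
        for _ in range(50):
            k, n = rng.integers(3, 9), rng.integers(3, 13)
            m = quantity({f"g{i}": list(rng.normal(30, 2, n)) for i in range(k)})
            res = genorm(m)
            min_m = res.m_value.min()
            assert (res.m_value == min_m).sum() == 2

    def test_k3_closed_form(self, rng):
        # M_j = (V_ja + V_jb) / 2 for three genes, no iteration
        m = quantity({f"g{i}": list(rng.normal(30, 2, 6)) for i in range(3)})
        log_q = np.log2(m.values)
        v = _pairwise_variation_matrix(log_q)
        closed = _m_values(v)
        for j in m.genes:
            partners = [x for x in m.genes if x != j]
            expected = (v.at[j, partners[0]] + v.at[j, partners[1]]) / 2
            assert closed[j] == pytest.approx(expected, rel=1e-12)
        res = genorm(m)
        worst = closed.idxmax()
        assert res.exclusion_order[0] == worst
        assert res.m_value[worst] == pytest.approx(closed.max(), rel=1e-12)

    def test_pairwise_v_values(self, rng):
        vals = {f"g{i}": list(rng.normal(30, 1, 8)) for i in range(5)}
        res = genorm(quantity(vals))
        assert res.pairwise_v is not None
        assert list(res.pairwise_v.index) == ["V2/3", "V3/4", "V4/5"]
        assert (res.pairwise_v >= 0).all()

    def test_requires_three_genes(self):
        with pytest.raises(DomainError):
            genorm(quantity({"g1": [30, 31], "g2": [28, 29]}))

    def test_requires_quantity_scale(self):
        with pytest.raises(DomainError):
            genorm(make_matrix(THREE_GENES))

    def test_ranking_most_stable_first(self):
        res = genorm(quantity(THREE_GENES))
        assert res.ranking()[-1] == "g3"


GROUPS_2x4 = {f"s{i + 1}": ("A" if i < 4 else "B") for i in range(8)}


def cycle_matrix_2groups(rng, k=5, planted=None, delta=0.0, noise=0.3):
    vals = {}
    for i in range(k):
        name = f"g{i}"
        base = 28.0 + i
        row = rng.normal(base, noise, 8)
        if name == planted:
            row[4:] += delta
        vals[name] = list(row)
    return make_matrix(vals, groups=GROUPS_2x4)


class TestNormFinder:
    def test_identical_values_zero(self):
        m = make_matrix({f"g{i}": [30.0] * 8 for i in range(4)}, groups=GROUPS_2x4)
        res = normfinder(m)
        assert (res.stability == 0).all()

    def test_gene_constant_shift_invariance(self, rng):
        m = cycle_matrix_2groups(rng)
        res1 = normfinder(m)
        shifted = m.values.copy()
        shifted.loc["g2"] += 7.5
        res2 = normfinder(make_matrix({g: list(shifted.loc[g]) for g in shifted.index},
                                      groups=GROUPS_2x4))
        pd.testing.assert_series_equal(res1.stability, res2.stability, rtol=1e-9)

    def test_planted_group_effect_detected(self, rng):
        hits = 0
        for _ in range(100):
            groups = {f"s{i + 1}": ("A" if i < 20 else "B") for i in range(40)}
            vals = {f"g{i}": list(rng.normal(28 + i, 0.2, 40)) for i in range(6)}
            row = np.array(vals["g3"])
            row[20:] += 2.0  # planted delta = 2 cycles
            vals["g3"] = list(row)
            res = normfinder(make_matrix(vals, groups=groups))
            if res.stability.idxmax() == "g3":
                hits += 1
        assert hits >= 95

    def test_single_group_is_intra_sd(self, rng):
        m = make_matrix({f"g{i}": list(rng.normal(30, 1, 6)) for i in range(4)})
        res = normfinder(m)
        assert res.inter_dev is None
        np.testing.assert_allclose(
            res.stability, np.sqrt(res.intra_var.iloc[:, 0]), rtol=1e-12
        )

    def test_intragroup_estimator_unbiased(self, rng):
        # planted per-gene variances recovered within 10% relative bias
        # at n = 1000 (bias measured by averaging over replicates)
        true_sd = np.array([0.2, 0.35, 0.5, 0.65, 0.8, 1.0])
        n, reps = 1000, 10
        est = np.zeros((reps, 6))
        for r in range(reps):
            # common per-sample shift cancels in the sample-centering step
            shift = rng.normal(0, 0.5, n)
            vals = {
                f"g{i}": list(30.0 + i + shift + rng.normal(0, true_sd[i], n))
                for i in range(6)
            }
            est[r] = normfinder(make_matrix(vals)).intra_var.iloc[:, 0].to_numpy()
        rel = np.abs(est.mean(axis=0) - true_sd**2) / true_sd**2
        assert (rel < 0.10).all()

    def test_group_too_small(self, rng):
        m = cycle_matrix_2groups(rng)
        groups = dict(GROUPS_2x4)
        groups["s8"] = "C"
        with pytest.raises(DomainError):
            normfinder(m, groups=groups)

    def test_needs_three_genes(self):
        m = make_matrix({"g1": [1.0, 2, 3, 4], "g2": [2.0, 3, 4, 5]})
        with pytest.raises(DomainError):
            normfinder(m)

    def test_no_shrink_flag(self, rng):
        m = cycle_matrix_2groups(rng, planted="g1", delta=1.0)
        shrunk = normfinder(m, shrink=True).stability
        raw = normfinder(m, shrink=False).stability
        # shrinkage can only pull the deviation term towards zero
        assert (raw >= shrunk - 1e-12).all()


class TestBestKeeper:
    def test_constant_gene(self):
        res = bestkeeper(make_matrix({"g1": [30.0, 30, 30], "g2": [28.0, 29, 30]}))
        assert res.table.at["g1", "sd_cq"] == 0.0
        assert res.table.at["g1", "cv_pct"] == 0.0

    def test_hand_computed_sd_cv(self):
        res = bestkeeper(make_matrix({"g1": [30.0, 32, 34, 32]}))
        assert res.table.at["g1", "sd_cq"] == pytest.approx(sd([30, 32, 34, 32]))
        assert res.table.at["g1", "sd_cq"] == pytest.approx(1.633, abs=1e-3)
        assert res.table.at["g1", "cv_pct"] == pytest.approx(100 * sd([30, 32, 34, 32]) / 32)

    def test_single_gene_index_self_correlation(self):
        res = bestkeeper(make_matrix({"g1": [30.0, 32, 34]}))
        np.testing.assert_allclose(res.index, [30, 32, 34])
        assert res.table.at["g1", "r_index"] == pytest.approx(1.0)

    def test_index_is_geometric_mean(self, rng):
        m = make_matrix({f"g{i}": list(rng.uniform(25, 35, 5)) for i in range(4)})
        res = bestkeeper(m)
        expected = np.prod(m.values.to_numpy(), axis=0) ** 0.25
        np.testing.assert_allclose(res.index, expected, rtol=1e-12)

    def test_am_gm_ordering(self, rng):
        m = make_matrix({f"g{i}": list(rng.uniform(25, 35, 10)) for i in range(3)})
        t = bestkeeper(m).table
        assert (t["min"] <= t["geo_mean"]).all()
        assert (t["geo_mean"] <= t["arith_mean"] + 1e-12).all()
        assert (t["arith_mean"] <= t["max"]).all()

    def test_single_sample_error(self):
        with pytest.raises(DomainError):
            bestkeeper(make_matrix({"g1": [30.0]}))


class TestDeltaCt:
    def test_hand_computed_example(self):
        m = make_matrix(
            {"A": [30.0, 30, 30, 30], "B": [32.0, 33, 32, 33], "C": [35.0, 35, 36, 36]}
        )
        res = delta_ct(m)
        ab = sd([-2, -3, -2, -3])
        ac = sd([-5, -5, -6, -6])
        bc = sd([-3, -2, -4, -3])
        assert res.pair_sd.at["A", "B"] == pytest.approx(ab)
        assert res.stability["A"] == pytest.approx((ab + ac) / 2)
        assert res.stability["B"] == pytest.approx((ab + bc) / 2)
        assert res.stability["B"] == pytest.approx(0.69695, abs=1e-4)

    def test_identical_genes(self):
        m = make_matrix({"A": [30.0, 31], "B": [30.0, 31], "C": [28.0, 30]})
        res = delta_ct(m)
        assert res.pair_sd.at["A", "B"] == 0.0
        assert res.stability["A"] == res.stability["B"]

    def test_shift_invariance(self, rng):
        m = make_matrix({f"g{i}": list(rng.normal(30, 1, 6)) for i in range(4)})
        res1 = delta_ct(m)
        vals = {g: list(m.values.loc[g] + (3.0 if g == "g0" else 0.0)) for g in m.genes}
        res2 = delta_ct(make_matrix(vals))
        pd.testing.assert_series_equal(res1.stability, res2.stability, rtol=1e-9)

    def test_brute_force_oracle(self, rng):
        # independent double loop over every size up to 8 genes x 12 samples
        for k in range(2, 9):
            for n in range(2, 13):
                m = make_matrix({f"g{i}": list(rng.normal(30, 2, n)) for i in range(k)})
                res = delta_ct(m)
                genes = m.genes
                for g in genes:
                    acc = []
                    for h in genes:
                        if h == g:
                            continue
                        diffs = m.values.loc[g].to_numpy() - m.values.loc[h].to_numpy()
                        acc.append(np.std(diffs, ddof=1))
                    assert res.stability[g] == pytest.approx(np.mean(acc), rel=1e-12)

    def test_symmetry_and_diagonal(self, rng):
        m = make_matrix({f"g{i}": list(rng.normal(30, 1, 5)) for i in range(5)})
        res = delta_ct(m)
        np.testing.assert_allclose(res.pair_sd, res.pair_sd.T)
        np.testing.assert_allclose(np.diag(res.pair_sd), 0.0)

    def test_needs_two_genes(self):
        with pytest.raises(DomainError):
            delta_ct(make_matrix({"g1": [30.0, 31]}))


class TestLocationInvariance:
    """Per-gene constant Cq shifts leave every stability ordering unchanged."""

    def test_all_estimators(self, rng):
        groups = GROUPS_2x4
        vals = {f"g{i}": list(rng.normal(28 + i, 0.5, 8)) for i in range(5)}
        shifts = dict(zip(vals, rng.uniform(-4, 4, 5)))
        shifted = {g: list(np.array(v) + shifts[g]) for g, v in vals.items()}
        m1, m2 = (make_matrix(v, groups=groups) for v in (vals, shifted))

        assert genorm(to_relative_quantity(m1)).ranking() == genorm(
            to_relative_quantity(m2)
        ).ranking()
        assert normfinder(m1).ranking() == normfinder(m2).ranking()
        bk1, bk2 = bestkeeper(m1), bestkeeper(m2)
        np.testing.assert_allclose(bk1.stability, bk2.stability, rtol=1e-9)
        assert bk1.ranking() == bk2.ranking()
        assert delta_ct(m1).ranking() == delta_ct(m2).ranking()
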