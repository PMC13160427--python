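"""Metric suite: closed forms, brute-force oracles, invariances."""

import itertools
import time

import numpy as np
import pytest

import scdrl
from scdrl.data import LabelTable
from scdrl.metrics import (_quantile_discretize, _stump_balanced_accuracy,
                           block_score_matrix, dci_from_importance)


def lt(cols):
    """LabelTable from a list of per-factor label vectors."""
    return LabelTable.full(np.stack([np.asarray(c) for c in cols], axis=1))


class TestMacroF1:
    def test_perfect_and_inverted(self):
        y = np.array([0, 1, 0, 1])
        assert scdrl.macro_f1(y, y) == 1.0
        assert scdrl.macro_f1(y, 1 - y) == 0.0

    def test_hand_contingency(self):
        # F1(class 0) = 2/3, F1(class 1) = 4/5 -> macro 11/15
        true = [0, 0, 1, 1]
        pred = [0, 1, 1, 1]
        assert scdrl.macro_f1(true, pred) == pytest.approx(11 / 15)

    def test_absent_categories_excluded(self):
        # category 2 appears in neither vector and must not dilute the mean
        assert scdrl.macro_f1([0, 1], [0, 1]) == 1.0

    def test_empty_input(self):
        with pytest.raises(ValueError, match="empty"):
            scdrl.macro_f1([], [])


def brute_force_ari(a, b):
    """Pair-counting ARI straight from its definition."""
    n = len(a)
    same_a = np.equal.outer(a, a)
    same_b = np.equal.outer(b, b)
    iu = np.triu_indices(n, k=1)
    n11 = int((same_a[iu] & same_b[iu]).sum())
    n00 = int((~same_a[iu] & ~same_b[iu]).sum())
    n10 = int((same_a[iu] & ~same_b[iu]).sum())
    n01 = int((~same_a[iu] & same_b[iu]).sum())
    total = n * (n - 1) / 2
    index = n11
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = ((n11 + n10) + (n11 + n01)) / 2
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


class TestARI:
    def test_identical_partitions(self):
        a = np.array([0, 0, 1, 1, 2])
        assert scdrl.ari(a, a) == 1.0

    def test_permutation_invariance(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        relabeled = np.array([2, 2, 0, 0, 1, 1])
        assert scdrl.ari(a, relabeled) == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        assert scdrl.ari(a, b) == pytest.approx(brute_force_ari(a, b))
        for _ in range(5):
            x = rng.integers(0, 3, 30)
            y = rng.integers(0, 4, 30)
            assert scdrl.ari(x, y) == pytest.approx(brute_force_ari(x, y))

    def test_degenerate_single_cluster(self):
        assert scdrl.ari([0, 0, 0], [1, 1, 1]) == 1.0

    def test_empty_input(self):
        with pytest.raises(ValueError, match="empty"):
            scdrl.ari([], [])


class TestSpearmanMatrix:
    def test_perfect_monotone(self, rng):
        codes = rng.integers(0, 2, 500)
        Z = np.stack([codes.astype(float), -codes.astype(float)], axis=1)
        sp = scdrl.spearman_matrix(Z, lt([codes]))
        assert sp.integer_coded[0, 0] == pytest.approx(1.0)
        assert sp.integer_coded[1, 0] == pytest.approx(-1.0)
        assert sp.one_vs_rest[0, 0] == pytest.approx(1.0)

    def test_independent_dim_near_zero(self):
        rng = np.random.default_rng(8)
        n = 2000
        codes = rng.integers(0, 2, n)
        Z = np.stack([rng.normal(size=n), rng.normal(size=n)], axis=1)
        sp = scdrl.spearman_matrix(Z, lt([codes]))
        assert np.all(np.abs(sp.integer_coded[:, 0]) < 0.08)  # ~3/sqrt(n)

    def test_constant_dim_defined_zero(self, rng):
        codes = rng.integers(0, 2, 100)
        Z = np.stack([np.ones(100), codes.astype(float)], axis=1)
        sp = scdrl.spearman_matrix(Z, lt([codes]))
        assert sp.integer_coded[0, 0] == 0.0

    def test_one_vs_rest_order_free(self, rng):
        # a dim that isolates category 1 of a 3-class factor: the integer-coded
        # rho is diluted, the one-vs-rest statistic is not
        codes = np.array([0, 1, 2] * 200)
        Z = np.stack([(codes == 1).astype(float), rng.normal(size=600)], axis=1)
        sp = scdrl.spearman_matrix(Z, lt([codes]))
        assert sp.one_vs_rest[0, 0] > 0.9
        assert abs(sp.integer_coded[0, 0]) < 0.1


def brute_force_mi(x, y):
    """Mutual information (nats) from the exhaustive contingency table."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    mi = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy == 0:
                continue
            px, py = np.mean(x == xv), np.mean(y == yv)
            mi += pxy * np.log(pxy / (px * py))
    return mi


class TestMIG:
    def test_perfect_copy_latent(self, rng):
        codes = rng.integers(0, 2, 400)
        Z = np.stack([codes.astype(float), np.zeros(400)], axis=1)
        assert scdrl.mig(Z, lt([codes])) == pytest.approx(1.0)

    def test_copy_plus_noise_dim(self):
        rng = np.random.default_rng(3)
        n = 2000
        codes = rng.integers(0, 2, n)
        Z = np.stack([codes.astype(float), rng.normal(size=n)], axis=1)
        assert scdrl.mig(Z, lt([codes])) == pytest.approx(1.0, abs=0.05)

    def test_independent_latent_near_zero(self):
        rng = np.random.default_rng(4)
        n = 2000
        codes = rng.integers(0, 2, n)
        Z = rng.normal(size=(n, 4))
        assert scdrl.mig(Z, lt([codes])) < 0.05

    def test_matches_brute_force_mi_oracle(self):
        rng = np.random.default_rng(5)
        v = rng.integers(0, 3, 300)
        z0 = v + rng.integers(0, 2, 300) * 3  # informative but not a copy
        z1 = rng.integers(0, 4, 300)
        z2 = rng.integers(0, 2, 300)
        Z = np.stack([z0, z1, z2], axis=1).astype(float)
        mis = sorted((brute_force_mi(zc, v) for zc in Z.T), reverse=True)
        hv = brute_force_mi(v, v)  # H(v) = MI(v, v)
        expected = np.clip((mis[0] - mis[1]) / hv, 0, 1)
        # integer dims with <= n_bins distinct values survive discretization
        assert scdrl.mig(Z, lt([v])) == pytest.approx(expected, abs=1e-12)

    def test_single_category_factor_excluded(self, rng):
        Z = rng.normal(size=(50, 3))
        with pytest.raises(ValueError, match="multi-category"):
            scdrl.mig(Z, lt([np.zeros(50, dtype=int)]))

    def test_needs_two_dims(self, rng):
        with pytest.raises(ValueError, match="2 latent"):
            scdrl.mig(rng.normal(size=(50, 1)), lt([rng.integers(0, 2, 50)]))


class TestSAP:
    def test_identical_dims_give_zero(self, rng):
        z = rng.normal(size=200)
        Z = np.stack([z, z, z], axis=1)
        codes = (z > 0).astype(int)
        assert scdrl.sap(Z, lt([codes])) == 0.0

    def test_one_separating_dim(self):
        rng = np.random.default_rng(6)
        n = 2000
        codes = rng.integers(0, 2, n)
        sep = codes * 10.0 + rng.normal(size=n)  # ~perfectly separable
        Z = np.stack([sep, rng.normal(size=n), rng.normal(size=n)], axis=1)
        assert scdrl.sap(Z, lt([codes])) == pytest.approx(0.5, abs=0.05)

    def test_duplicated_best_dim_forces_zero_gap(self):
        rng = np.random.default_rng(7)
        n = 500
        codes = rng.integers(0, 2, n)
        sep = codes * 10.0 + rng.normal(size=n)
        Z = np.stack([sep, sep.copy(), rng.normal(size=n)], axis=1)
        assert scdrl.sap(Z, lt([codes])) == 0.0

    def test_stump_oracle_on_tiny_input(self):
        # best threshold on z=[1,2,3,4], y=[0,0,1,1] classifies perfectly
        assert _stump_balanced_accuracy(
            np.array([1.0, 2, 3, 4]), np.array([0.0, 0, 1, 1])) == 1.0
        # orientation flip: separator works with labels inverted too
        assert _stump_balanced_accuracy(
            np.array([1.0, 2, 3, 4]), np.array([1.0, 1, 0, 0])) == 1.0
        # uninformative constant dimension scores chance level
        assert _stump_balanced_accuracy(
            np.ones(4), np.array([0.0, 1, 0, 1])) == 0.5


class TestDCI:
    def test_identity_importance(self):
        dis, comp = dci_from_importance(np.eye(4))
        assert dis == 1.0 and comp == 1.0

    def test_uniform_importance(self):
        dis, comp = dci_from_importance(np.full((4, 4), 0.25))
        assert dis == pytest.approx(0.0, abs=1e-12)
        assert comp == pytest.approx(0.0, abs=1e-12)

    def test_hand_2x2_matrix(self):
        R = np.array([[0.9, 0.1], [0.1, 0.9]])
        h = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1)) / np.log(2)
        dis, comp = dci_from_importance(R)
        assert dis == pytest.approx(1 - h)
        assert comp == pytest.approx(1 - h)

    def test_single_dim_disentanglement_is_one(self):
        dis, _ = dci_from_importance(np.array([[0.5, 0.5]]))
        assert dis == 1.0

    def test_full_dci_on_injected_latent(self, rng):
        # one latent dim per factor plus noise -> near-ideal DCI; forest
        # impurity importances leak a few percent of mass to other dims, and
        # binary-normalized entropy punishes that leakage steeply
        n = 1500
        f1 = rng.integers(0, 2, n)
        f2 = rng.integers(0, 3, n)
        Z = np.stack([f1 + 0.01 * rng.normal(size=n),
                      f2 + 0.01 * rng.normal(size=n),
                      rng.normal(size=n)], axis=1)
        info, dis, comp = scdrl.dci(Z, lt([f1, f2]), seed=0)
        assert info > 0.95
        assert dis > 0.7
        assert comp > 0.65


class TestHungarian:
    def test_identity_and_permutation(self):
        assert scdrl.hungarian_alignment(np.eye(3)) == 1.0
        perm = np.eye(3)[:, [2, 0, 1]]
        assert scdrl.hungarian_alignment(perm) == 1.0

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            S = rng.uniform(size=(3, 3))
            best = max(
                np.mean([S[i, p[i]] for i in range(3)])
                for p in itertools.permutations(range(3))
            )
            assert scdrl.hungarian_alignment(S) == pytest.approx(best)

    def test_rectangular_more_blocks_than_factors(self, rng):
        S = np.array([[1.0, 0.0], [0.0, 1.0], [0.3, 0.3]])
        assert scdrl.hungarian_alignment(S) == 1.0

    def test_more_factors_than_blocks_rejected(self):
        with pytest.raises(ValueError, match="more factors"):
            scdrl.hungarian_alignment(np.ones((2, 3)) * 0.5)

    def test_score_range_enforced(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            scdrl.hungarian_alignment(np.array([[1.5]]))


class TestInvariances:
    def test_category_relabeling(self, rng):
        n = 600
        codes = rng.integers(0, 3, n)
        Z = np.stack([codes + 0.1 * rng.normal(size=n),
                      rng.normal(size=n)], axis=1)
        relabeled = np.array([2, 0, 1])[codes]  # permute category indices
        a, b = lt([codes]), lt([relabeled])
        assert scdrl.mig(Z, a) == pytest.approx(scdrl.mig(Z, b))
        assert scdrl.sap(Z, a) == pytest.approx(scdrl.sap(Z, b))
        assert scdrl.ari(codes, relabeled) == 1.0

    def test_latent_dim_permutation(self, rng):
        n = 600
        codes = rng.integers(0, 2, n)
        Z = np.stack([codes + 0.1 * rng.normal(size=n),
                      rng.normal(size=n), rng.normal(size=n)], axis=1)
        Zp = Z[:, [2, 0, 1]]
        t = lt([codes])
        assert scdrl.mig(Z, t) == pytest.approx(scdrl.mig(Zp, t))
        assert scdrl.sap(Z, t) == pytest.approx(scdrl.sap(Zp, t))


class TestOracleLatent:
    """Injecting the true factor codes as latent dims scores far above an
    entangled (randomly rotated) version of the same latent.

    Absolute ceilings differ per metric — ties cap Spearman of a binary
    factor at sqrt(3)/2, stumps cap multi-class one-vs-rest scores, forest
    importances leak mass — so the load-bearing check is the contrast."""

    def test_near_oracle_metrics(self, tiny_sim):
        from scipy.stats import ortho_group

        rng = np.random.default_rng(0)
        labs = tiny_sim.truth.labels
        n = labs.shape[0]
        noise = rng.normal(size=(n, 4))
        Z = np.hstack([labs.astype(float) + 0.01 * rng.normal(size=labs.shape),
                       noise])
        Z_mixed = Z @ ortho_group.rvs(Z.shape[1], random_state=0)
        truth = tiny_sim.truth
        cmap = {name: (j, j + 1) for j, name in enumerate(tiny_sim.spec.names)}
        cmap["residual"] = (4, 8)

        t0 = time.time()
        scores = {}
        for tag, z in (("oracle", Z), ("mixed", Z_mixed)):
            info, dis, comp = scdrl.dci(z, truth, seed=0)
            S = block_score_matrix(z, cmap, truth, tiny_sim.spec.names)
            scores[tag] = dict(mig=scdrl.mig(z, truth), sap=scdrl.sap(z, truth),
                               info=info, dis=dis, comp=comp,
                               hung=scdrl.hungarian_alignment(S))
        elapsed = time.time() - t0

        o, m = scores["oracle"], scores["mixed"]
        assert o["mig"] > 0.8
        assert o["info"] > 0.95
        for key in ("mig", "sap", "dis", "comp", "hung"):
            assert o[key] > m[key] + 0.3, f"{key}: {o[key]:.3f} vs {m[key]:.3f}"
        assert elapsed < 60.0  # full suite twice on 2000 cells stays interactive
        assert elapsed < 60.0  # full suite on 2000 cells stays interactive


def test_quantile_discretize_handles_constant_and_binary(rng):
    assert len(np.unique(_quantile_discretize(np.ones(100), 20))) == 1
    z = rng.integers(0, 2, 100).astype(float)
    assert len(np.unique(_quantile_discretize(z, 20))) == 2
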