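import numpy as np
import pytest
from scipy import stats as sps

from _oracles import exhaustive_backward, sur_lrt, univariate_lrt
from mtqtl import (DataError, backward_eliminate, effect_tests,
                   lrt_given_trivial, lrt_joint, scan_genome)
from mtqtl.io import GenotypeMatrix, PhenotypeMatrix
from mtqtl import core
from mtqtl.mtreg import ScanStatistics, SingularModelError


def _toy(seed, n=25, p=3, effect=0.8):
    rng = np.random.default_rng(seed)
    x = rng.choice([0.5, -0.5], n)
    A = rng.normal(size=(p, p))
    sigma = A @ A.T / p + 0.5 * np.eye(p)
    Y = rng.multivariate_normal(np.zeros(p), sigma, n)
    Y[:, 0] += effect * x
    return x, Y


@pytest.mark.parametrize("seed", [1, 2, 3])
@pytest.mark.parametrize("active", [(0,), (1,), (0, 1), (0, 2), (0, 1, 2)])
def test_lrt_joint_matches_sur_oracle(seed, active):
    """The closed-form LRT agrees with a brute-force constrained-MLE fit."""
    x, Y = _toy(seed)
    ours = lrt_joint(x, Y, active)
    oracle = sur_lrt(Y, x, set(active))
    assert ours == pytest.approx(oracle, rel=1e-8, abs=1e-8)


def test_lrt_joint_small_p2_case():
    x, Y = _toy(7, n=8, p=2)
    ours = lrt_joint(x, Y, (0, 1))
    oracle = sur_lrt(Y, x, {0, 1})
    assert ours == pytest.approx(oracle, rel=1e-8)


def test_monomorphic_locus_scores_zero():
    _, Y = _toy(4)
    x = np.full(Y.shape[0], 0.5)
    with pytest.warns(UserWarning, match="monomorphic"):
        assert lrt_joint(x, Y) == 0.0


def test_lrt_joint_input_validation():
    x, Y = _toy(5)
    with pytest.raises(DataError):
        lrt_joint(x, Y, ())
    with pytest.raises(DataError):
        lrt_joint(x, Y, (5,))
    with pytest.raises(SingularModelError):
        lrt_joint(x[:4], Y[:4])
    dup = np.column_stack([Y[:, 0], Y[:, 0]])
    with pytest.raises(SingularModelError):
        lrt_joint(x, dup)


@pytest.mark.parametrize("seed", [1, 5, 9])
@pytest.mark.parametrize("p", [3, 4])
def test_backward_elimination_matches_exhaustive_oracle(seed, p):
    x, Y = _toy(seed, n=30, p=p)
    best, order = backward_eliminate(x, Y)
    best_o, order_o = exhaustive_backward(Y, x)
    np.testing.assert_allclose(best, best_o, rtol=1e-8)
    assert list(order) == order_o


def test_backward_elimination_p1():
    x, Y = _toy(2, p=3)
    best, order = backward_eliminate(x, Y[:, :1])
    assert best.shape == (1,)
    assert best[0] == pytest.approx(lrt_joint(x, Y[:, :1], (0,)))
    assert list(order) == [0]


@pytest.mark.parametrize("seed", range(5))
def test_nestedness_and_monotonicity(seed):
    """Adding an effect never decreases the joint statistic; best-k sequences
    are nondecreasing."""
    x, Y = _toy(seed, n=35, p=4)
    best, _ = backward_eliminate(x, Y)
    assert np.all(np.diff(best) >= -1e-9)
    rng = np.random.default_rng(seed)
    small = set(rng.choice(4, size=2, replace=False).tolist())
    big = small | {int(rng.integers(4))}
    assert lrt_joint(x, Y, small) <= lrt_joint(x, Y, big) + 1e-9


def test_scan_genome_structure(small_data):
    geno, pheno, _ = small_data
    scan = scan_genome(geno, pheno)
    assert scan.stats.shape == (geno.n_markers, pheno.n_traits)
    assert np.all(scan.stats >= 0)
    assert np.all(np.diff(scan.stats, axis=1) >= -1e-9)
    # per-locus result equals the single-locus operation
    best1, order1 = backward_eliminate(geno.values[:, 1], pheno)
    np.testing.assert_allclose(scan.stats[1], best1, rtol=1e-10)
    assert list(scan.elimination_order[1]) == list(order1)


def test_scan_locus_order_equivariance(small_data):
    geno, pheno, _ = small_data
    perm = [2, 0, 3, 1]
    geno_p = GenotypeMatrix(geno.values[:, perm], geno.individuals,
                            tuple(geno.marker_id[i] for i in perm))
    scan = scan_genome(geno, pheno)
    scan_p = scan_genome(geno_p, pheno)
    np.testing.assert_allclose(scan_p.stats, scan.stats[perm], rtol=1e-12)


def test_effect_tests_identities(small_data):
    geno, pheno, _ = small_data
    eff = effect_tests(geno, pheno)
    p = pheno.n_traits
    for l in [0, 1]:
        x = geno.values[:, l]
        full = lrt_joint(x, pheno)
        for k in range(p):
            rest = tuple(j for j in range(p) if j != k)
            # effect given all others = difference of joint refits
            assert eff.indiv[l, k] == pytest.approx(full - lrt_joint(x, pheno, rest),
                                                    abs=1e-8)
            # ... which for this model equals the marginal univariate LRT
            assert eff.indiv[l, k] == pytest.approx(
                univariate_lrt(pheno.values[:, k], x), rel=1e-8)
            # effect alone, all others excluded, against the SUR oracle
            assert eff.single[l, k] == pytest.approx(
                sur_lrt(pheno.values, x, {k}), rel=1e-7, abs=1e-7)


def test_effect_tests_p1_coincide(small_data):
    geno, pheno, _ = small_data
    Y1 = PhenotypeMatrix(pheno.values[:, :1], pheno.trait_names[:1],
                         pheno.individuals)
    eff = effect_tests(geno, Y1)
    joint = lrt_joint(geno.values[:, 0], Y1)
    assert eff.indiv[0, 0] == pytest.approx(joint)
    assert eff.single[0, 0] == pytest.approx(joint)


def test_lrt_given_trivial_identities(small_data):
    geno, pheno, _ = small_data
    x = geno.values[:, 1]
    p = pheno.n_traits
    eff = effect_tests(geno, pheno)
    # empty trivial set: equals the individual-effect statistic
    assert lrt_given_trivial(x, pheno, 0, ()) == pytest.approx(eff.indiv[1, 0],
                                                               abs=1e-9)
    # trivial set = everything else: equals the single-effect statistic
    assert lrt_given_trivial(x, pheno, 2, (0, 1)) == pytest.approx(
        eff.single[1, 2], abs=1e-9)
    # general case equals the difference of two joint refits
    got = lrt_given_trivial(x, pheno, 1, (2,))
    expect = lrt_joint(x, pheno, (0, 1)) - lrt_joint(x, pheno, (0,))
    assert got == pytest.approx(expect, abs=1e-9)
    with pytest.raises(DataError):
        lrt_given_trivial(x, pheno, 1, (1, 2))


def test_null_distribution_chisquare():
    """Under no QTL the joint LRT for k effects is asymptotically chi2_k."""
    rng = np.random.default_rng(42)
    n, p, reps = 200, 4, 600
    t_full = np.empty(reps)
    t_one = np.empty(reps)
    for i in range(reps):
        x = rng.choice([0.5, -0.5], n)
        Y = rng.normal(size=(n, p))
        ws = core.workspace_for_loci(Y, x[:, None])
        t_full[i] = ws.full_stat()[0]
        t_one[i] = ws.active_set_stat(np.array([0]))[0]
    for t, df in ((t_full, p), (t_one, 1)):
        q95 = np.quantile(t, 0.95)
        assert q95 == pytest.approx(sps.chi2.ppf(0.95, df), rel=0.12)


def test_scan_statistics_invariants():
    with pytest.raises(DataError, match="non-negative"):
        ScanStatistics(np.array([[-1.0, 2.0]]), np.array([[0, 1]]), ("m",))
    with pytest.raises(DataError, match="nondecreasing"):
        ScanStatistics(np.array([[3.0, 2.0]]), np.array([[0, 1]]), ("m",))
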