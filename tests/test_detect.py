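import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mtqtl import (DataError, RunConfig, all_detect, bicdelta_detect,
                   estimate_thresholds, indv_detect, mbp_detect, scan_genome,
                   seq_detect, select_k0, simulate_traits)
from mtqtl.detect import BootstrapFrequency, DetectionResult
from mtqtl.io import PhenotypeMatrix
from mtqtl.mtreg import ScanStatistics, effect_tests
from mtqtl.thresholds import ThresholdSet


def _thresholds(p, lam, tau=10.0, penalty=10.0):
    lam = np.asarray(lam, dtype=float)
    return ThresholdSet(lam, lam, 0.05, tau, lam.copy(), penalty, {}, 0.05, 100, 0)


def _scan(stats):
    stats = np.atleast_2d(np.asarray(stats, dtype=float))
    L, p = stats.shape
    order = np.tile(np.arange(p), (L, 1))
    return ScanStatistics(stats, order, tuple(f"m{i+1}" for i in range(L)))


def test_select_k0_rules():
    assert select_k0(np.array([[0.1, 0.2, 0.3, 0.9, 0.3]]))[0] == 4
    # tie between k=2 and k=5 -> floor((2+5)/2) = 3
    assert select_k0(np.array([[0.1, 0.9, 0.3, 0.4, 0.9]]))[0] == 3
    # full tie over k=1..p -> floor((1+p)/2)
    assert select_k0(np.ones((1, 8)))[0] == 4
    assert select_k0(np.ones((1, 5)))[0] == 3


@settings(deadline=None, derandomize=True)
@given(hnp.arrays(float, st.tuples(st.integers(1, 6), st.integers(1, 8)),
                  elements=st.floats(0, 1, width=16)))
def test_select_k0_matches_tie_rule_reference(fk):
    """For arbitrary frequency tables the selected count obeys the stated
    rule: the unique argmax, or the integer midpoint of tied maximizers."""
    got = select_k0(fk)
    for row, k0 in zip(np.atleast_2d(fk), got):
        ties = [k + 1 for k, v in enumerate(row) if v >= row.max() - 1e-12]
        assert k0 == (ties[0] + ties[-1]) // 2
        assert 1 <= k0 <= len(row)


def test_all_detect_strict_boundary():
    scan = _scan([[1.0, 5.0], [1.0, 4.0]])
    thr = _thresholds(2, [3.0, 5.0])
    res = all_detect(scan, thr)
    # statistic equal to the threshold is NOT a claim
    assert res.claimed.tolist() == [False, False]
    thr2 = _thresholds(2, [3.0, 4.5])
    res2 = all_detect(scan, thr2)
    assert res2.claimed.tolist() == [True, False]
    assert res2.trait_sets[0] == (0, 1)


def test_indv_detect_claims_exceeding_traits():
    class Eff:
        indiv = np.array([[1.0, 2.0], [1.0, 12.0]])
        marker_id = ("m1", "m2")

    res = indv_detect(Eff(), tau_alpha=10.0)
    assert res.claimed.tolist() == [False, True]
    assert res.trait_sets[1] == (1,)
    none = indv_detect(Eff(), tau_alpha=100.0)
    assert not none.any_claim


def test_seq_detect_first_significant_step(null_data):
    geno, pheno = null_data
    scan = scan_genome(geno, pheno)
    huge = np.full(pheno.n_traits, 1e6)
    assert not seq_detect(geno, pheno, huge, scan=scan).any_claim
    tiny = np.full(pheno.n_traits, 1e-6)
    res = seq_detect(geno, pheno, tiny, scan=scan)
    assert res.claimed.all()
    # with every step significant, the claim happens at the full model
    assert (res.k0 == pheno.n_traits).all()


def test_seq_p1_equivalent_to_all(null_data):
    geno, pheno = null_data
    Y1 = PhenotypeMatrix(pheno.values[:, :1], pheno.trait_names[:1],
                         pheno.individuals)
    scan = scan_genome(geno, Y1)
    thr = _thresholds(1, [scan.stats.max() * 0.5])
    res_all = all_detect(scan, thr)
    res_seq = seq_detect(geno, Y1, thr.seq_thresholds, scan=scan)
    np.testing.assert_array_equal(res_all.claimed, res_seq.claimed)


def test_bicdelta_penalty_extremes(null_data):
    geno, pheno = null_data
    scan = scan_genome(geno, pheno)
    assert not bicdelta_detect(geno, pheno, 1e9, scan=scan).any_claim
    with pytest.warns(UserWarning, match="penalty"):
        res = bicdelta_detect(geno, pheno, 0.0, scan=scan)
    assert res.claimed.all()
    # model choice: claimed locus retains the criterion-optimal set
    res2 = bicdelta_detect(geno, pheno, 1e-6, scan=scan)
    ks = np.arange(1, pheno.n_traits + 1)
    for l in range(scan.n_loci):
        expect = np.argmax(scan.stats[l] - ks * 1e-6) + 1
        assert res2.k0[l] == expect


def test_mbp_detect_workflow(small_data):
    geno, pheno, spec = small_data
    cfg = RunConfig(alpha=0.1, n_permutations=80, n_bootstrap=40, seed=21)
    thr = estimate_thresholds(geno, pheno, cfg)
    res, bf = mbp_detect(geno, pheno, thr, B=40, seed=22)
    assert bf.fk.shape == (geno.n_markers, pheno.n_traits)
    assert np.all((bf.fk >= 0) & (bf.fk <= 1))
    assert np.all((bf.k0 >= 1) & (bf.k0 <= pheno.n_traits))
    # claim uses the original best-k0 statistic against lambda_k0(alpha)
    scan = scan_genome(geno, pheno)
    l = np.arange(geno.n_markers)
    np.testing.assert_allclose(res.statistic, scan.stats[l, bf.k0 - 1])
    np.testing.assert_allclose(res.threshold, thr.lambda_alpha[bf.k0 - 1])
    # the simulated QTL at m2 carries a strong effect: detected
    assert res.claimed[1]
    assert 1 in res.trait_sets[1]  # the affected trait is kept nontrivial


def test_mbp_determinism(small_data):
    geno, pheno, _ = small_data
    cfg = RunConfig(alpha=0.1, n_permutations=60, n_bootstrap=30, seed=2)
    thr = estimate_thresholds(geno, pheno, cfg)
    r1, b1 = mbp_detect(geno, pheno, thr, B=30, seed=8)
    r2, b2 = mbp_detect(geno, pheno, thr, B=30, seed=8)
    np.testing.assert_array_equal(b1.fk, b2.fk)
    np.testing.assert_array_equal(r1.claimed, r2.claimed)


def test_mbp_input_validation(small_data):
    geno, pheno, _ = small_data
    thr = _thresholds(5, np.ones(5))  # wrong trait count
    with pytest.raises(DataError, match="trait count"):
        mbp_detect(geno, pheno, thr, B=10, seed=0)
    thr3 = _thresholds(3, np.ones(3))
    with pytest.raises(DataError, match="bootstrap"):
        mbp_detect(geno, pheno, thr3, B=0, seed=0)


def test_detection_result_invariant():
    with pytest.raises(DataError, match="claimed"):
        DetectionResult("x", ("m1",), np.array([True]), np.array([1.0]),
                        np.array([2.0]), np.array([1]), ((0,),))


def test_bootstrap_frequency_invariants():
    with pytest.raises(DataError):
        BootstrapFrequency(np.array([[1.2]]), np.array([1]), 10)
    with pytest.raises(DataError):
        BootstrapFrequency(np.array([[0.5]]), np.array([2]), 10)
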