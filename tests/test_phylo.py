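"""Tree handling, the lambda model, and BM ancestral states."""

import numpy as np
import pytest
from scipy.optimize import minimize

from tubetask import asr_bm, fit_lambda, lambda_transform, simulate_tree
from tubetask.phylo import Phylogeny, TreeError
from tubetask.simulate import simulate_species_effects


def test_parse_basic():
    t = Phylogeny.from_newick("(A:1,B:1);")
    assert sorted(t.tips) == ["A", "B"]
    assert len(t) == 2


def test_parse_error():
    with pytest.raises(TreeError):
        Phylogeny.from_newick("((A:1,B:1;")


def test_round_trip_random_trees():
    for seed in (1, 2, 3):
        t = simulate_tree(12, seed=seed)
        back = Phylogeny.from_newick(t.to_newick())
        assert sorted(back.tips) == sorted(t.tips)
        np.testing.assert_allclose(back.vcv(sorted(t.tips)),
                                   t.vcv(sorted(t.tips)), atol=1e-9)


def test_vcv_three_tips(three_tip_tree):
    C = three_tip_tree.vcv(["A", "B", "C"])
    np.testing.assert_allclose(C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])


def test_vcv_permutation_consistency(three_tip_tree):
    C1 = three_tip_tree.vcv(["A", "B", "C"])
    C2 = three_tip_tree.vcv(["C", "A", "B"])
    perm = [2, 0, 1]  # position of C,A,B within A,B,C
    np.testing.assert_allclose(C2, C1[np.ix_(perm, perm)])


def test_vcv_unknown_tip(three_tip_tree):
    with pytest.raises(TreeError):
        three_tip_tree.vcv(["A", "Z"])


def test_mrca(three_tip_tree):
    assert three_tip_tree.mrca(["A", "B"]) == "node1"
    assert three_tip_tree.mrca(["A", "B", "C"]) == "node0"
    assert three_tip_tree.mrca(["A"]) == "A"
    with pytest.raises(TreeError):
        three_tip_tree.mrca([])


def test_substitute_tips_preserves_vcv(three_tip_tree):
    renamed = three_tip_tree.substitute_tips({"A": "A2"})
    np.testing.assert_allclose(renamed.vcv(["A2", "B", "C"]),
                               three_tip_tree.vcv(["A", "B", "C"]))
    with pytest.raises(TreeError):
        three_tip_tree.substitute_tips({"Z": "Q"})


def test_graft_tip_ultrametric():
    t = Phylogeny.from_newick("(A:2,B:2);")
    g = t.graft_tip("C", sister="B", divergence_time=1.0)
    assert sorted(g.tips) == ["A", "B", "C"]
    assert g.is_ultrametric()
    C = g.vcv(["B", "C"])
    assert C[0, 1] == pytest.approx(1.0)  # split 1 time unit before present
    assert C[0, 0] == pytest.approx(2.0)


def test_graft_infeasible_divergence():
    t = Phylogeny.from_newick("(A:2,B:2);")
    with pytest.raises(TreeError):
        t.graft_tip("C", sister="B", divergence_time=3.0)


@pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
def test_lambda_transform(three_tip_tree, lam):
    C = three_tip_tree.vcv(["A", "B", "C"])
    T = lambda_transform(C, lam)
    np.testing.assert_allclose(np.diag(T), np.diag(C))
    assert T[0, 1] == pytest.approx(lam * C[0, 1])


def test_lambda_transform_rejects_out_of_range(three_tip_tree):
    C = three_tip_tree.vcv(["A", "B", "C"])
    with pytest.raises(ValueError):
        lambda_transform(C, 1.5)


def test_fit_lambda_recovers_bm(big_tree):
    """Traits simulated under pure BM yield lambda-hat near 1."""
    hits = 0
    for rep in range(20):
        x = simulate_species_effects(big_tree, 1.0, 1.0, seed=500 + rep)
        if fit_lambda(x, big_tree).lambda_hat > 0.9:
            hits += 1
    assert hits >= 18


def test_fit_lambda_iid_trait_near_zero(big_tree):
    hits = 0
    for rep in range(20):
        x = simulate_species_effects(big_tree, 0.0, 1.0, seed=900 + rep)
        fit = fit_lambda(x, big_tree)
        if fit.lambda_hat < 0.1:
            hits += 1
    assert hits >= 18


def test_lambda_zero_gives_lrt_p_one(big_tree):
    x = simulate_species_effects(big_tree, 0.0, 1.0, seed=4242)
    fit = fit_lambda(x, big_tree)
    if fit.lambda_hat == 0.0:  # the typical outcome for iid data
        assert fit.lrt_stat == pytest.approx(0.0, abs=1e-8)
        assert fit.p == pytest.approx(1.0)


def test_fit_lambda_affine_invariance(big_tree):
    x = simulate_species_effects(big_tree, 0.7, 1.0, seed=77)
    fit1 = fit_lambda(x, big_tree)
    fit2 = fit_lambda({k: 3.0 * v - 5.0 for k, v in x.items()}, big_tree)
    assert fit2.lambda_hat == pytest.approx(fit1.lambda_hat, abs=1e-4)
    assert fit2.lrt_stat == pytest.approx(fit1.lrt_stat, abs=1e-6)


def test_fit_lambda_optimum_beats_endpoints(big_tree):
    from tubetask.phylo import _profile_loglik
    x = simulate_species_effects(big_tree, 0.5, 1.0, seed=31)
    fit = fit_lambda(x, big_tree)
    C = big_tree.vcv(sorted(x))
    xv = np.array([x[k] for k in sorted(x)])
    assert fit.loglik >= _profile_loglik(xv, C, 0.0)[0] - 1e-8
    assert fit.loglik >= _profile_loglik(xv, C, 1.0)[0] - 1e-8


def test_fit_lambda_star_tree_flat_warning():
    star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1);")
    x = {"A": 0.1, "B": -0.4, "C": 0.3, "D": 0.0, "E": 0.7}
    with pytest.warns(UserWarning, match="flat"):
        fit = fit_lambda(x, star)
    assert fit.flat_surface


def test_fit_lambda_constant_trait_rejected(big_tree):
    with pytest.raises(ValueError, match="constant"):
        fit_lambda({t: 1.0 for t in big_tree.tips}, big_tree)


def test_asr_two_tip_symmetry(cherry_tree):
    est = asr_bm({"A": 0.4, "B": 0.8}, cherry_tree)
    assert est["node0"].estimate == pytest.approx(0.6)


def test_asr_constant_trait(three_tip_tree):
    est = asr_bm({"A": 0.3, "B": 0.3, "C": 0.3}, three_tip_tree)
    for e in est.values():
        assert e.estimate == pytest.approx(0.3)


def test_asr_matches_brute_force_joint_likelihood():
    """Node estimates equal direct numerical optimization of the joint BM
    likelihood over all internal states."""
    tree = simulate_tree(5, seed=9)
    vals = dict(zip(sorted(tree.tips), [0.2, 0.8, 0.5, -0.3, 1.1]))
    est = asr_bm(vals, tree)
    edges = tree.edges()
    internal = list(dict.fromkeys(p for p, _, _ in edges))

    def neg_joint_ll(z):
        states = {**vals, **dict(zip(internal, z))}
        return sum((states[c] - states[p]) ** 2 / (2 * l) for p, c, l in edges)

    res = minimize(neg_joint_ll, np.zeros(len(internal)), method="BFGS",
                   options={"gtol": 1e-12})
    for node, val in zip(internal, res.x):
        assert est[node].estimate == pytest.approx(val, abs=1e-5)


def test_asr_root_equals_gls_mean():
    tree = simulate_tree(30, seed=21)
    x = simulate_species_effects(tree, 1.0, 0.5, seed=22)
    est = asr_bm(x, tree)
    C = tree.vcv(sorted(x))
    xv = np.array([x[k] for k in sorted(x)])
    ones = np.ones_like(xv)
    iC = np.linalg.inv(C)
    gls_mean = (ones @ iC @ xv) / (ones @ iC @ ones)
    assert est[tree.root_label].estimate == pytest.approx(gls_mean, abs=1e-8)


def test_asr_affine_equivariance():
    tree = simulate_tree(8, seed=33)
    x = simulate_species_effects(tree, 1.0, 0.5, seed=34)
    est1 = asr_bm(x, tree)
    est2 = asr_bm({k: 2.0 * v + 1.0 for k, v in x.items()}, tree)
    for node in est1:
        assert est2[node].estimate == pytest.approx(
            2.0 * est1[node].estimate + 1.0, abs=1e-8)


def test_asr_variances_positive():
    tree = simulate_tree(10, seed=35)
    x = simulate_species_effects(tree, 1.0, 0.5, seed=36)
    est = asr_bm(x, tree)
    assert all(e.variance > 0 for e in est.values())
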