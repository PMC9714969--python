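"""The synthetic-study generator and its ground truth."""

import numpy as np
import pytest

from tubetask import (
    SimConfig,
    filter_subjects,
    generate_study,
    score_subjects,
    simulate_species_effects,
    simulate_tree,
    summarize_by,
)
from tubetask.simulate import simulate_individuals


def test_tree_basic_properties():
    t = simulate_tree(38, seed=1)
    assert len(t) == 38
    assert t.is_ultrametric(rel_tol=1e-9)
    assert t.height() == pytest.approx(1.0)


def test_tree_seed_determinism():
    assert simulate_tree(25, seed=9).to_newick() == simulate_tree(25, seed=9).to_newick()
    assert simulate_tree(25, seed=9).to_newick() != simulate_tree(25, seed=10).to_newick()


def test_tree_two_tips_is_cherry():
    t = simulate_tree(2, seed=3)
    assert len(t) == 2
    with pytest.raises(ValueError):
        simulate_tree(1, seed=3)


def test_species_effects_zero_variance_constant():
    t = simulate_tree(10, seed=4)
    x = simulate_species_effects(t, 0.5, 0.0, seed=5)
    assert len(set(x.values())) == 1


def test_species_effects_sisters_correlate_under_bm():
    """Under BM the empirical covariance of two tips tracks their shared
    branch length: sisters co-vary, distant pairs do not."""
    t = simulate_tree(12, seed=6)
    tips = sorted(t.tips)
    C = t.vcv(tips)
    off = C - np.diag(np.diag(C))
    i, j = np.unravel_index(np.argmax(off), C.shape)  # closest pair
    a, b = np.unravel_index(np.argmin(C + np.eye(len(tips)) * 9), C.shape)
    close, far = [], []
    for rep in range(400):
        x = simulate_species_effects(t, 1.0, 1.0, seed=10_000 + rep)
        v = [x[s] for s in tips]
        close.append(v[i] * v[j])
        far.append(v[a] * v[b])
    assert np.mean(close) == pytest.approx(C[i, j], abs=0.25)
    assert np.mean(far) == pytest.approx(C[a, b], abs=0.25)
    assert np.mean(close) > np.mean(far)


def test_species_effects_lambda_zero_diagonal_covariance():
    t = simulate_tree(8, seed=7)
    tips = sorted(t.tips)
    draws = np.array(
        [[simulate_species_effects(t, 0.0, 1.0, seed=20_000 + rep)[s] for s in tips]
         for rep in range(500)]
    )
    emp = np.cov(draws.T)
    off_diag = emp - np.diag(np.diag(emp))
    assert np.abs(off_diag).max() < 0.2
    assert np.diag(emp).mean() == pytest.approx(1.0, abs=0.25)


def test_individuals_symmetric_null():
    cfg = SimConfig(n_species=6, seed=8)
    t = simulate_tree(6, seed=8)
    mu = {s: 0.0 for s in t.tips}
    tau = {s: 0.0 for s in t.tips}
    subjects, p = simulate_individuals(mu, tau, cfg)
    assert set(p.values()) == {0.5}
    scores = score_subjects(subjects)
    cohort_mean = np.mean([r.hi for r in scores])
    assert cohort_mean == pytest.approx(0.0, abs=0.05)


def test_individuals_insertions_within_range():
    cfg = SimConfig(n_species=6, seed=9)
    t = simulate_tree(6, seed=9)
    mu = {s: 0.0 for s in t.tips}
    tau = {s: 1.0 for s in t.tips}
    subjects, _ = simulate_individuals(mu, tau, cfg)
    for s in subjects:
        assert 30 <= s.total_insertions <= 155
        assert s.bouts >= 6


def test_large_tau_gives_strong_lateralization():
    """A wide within-species spread of preference probabilities pushes
    nearly every subject away from p = 0.5, mimicking strongly lateralized
    species such as langurs or spider monkeys."""
    cfg = SimConfig(n_species=5, seed=11)
    t = simulate_tree(5, seed=11)
    mu = {s: 0.0 for s in t.tips}
    subjects, _ = simulate_individuals(mu, {s: 6.0 for s in t.tips}, cfg)
    scores = score_subjects(subjects)
    summaries = summarize_by(subjects, scores)
    assert all(s.mean_abs_hi > 0.7 for s in summaries)
    assert np.mean([s.mean_abs_hi for s in summaries]) > 0.8


def test_strength_monotone_in_tau():
    cfg = SimConfig(n_species=5, seed=11, n_ind_range=(60, 60))
    t = simulate_tree(5, seed=11)
    mu = {s: 0.0 for s in t.tips}
    means = []
    for tau in (0.25, 0.75, 1.5, 3.0):
        subjects, _ = simulate_individuals(mu, {s: tau for s in t.tips}, cfg,
                                           seed=1234)
        scores = score_subjects(subjects)
        means.append(np.mean([r.abs_hi for r in scores]))
    assert means == sorted(means)


def test_generate_study_passes_filters_and_counts():
    cfg = SimConfig(n_species=10, seed=12, n_ind_range=(25, 25))
    dataset, truth = generate_study(cfg)
    assert len(dataset.subjects) == 250
    assert len(filter_subjects(dataset.subjects)) == len(dataset.subjects)
    assert sorted(truth.species) == sorted(dataset.tree.tips)
    assert len(dataset.predictors) == 10
    assert set(truth.mu) == set(truth.species)


def test_generate_study_reproducible():
    cfg = SimConfig(n_species=8, seed=13)
    d1, t1 = generate_study(cfg)
    d2, t2 = generate_study(cfg)
    assert t1.tree_newick == t2.tree_newick
    assert [s.right_insertions for s in d1.subjects] == [
        s.right_insertions for s in d2.subjects]
    assert t1.mu == t2.mu


def test_ecology_injection_shifts_strength():
    """A negative terrestrial effect on latent spread lowers terrestrial
    species' mean |HI| in expectation."""
    gaps = []
    for rep in range(30):
        cfg = SimConfig(n_species=24, seed=300 + rep, n_ind_range=(25, 25),
                        beta_ecology_strength=-1.0, p_terrestrial=0.5,
                        sigma2_strength=0.05)
        dataset, truth = generate_study(cfg)
        scores = score_subjects(dataset.subjects)
        summaries = summarize_by(dataset.subjects, scores)
        terr = [s.mean_abs_hi for s in summaries
                if truth.ecology[s.group_id] == "terrestrial"]
        arb = [s.mean_abs_hi for s in summaries
               if truth.ecology[s.group_id] == "arboreal"]
        if terr and arb:
            gaps.append(np.mean(arb) - np.mean(terr))
    assert np.mean(gaps) > 0.05


def test_heritable_strength_detected_end_to_end():
    """With heritable strength (lambda 0.9) and unheritable direction
    (lambda 0) — the structure seen in the real data — the fitted signal on
    species MeanAbsHI is strong while MeanHI shows none.  Binomial sampling
    noise attenuates the strength estimate somewhat below its latent value."""
    from tubetask import fit_lambda

    strength_l, direction_l = [], []
    for rep in range(20):
        cfg = SimConfig(seed=5000 + rep)
        ds, truth = generate_study(cfg)
        summ = summarize_by(ds.subjects, score_subjects(ds.subjects))
        strength_l.append(
            fit_lambda({s.group_id: s.mean_abs_hi for s in summ}, ds.tree).lambda_hat)
        direction_l.append(
            fit_lambda({s.group_id: s.mean_hi for s in summ}, ds.tree).lambda_hat)
    assert np.median(strength_l) > 0.5
    assert np.median(direction_l) < 0.3


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(lambda_strength=1.5)
    with pytest.raises(ValueError):
        SimConfig(n_ind_range=(10, 5))
    with pytest.raises(ValueError):
        SimConfig(sigma2_direction=-1.0)
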