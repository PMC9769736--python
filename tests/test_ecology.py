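"""Diversity, Bray-Curtis, PCoA, PERMANOVA, rarefaction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from magcat import (PCoA, alpha_diversity, bray_curtis, diversity_comparison,
                    permanova, rarefaction)


def test_shannon_uniform_closed_form():
    for S in (2, 5, 17):
        X = np.full((1, S), 1.0 / S)
        assert alpha_diversity(X, "shannon").iloc[0] == pytest.approx(np.log(S), abs=1e-12)


def test_simpson_single_species_zero():
    X = np.array([[7.0, 0.0, 0.0]])
    assert alpha_diversity(X, "simpson").iloc[0] == 0.0


def test_shannon_hand_computed_toy():
    p = np.array([0.5, 0.3, 0.2])
    expect = -(p * np.log(p)).sum()
    assert alpha_diversity(p[None, :], "shannon").iloc[0] == pytest.approx(expect, abs=1e-12)


def test_alpha_rejects_all_zero_sample():
    with pytest.raises(ValueError, match="zero total"):
        alpha_diversity(np.array([[0.0, 0.0]]), "shannon")


def test_bray_curtis_identical_and_disjoint():
    X = np.array([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 4]], dtype=float)
    D = bray_curtis(X).to_numpy()
    assert D[0, 1] == 0.0
    assert D[0, 2] == 1.0
    assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)


def test_bray_curtis_hand_computed_3x3():
    X = np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0], [0.0, 1.0, 5.0]])
    D = bray_curtis(X).to_numpy()
    for i, j in itertools.combinations(range(3), 2):
        expect = np.abs(X[i] - X[j]).sum() / (X[i] + X[j]).sum()
        assert D[i, j] == pytest.approx(expect, abs=1e-12)


def test_bray_curtis_two_empty_samples_error():
    with pytest.raises(ValueError):
        bray_curtis(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))


def test_pcoa_recovers_planar_distances(rng):
    pts = rng.normal(size=(12, 2))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    est = PCoA().fit(pd.DataFrame(D))
    C = est.coordinates_.to_numpy()
    D_hat = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
    assert np.allclose(D_hat, D, atol=1e-9)
    # coordinates are centered and axes ordered by decreasing eigenvalue
    assert np.allclose(C.mean(axis=0), 0, atol=1e-9)
    assert np.all(np.diff(est.eigenvalues_) <= 1e-9)
    assert est.proportion_explained_[0] >= est.proportion_explained_[1]


def test_pcoa_simplex_symmetry():
    n = 5
    D = np.ones((n, n)) - np.eye(n)
    est = PCoA().fit(pd.DataFrame(D))
    pos = est.eigenvalues_[est.eigenvalues_ > 1e-10]
    assert np.allclose(pos, pos[0])


def test_pcoa_matches_skbio(rng):
    skbio = pytest.importorskip("skbio")
    X = rng.lognormal(size=(10, 6))
    D = bray_curtis(X).to_numpy()
    ours = PCoA().fit(pd.DataFrame(D))
    theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
    n_pos = ours.coordinates_.shape[1]
    ev_theirs = np.sort(theirs.eigvals.to_numpy())[::-1][:n_pos]
    assert np.allclose(np.sort(ours.eigenvalues_)[::-1][:n_pos], ev_theirs, atol=1e-8)
    for ax in range(2):
        a = ours.coordinates_.to_numpy()[:, ax]
        b = theirs.samples.to_numpy()[:, ax]
        assert np.allclose(np.abs(a), np.abs(b), atol=1e-6)  # up to reflection


def test_pcoa_too_few_samples():
    with pytest.raises(ValueError):
        PCoA().fit(pd.DataFrame(np.zeros((2, 2))))


def _shifted_groups(rng, n_per=10, shift=2.0, n_sp=12):
    a = rng.lognormal(mean=0.0, size=(n_per, n_sp))
    b = rng.lognormal(mean=0.0, size=(n_per, n_sp))
    b[:, : n_sp // 3] *= np.exp(shift)
    X = np.vstack([a, b])
    labels = ["A"] * n_per + ["B"] * n_per
    return X, labels


def test_permanova_separated_groups_significant(rng):
    X, labels = _shifted_groups(rng, shift=3.0)
    res = permanova(bray_curtis(X), labels, n_perm=199, seed=1)
    assert res.p_value <= 0.02
    assert 0 < res.r2 < 1
    assert res.p_value >= 1 / 200  # add-one estimator floor


def test_permanova_deterministic_under_seed(rng):
    X, labels = _shifted_groups(rng)
    D = bray_curtis(X)
    r1 = permanova(D, labels, n_perm=99, seed=42)
    r2 = permanova(D, labels, n_perm=99, seed=42)
    assert r1 == r2


def test_permanova_degenerate_inputs(rng):
    X, _ = _shifted_groups(rng)
    D = bray_curtis(X)
    with pytest.raises(ValueError):
        permanova(D, ["A"] * 20)
    with pytest.raises(ValueError):
        permanova(D, ["A"] + ["B"] * 19)


def test_permanova_extreme_block_distances_r2_near_one():
    n_per = 10
    D = np.ones((2 * n_per, 2 * n_per))
    D[:n_per, :n_per] = 0
    D[n_per:, n_per:] = 0
    np.fill_diagonal(D, 0)
    res = permanova(pd.DataFrame(D), ["A"] * n_per + ["B"] * n_per,
                    n_perm=99, seed=0)
    assert res.r2 > 0.9


def test_permanova_matches_skbio_statistic(rng):
    skbio = pytest.importorskip("skbio")
    X, labels = _shifted_groups(rng)
    D = bray_curtis(X)
    ours = permanova(D, labels, n_perm=99, seed=0)
    theirs = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(D.to_numpy()), grouping=labels, permutations=99)
    assert ours.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-10)


def test_rarefaction_flat_when_all_species_everywhere():
    pres = pd.DataFrame(np.ones((6, 9), dtype=bool))
    curve = rarefaction(pres, n_perm=5, seed=0)
    assert (curve["mean_species"] == 9).all()


def test_rarefaction_endpoint_and_monotone(rng):
    pres = pd.DataFrame(rng.random((8, 20)) < 0.4)
    curve = rarefaction(pres, n_perm=50, seed=1)
    total = int((pres.sum(axis=0) > 0).sum())
    assert curve["mean_species"].iloc[-1] == total
    assert (np.diff(curve["mean_species"]) >= -1e-12).all()


def test_rarefaction_sampled_matches_exhaustive_4_samples(rng):
    pres = pd.DataFrame(rng.random((4, 15)) < 0.5)
    P = pres.to_numpy()
    exact = np.zeros(4)
    perms = list(itertools.permutations(range(4)))
    for order in perms:
        seen = np.cumsum(P[list(order)], axis=0) > 0
        exact += seen.sum(axis=1)
    exact /= len(perms)
    curve = rarefaction(pres, n_perm=2000, seed=3)
    assert np.allclose(curve["mean_species"], exact, atol=0.3)


def test_diversity_comparison_two_sided(rng):
    X = rng.lognormal(size=(12, 10))
    groups = pd.Series(["A"] * 6 + ["B"] * 6,
                       index=[f"s{i}" for i in range(12)])
    Xdf = pd.DataFrame(X, index=groups.index)
    out = diversity_comparison(Xdf, groups, "shannon")
    assert len(out) == 1 and 0 < out["p_value"].iloc[0] <= 1


def test_alpha_and_bray_invariant_to_species_order(rng):
    X = pd.DataFrame(rng.lognormal(size=(6, 8)),
                     columns=[f"sp{j}" for j in range(8)])
    perm = X[list(X.columns[::-1])]
    pd.testing.assert_series_equal(alpha_diversity(X, "shannon"),
                                   alpha_diversity(perm, "shannon"))
    assert np.allclose(bray_curtis(X).to_numpy(), bray_curtis(perm).to_numpy())
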