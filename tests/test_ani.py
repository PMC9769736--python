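"""k-mer ANI estimation and greedy dereplication."""

import itertools

import numpy as np
import pandas as pd
import pytest

from magcat import (GreedyANIClusterer, SimulationConfig, catalog_overlap,
                    cluster_genomes, dereplicate, estimate_ani, kmer_set,
                    pairwise_ani, simulate_genomes)

BASES = np.array(list("ACGT"))
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate(seq, rate, rng):
    arr = np.array(list(seq))
    pos = np.where(rng.random(len(arr)) < rate)[0]
    for p in pos:
        arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
    return "".join(arr)


def test_identical_sequences_give_100(rng):
    s = random_seq(rng, 2000)
    est = estimate_ani(s, s)
    assert est.ani == 100.0 and est.aligned_fraction == 1.0


def test_disjoint_kmer_sets_floor_at_zero(rng):
    a = "A" * 1000
    b = "C" * 1000
    est = estimate_ani(a, b)
    assert est.ani == 0.0 and est.aligned_fraction == 0.0


def test_short_sequence_rejected():
    with pytest.raises(ValueError):
        estimate_ani("ACGT" * 10, "ACGT" * 100, k=16)


def test_canonical_kmers_strand_invariant(rng):
    s = random_seq(rng, 3000)
    rc = "".join(COMP[b] for b in reversed(s))
    assert np.array_equal(kmer_set(s), kmer_set(rc))


def test_ani_tracks_true_identity_at_3_percent(rng):
    """Median estimate over 20 draws within +/-1 of the true 97 % identity."""
    anis = []
    for _ in range(20):
        s = random_seq(rng, 20_000)
        anis.append(estimate_ani(s, mutate(s, 0.03, rng)).ani)
    assert abs(np.median(anis) - 97.0) <= 1.0


def test_simulated_within_species_ani_matches_base_identity():
    """Estimator agrees with directly counted matching bases on planted copies."""
    cfg = SimulationConfig(seed=3, n_species=2, copies_per_species=2,
                           genome_length=20_000, mutation_rate_within=0.01)
    seqs, truth = simulate_genomes(cfg)
    a, b = seqs["sp000_c0"], seqs["sp000_c1"]
    true_identity = 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
    assert true_identity == pytest.approx(99.0, abs=0.3)
    assert estimate_ani(a, b).ani == pytest.approx(true_identity, abs=1.0)
    assert truth["sp000_c0"] == truth["sp000_c1"] == "sp000"


def _precomputed(ani_pairs, ids):
    rows = [(a, b, v, 1.0) for (a, b), v in ani_pairs.items()]
    return pd.DataFrame(rows, columns=["genome_a", "genome_b", "ani", "aligned_fraction"])


def test_threshold_forced_two_clusters():
    ani = _precomputed({("A", "B"): 96, ("A", "C"): 80, ("B", "C"): 80}, "ABC")
    est = GreedyANIClusterer(threshold=95).fit(
        ani, ids=["A", "B", "C"], scores={"A": 90, "B": 80, "C": 70})
    member_sets = {frozenset(c.members) for c in est.clusters_}
    assert member_sets == {frozenset({"A", "B"}), frozenset({"C"})}
    assert est.clusters_[0].representative == "A"


def test_all_below_threshold_gives_singletons():
    ani = _precomputed({("A", "B"): 95, ("A", "C"): 90, ("B", "C"): 50}, "ABC")
    est = GreedyANIClusterer(threshold=95).fit(ani, ids=["A", "B", "C"])
    assert len(est.clusters_) == 3  # 'ANI > 95' is strict


def test_clustering_is_a_partition_with_valid_representatives(rng):
    cfg = SimulationConfig(seed=5, n_species=5, copies_per_species=3,
                           genome_length=8_000)
    seqs, _ = simulate_genomes(cfg)
    scores = {g: float(rng.uniform(60, 100)) for g in seqs}
    clusters = cluster_genomes(seqs, 95.0, scores=scores)
    all_members = [m for c in clusters for m in c.members]
    assert sorted(all_members) == sorted(seqs)  # partition
    ani_lookup = {}
    ani_df = pairwise_ani(seqs)
    for row in ani_df.itertuples():
        ani_lookup[frozenset((row.genome_a, row.genome_b))] = row.ani
    for c in clusters:
        assert c.representative in c.members
        # representative has the max quality score of its members
        assert scores[c.representative] == max(scores[m] for m in c.members)
        for m in c.members:
            if m != c.representative:
                assert ani_lookup[frozenset((m, c.representative))] > 95.0


def test_dereplicate_keeps_best_scoring_copy(rng):
    s = random_seq(rng, 2000)
    bins = pd.DataFrame({"bin_id": ["x", "y"], "quality_score": [80.0, 60.0]})
    mags, collections = dereplicate(bins, {"x": s, "y": s})
    assert list(mags["bin_id"]) == ["x"]
    assert len(collections) == 1 and collections[0].representative == "x"


def test_dereplicate_tie_broken_by_lexicographic_id(rng):
    s = random_seq(rng, 2000)
    bins = pd.DataFrame({"bin_id": ["b", "a"], "quality_score": [70.0, 70.0]})
    mags, _ = dereplicate(bins, {"b": s, "a": s})
    assert list(mags["bin_id"]) == ["a"]


def test_dereplicate_singletons_pass_through(rng):
    seqs = {f"g{i}": random_seq(rng, 2000) for i in range(4)}
    bins = pd.DataFrame({"bin_id": list(seqs), "quality_score": [70.0] * 4})
    mags, _ = dereplicate(bins, seqs)
    assert len(mags) == 4


def test_two_level_consistency():
    """No 99 % collection is split across 95 % SGBs."""
    cfg = SimulationConfig(seed=9, n_species=4, copies_per_species=3,
                           genome_length=10_000, mutation_rate_within=0.001)
    seqs, _ = simulate_genomes(cfg)
    coll = cluster_genomes(seqs, 99.0, level="collection_99")
    sgbs = cluster_genomes(seqs, 95.0)
    sgb_of = {m: c.cluster_id for c in sgbs for m in c.members}
    for c in coll:
        assert len({sgb_of[m] for m in c.members}) == 1


def test_catalog_overlap_disjoint_and_identical(rng):
    a = {f"a{i}": random_seq(rng, 2000) for i in range(3)}
    b = {f"b{i}": random_seq(rng, 2000) for i in range(3)}
    out = catalog_overlap({"cat1": a, "cat2": b})
    assert (out["degree"] == 1).all()  # no shared clusters
    twin = {f"t{i}": seq for i, seq in enumerate(a.values())}
    out2 = catalog_overlap({"cat1": a, "cat2": twin})
    assert set(out2["catalogs"]) == {"cat1&cat2"}


def test_catalog_overlap_planted_three_way():
    cfg = SimulationConfig(seed=21, n_species=4, copies_per_species=3,
                           genome_length=8_000)
    seqs, truth = simulate_genomes(cfg)
    by_sp = {}
    for gid, sp in truth.items():
        by_sp.setdefault(sp, []).append(gid)
    # species sp000: cats 1&3; sp001: all three; sp002: cat2 only; sp003: cat3 only
    cats = {
        "c1": {g: seqs[g] for g in [by_sp["sp000"][0], by_sp["sp001"][0]]},
        "c2": {g: seqs[g] for g in [by_sp["sp001"][1], by_sp["sp002"][0]]},
        "c3": {g: seqs[g] for g in [by_sp["sp000"][1], by_sp["sp001"][2],
                                    by_sp["sp003"][0]]},
    }
    out = catalog_overlap(cats).set_index("catalogs")["n_clusters"]
    assert out.to_dict() == {"c1&c3": 1, "c1&c2&c3": 1, "c2": 1, "c3": 1}


def test_catalog_overlap_duplicate_ids_rejected(rng):
    a = {"g1": random_seq(rng, 2000)}
    with pytest.raises(ValueError):
        catalog_overlap({"c1": a, "c2": a})


def brute_force_min_clusterings(ani, ids, threshold):
    """All minimum-cardinality partitions admitting a valid representative
    (every member ANI > threshold to it) per block."""
    def valid(block):
        return any(all(ani[frozenset((r, m))] > threshold
                       for m in block if m != r) for r in block)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i, block in enumerate(part):
                yield part[:i] + [[first] + block] + part[i + 1:]
            yield [[first]] + part

    best, best_size = [], None
    for part in partitions(list(ids)):
        if all(valid(b) for b in part):
            if best_size is None or len(part) < best_size:
                best, best_size = [part], len(part)
            elif len(part) == best_size:
                best.append(part)
    return best


def test_greedy_matches_exhaustive_on_forced_instances(rng):
    """On block-structured instances with a unique minimum-cardinality valid
    partition, greedy clustering returns exactly that partition."""
    for trial in range(25):
        n = int(rng.integers(4, 9))
        n_blocks = int(rng.integers(1, max(2, n // 2) + 1))
        assignment = rng.integers(0, n_blocks, n)
        ids = [f"g{i}" for i in range(n)]
        ani = {}
        for i, j in itertools.combinations(range(n), 2):
            same = assignment[i] == assignment[j]
            val = rng.uniform(96, 99.5) if same else rng.uniform(70, 90)
            ani[frozenset((ids[i], ids[j]))] = val
        rows = [(a_id, b_id, ani[frozenset((a_id, b_id))], 1.0)
                for a_id, b_id in itertools.combinations(ids, 2)]
        table = pd.DataFrame(rows, columns=["genome_a", "genome_b", "ani",
                                            "aligned_fraction"])
        est = GreedyANIClusterer(threshold=95).fit(
            table, ids=ids, scores={g: float(rng.uniform(0, 100)) for g in ids})
        greedy = {frozenset(c.members) for c in est.clusters_}
        optima = brute_force_min_clusterings(ani, ids, 95)
        assert len(optima) >= 1
        as_sets = [{frozenset(b) for b in part} for part in optima]
        assert all(s == as_sets[0] for s in as_sets), "instance not forced"
        assert greedy == as_sets[0]
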