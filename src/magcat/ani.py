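"""k-mer based ANI estimation and two-level greedy dereplication.

ANI between two genomes is estimated from canonical k-mer sets (default
k = 16): with containment c = |A ∩ B| / min(|A|, |B|), the Jaccard-equivalent
for equal-content genomes is J = c / (2 - c), and the Mash-style distance
transform ANI = 100 * (1 + (1/k) * ln(2J / (1 + J))) collapses to

    ANI = 100 * (1 + ln(c) / k),   floored at 0.

Dereplication is greedy centroid clustering: genomes sorted by descending
quality score (ties: longer genome, then lexicographically smaller id); the
best unassigned genome becomes a representative and every unassigned genome
whose ANI to it strictly exceeds the threshold (and whose shared k-mer
containment meets the aligned-fraction floor) joins. Applied at 99 % this
yields dereplication collections whose representatives are the MAGs; at 95 %
it yields species-level genome bins (SGBs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClusterMixin

LEVEL_COLLECTION = "collection_99"
LEVEL_SGB = "sgb_95"

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


def kmer_set(sequence: str, k: int = 16) -> np.ndarray:
    """Sorted unique canonical k-mer codes of a sequence.

    Each k-mer is 2-bit packed into a uint64; the canonical form is the
    minimum of the forward code and the reverse-complement code. Windows
    containing non-ACGT characters are dropped.
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31]")
    a = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if len(a) < k:
        return np.empty(0, dtype=np.uint64)
    win = sliding_window_view(a, k)
    valid = (win < 4).all(axis=1)
    w = win[valid].astype(np.uint64)
    if not len(w):
        return np.empty(0, dtype=np.uint64)
    pw_f = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    pw_r = (np.uint64(4) ** np.arange(k, dtype=np.uint64))
    fwd = (w * pw_f).sum(axis=1)
    rev = ((np.uint64(3) - w) * pw_r).sum(axis=1)
    return np.unique(np.minimum(fwd, rev))


@dataclass(frozen=True)
class ANIEstimate:
    """Pairwise ANI estimate with its shared-k-mer containment."""
    genome_a: str
    genome_b: str
    ani: float
    aligned_fraction: float


def _ani_from_sets(sa: np.ndarray, sb: np.ndarray, k: int) -> tuple[float, float]:
    denom = min(len(sa), len(sb))
    if denom == 0:
        return 0.0, 0.0
    inter = np.intersect1d(sa, sb, assume_unique=True).size
    c = inter / denom
    if c <= 0.0:
        return 0.0, 0.0
    ani = 100.0 * (1.0 + np.log(c) / k)
    return float(max(ani, 0.0)), float(c)


def estimate_ani(seq_a: str, seq_b: str, k: int = 16,
                 ids: tuple[str, str] = ("a", "b")) -> ANIEstimate:
    """Estimate ANI between two sequences from canonical k-mer containment.

    Identical sequences give exactly 100; sequences sharing no k-mer give 0.
    Both sequences must be at least 10*k bases long.
    """
    if min(len(seq_a), len(seq_b)) < 10 * k:
        raise ValueError(f"sequences must be >= {10 * k} bases for k={k}")
    ani, af = _ani_from_sets(kmer_set(seq_a, k), kmer_set(seq_b, k), k)
    return ANIEstimate(ids[0], ids[1], ani, af)


def pairwise_ani(sequences: Mapping[str, str], k: int = 16) -> pd.DataFrame:
    """Long-format pairwise ANI table (each unordered pair once)."""
    ids = sorted(sequences)
    sets = {g: kmer_set(sequences[g], k) for g in ids}
    rows = []
    for ga, gb in itertools.combinations(ids, 2):
        ani, af = _ani_from_sets(sets[ga], sets[gb], k)
        rows.append((ga, gb, ani, af))
    return pd.DataFrame(rows, columns=["genome_a", "genome_b", "ani", "aligned_fraction"])


@dataclass
class SpeciesCluster:
    """An ANI-defined cluster with its best-quality representative."""
    cluster_id: str
    level: str
    representative: str
    members: list[str] = field(default_factory=list)


def _to_square(ani: pd.DataFrame, ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    idx = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    np.fill_diagonal(A, 100.0)
    AF = np.zeros((n, n))
    np.fill_diagonal(AF, 1.0)
    for ga, gb, a, f in ani[["genome_a", "genome_b", "ani", "aligned_fraction"]].itertuples(index=False):
        i, j = idx[ga], idx[gb]
        A[i, j] = A[j, i] = a
        AF[i, j] = AF[j, i] = f
    return A, AF


class GreedyANIClusterer(BaseEstimator, ClusterMixin):
    """Greedy centroid clustering of genomes at an ANI threshold.

    Sklearn-compatible: ``fit`` accepts either a mapping ``{id: sequence}``
    or a precomputed long-format ANI table (``metric='precomputed'`` with
    ``ids`` given). Quality scores drive both the processing order and the
    representative choice, matching how dereplication picks the best bin of
    each collection.

    Parameters
    ----------
    threshold : float
        ANI threshold in percent; membership requires ANI strictly above it.
    k : int
        k-mer size of the built-in estimator.
    min_aligned_fraction : float
        Containment floor required in addition to the ANI threshold.
    level : str
        Label stored on emitted clusters ('collection_99' or 'sgb_95').

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster index per input genome (input order).
    clusters_ : list of SpeciesCluster
    representatives_ : list of str
    ani_ : pandas.DataFrame
        The pairwise ANI table used.
    """

    def __init__(self, threshold: float = 95.0, k: int = 16,
                 min_aligned_fraction: float = 0.3, level: str = LEVEL_SGB):
        self.threshold = threshold
        self.k = k
        self.min_aligned_fraction = min_aligned_fraction
        self.level = level

    def fit(self, X, y=None, scores: Mapping[str, float] | None = None,
            lengths: Mapping[str, float] | None = None,
            ids: Sequence[str] | None = None):
        if isinstance(X, pd.DataFrame):
            if ids is None:
                raise ValueError("ids must be given with a precomputed ANI table")
            self.ids_ = list(ids)
            self.ani_ = X
            lengths = lengths or {}
        else:
            seqs = dict(X)
            self.ids_ = list(seqs)
            self.ani_ = pairwise_ani(seqs, self.k)
            if lengths is None:
                lengths = {g: len(s) for g, s in seqs.items()}
        scores = scores or {}

        A, AF = _to_square(self.ani_, self.ids_)
        order = sorted(
            range(len(self.ids_)),
            key=lambda i: (-float(scores.get(self.ids_[i], 0.0)),
                           -float(lengths.get(self.ids_[i], 0.0)),
                           self.ids_[i]))
        labels = np.full(len(self.ids_), -1, dtype=int)
        clusters: list[SpeciesCluster] = []
        for i in order:
            if labels[i] != -1:
                continue
            cid = len(clusters)
            labels[i] = cid
            members = [self.ids_[i]]
            for j in order:
                if labels[j] != -1 or j == i:
                    continue
                if A[i, j] > self.threshold and AF[i, j] >= self.min_aligned_fraction:
                    labels[j] = cid
                    members.append(self.ids_[j])
            clusters.append(SpeciesCluster(
                cluster_id=f"{self.level}_{cid:04d}", level=self.level,
                representative=self.ids_[i], members=members))
        self.labels_ = labels
        self.clusters_ = clusters
        self.representatives_ = [c.representative for c in clusters]
        return self

    def fit_predict(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).labels_


def cluster_genomes(sequences: Mapping[str, str], ani_threshold: float,
                    scores: Mapping[str, float] | None = None, k: int = 16,
                    min_aligned_fraction: float = 0.3,
                    level: str = LEVEL_SGB) -> list[SpeciesCluster]:
    """Functional wrapper over :class:`GreedyANIClusterer`."""
    est = GreedyANIClusterer(threshold=ani_threshold, k=k,
                             min_aligned_fraction=min_aligned_fraction, level=level)
    est.fit(sequences, scores=scores)
    return est.clusters_


def dereplicate(bins: pd.DataFrame, sequences: Mapping[str, str],
                ani_threshold: float = 99.0, k: int = 16,
                min_aligned_fraction: float = 0.3
                ) -> tuple[pd.DataFrame, list[SpeciesCluster]]:
    """Collapse >99 %-ANI collections to their best-quality representative.

    Returns the MAG table (one row per collection representative, with a
    ``collection_id`` column) and the collections themselves. Score ties are
    broken by genome length, then by lexicographically smaller bin id.
    """
    scores = dict(zip(bins["bin_id"], bins["quality_score"]))
    seqs = {b: sequences[b] for b in bins["bin_id"]}
    clusters = cluster_genomes(seqs, ani_threshold, scores=scores, k=k,
                               min_aligned_fraction=min_aligned_fraction,
                               level=LEVEL_COLLECTION)
    rep_to_cluster = {c.representative: c.cluster_id for c in clusters}
    mags = bins[bins["bin_id"].isin(rep_to_cluster)].copy()
    mags["collection_id"] = mags["bin_id"].map(rep_to_cluster)
    return mags.reset_index(drop=True), clusters


def catalog_overlap(catalogs: Mapping[str, Mapping[str, str]],
                    scores: Mapping[str, float] | None = None,
                    ani_threshold: float = 95.0, k: int = 16,
                    min_aligned_fraction: float = 0.3) -> pd.DataFrame:
    """UpSet-style intersection counts between genome catalogs.

    All genomes are pooled and clustered at the species threshold; each
    cluster is labelled by the set of catalogs contributing members, and
    clusters are counted per label combination. A catalog's novel count is
    the row whose combination is that catalog alone.
    """
    if len(catalogs) < 2:
        raise ValueError("need at least two catalogs")
    owner: dict[str, str] = {}
    pooled: dict[str, str] = {}
    for name, genomes in catalogs.items():
        for gid, seq in genomes.items():
            if gid in owner:
                raise ValueError(f"genome id {gid!r} occurs in catalogs "
                                 f"{owner[gid]!r} and {name!r}")
            owner[gid] = name
            pooled[gid] = seq
    clusters = cluster_genomes(pooled, ani_threshold, scores=scores, k=k,
                               min_aligned_fraction=min_aligned_fraction)
    combos: dict[tuple[str, ...], int] = {}
    for c in clusters:
        combo = tuple(sorted({owner[m] for m in c.members}))
        combos[combo] = combos.get(combo, 0) + 1
    rows = [{"catalogs": "&".join(combo), "degree": len(combo), "n_clusters": n}
            for combo, n in sorted(combos.items())]
    return pd.DataFrame(rows, columns=["catalogs", "degree", "n_clusters"])


def clusters_to_frame(clusters: Iterable[SpeciesCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"cluster_id": c.cluster_id, "level": c.level,
          "representative": c.representative, "members": ",".join(sorted(c.members)),
          "n_members": len(c.members)} for c in clusters],
        columns=["cluster_id", "level", "representative", "members", "n_members"])
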