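"""Presence calls, core/unique SGB sets, and region-universal species lists.

Two value kinds flow through the same matrix container and are deliberately
not interchangeable: per-sample genome *coverage* (percent, drives presence
calls at the 1 % cutoff) and *relative abundance* (percent, rows sum to 100,
drives the region-universality rule: >= 0.01 % abundance in at least 50 % of
a region's samples).

All boundary comparisons use >= ("cutoff" / "at least").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

KIND_COVERAGE = "coverage"
KIND_RELATIVE = "relative"


@dataclass
class AbundanceMatrix:
    """Samples x SGBs matrix plus its value kind and sample metadata.

    ``values`` is indexed by sample id with one column per SGB/species.
    """

    values: pd.DataFrame
    kind: str
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in (KIND_COVERAGE, KIND_RELATIVE):
            raise ValueError(f"unknown value kind {self.kind!r}")
        v = self.values.to_numpy(dtype=float)
        if (v < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.kind == KIND_COVERAGE and (v > 100).any():
            raise ValueError("coverage values must lie in [0, 100]")
        if self.kind == KIND_RELATIVE:
            sums = v.sum(axis=1)
            if not np.allclose(sums, 100.0, atol=1e-6):
                raise ValueError("relative-abundance rows must sum to 100")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename_axis("sample_id").reset_index().to_csv(
            path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str,
                 metadata: pd.DataFrame | None = None) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t").set_index("sample_id")
        return cls(df.astype(float), kind=kind, metadata=metadata)


def relative_from_depth(depth: pd.DataFrame, lengths: pd.Series | None = None
                        ) -> AbundanceMatrix:
    """Depth-weighted relative abundance: depth x genome length mass,
    normalised per sample to 100."""
    mass = depth.mul(lengths, axis=1) if lengths is not None else depth
    rel = 100.0 * mass.div(mass.sum(axis=1), axis=0)
    return AbundanceMatrix(rel, kind=KIND_RELATIVE)


def presence(matrix: AbundanceMatrix, coverage_cutoff: float = 1.0) -> pd.DataFrame:
    """Boolean presence matrix: coverage >= cutoff.

    Only defined for coverage-kind matrices; passing relative abundance is an
    error because the two kinds are on incomparable scales.
    """
    if matrix.kind != KIND_COVERAGE:
        raise ValueError("presence calls require a coverage-kind matrix")
    return matrix.values >= coverage_cutoff


def core_sets(presence_matrix: pd.DataFrame, core_fraction: float = 90.0
              ) -> dict[str, list[str]]:
    """Core / universal / single-sample-unique SGB sets from a presence matrix.

    core: present in >= core_fraction percent of samples; universal: present
    in every sample (a subset of core); unique: present in exactly one.
    """
    n = len(presence_matrix)
    counts = presence_matrix.sum(axis=0)
    core = counts[counts / n * 100.0 >= core_fraction - 1e-12].index
    return {
        "core": sorted(core),
        "universal": sorted(counts[counts == n].index),
        "unique": sorted(counts[counts == 1].index),
    }


def region_universal(matrix: AbundanceMatrix, metadata: pd.DataFrame | None = None,
                     abundance_min: float = 0.01, sample_fraction: float = 50.0
                     ) -> dict[str, object]:
    """Region-universal species sets plus the cross-region shared/endemic split.

    A species is universal in a region when its relative abundance reaches
    ``abundance_min`` percent in at least ``sample_fraction`` percent of that
    region's samples. ``shared`` is the intersection over all regions;
    ``endemic[r]`` the species universal in region r and nowhere else.
    """
    if matrix.kind != KIND_RELATIVE:
        raise ValueError("region universality is defined on relative abundance")
    meta = metadata if metadata is not None else matrix.metadata
    if meta is None or "region" not in meta.columns:
        raise ValueError("sample metadata with a 'region' column is required")
    region_of = meta.set_index("sample_id")["region"]

    per_region: dict[str, set[str]] = {}
    for region, sample_ids in region_of.groupby(region_of).groups.items():
        samples = [s for s in sample_ids if s in matrix.values.index]
        if not samples:
            raise ValueError(f"region {region!r} has no samples in the matrix")
        sub = matrix.values.loc[samples]
        frac = 100.0 * (sub >= abundance_min).sum(axis=0) / len(samples)
        per_region[str(region)] = set(frac[frac >= sample_fraction].index)

    shared = set.intersection(*per_region.values()) if per_region else set()
    endemic = {
        r: sorted(s - set.union(*(per_region[o] for o in per_region if o != r))
                  if len(per_region) > 1 else s)
        for r, s in per_region.items()
    }
    return {
        "universal": {r: sorted(s) for r, s in per_region.items()},
        "shared": sorted(shared),
        "endemic": endemic,
    }
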