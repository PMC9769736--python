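"""Run configuration: every fixed threshold of the catalog pipeline in one place.

All thresholds default to the values used to build the published Caprinae gut
catalog and are individually overridable, either programmatically or through a
YAML run-config file consumed by the CLI.

Scale conventions: completeness, contamination, coverage and relative abundance
are carried on the 0-100 percent scale; G+C content is carried as a fraction in
[0, 1] (the merge tolerance of +/-0.02 is on that scale).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class RunConfig:
    """Thresholds, paths and the global seed for a pipeline run.

    Parameters
    ----------
    completeness_min : float
        Minimum estimated completeness (percent) for a bin to be retained.
    contamination_max : float
        Contamination bound (percent); the comparison is strict (``< 5``).
    quality_score_min : float
        Retention bound on ``completeness - 5 * contamination``; strict
        (``> 55``), so a bin landing exactly on 55 is rejected.
    ani_species : float
        ANI species boundary (percent); genomes with pairwise ANI strictly
        above this belong to one species-level genome bin (SGB).
    ani_collection : float
        ANI threshold (percent) for the first-pass dereplication collections.
    min_aligned_fraction : float
        Minimum shared k-mer containment required in addition to the ANI
        threshold at both clustering levels.
    presence_coverage : float
        Coverage cutoff (percent) for calling an SGB present in a sample.
    core_sample_fraction : float
        An SGB present in at least this percent of samples is "core".
    region_prevalence_abundance : float
        Relative-abundance floor (percent) for the region-universality rule.
    region_prevalence_fraction : float
        Percent of a region's samples that must reach the abundance floor.
    reporter_threshold : float
        Module reporter-score detection threshold.
    min_samples_per_ko : int
        A KO enters the rank-sum testing only if nonzero in strictly more
        than this many samples.
    """

    completeness_min: float = 70.0
    contamination_max: float = 5.0
    quality_score_min: float = 55.0
    ani_species: float = 95.0
    ani_collection: float = 99.0
    min_aligned_fraction: float = 0.3
    kmer_size: int = 16
    depth_merge_tolerance: float = 0.10
    gc_merge_tolerance: float = 0.02
    presence_coverage: float = 1.0
    core_sample_fraction: float = 90.0
    region_prevalence_abundance: float = 0.01
    region_prevalence_fraction: float = 50.0
    reporter_threshold: float = 1.6
    min_samples_per_ko: int = 3
    permanova_permutations: int = 1000
    seed: int = 0
    outdir: Path = field(default_factory=lambda: Path("magcat_out"))

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name in ("completeness_min", "contamination_max", "core_sample_fraction",
                     "region_prevalence_fraction", "presence_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v!r} must lie in [0, 100]")
        if not 0 < self.ani_species <= 100 or not 0 < self.ani_collection <= 100:
            raise ValueError("ANI thresholds must lie in (0, 100]")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
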