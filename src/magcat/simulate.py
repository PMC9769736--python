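"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a gut-metagenome MAG
study: species clusters straddling the 95 % ANI boundary, bin-quality tables
spanning the retention thresholds, compositional sample-by-species matrices
with a planted between-group shift, and KEGG-style annotation tables with
planted differential modules. Each stage draws from an independent substream
fanned out from one global seed, so outputs are byte-identical under a fixed
seed and stages can be regenerated in isolation.

Mutation is substitution-only, which keeps true ANI analytically computable
as 1 minus the substitution rate. Species ancestors are derived from a shared
root with per-branch rate r = (3/4)(1 - sqrt(1 - 4d/3)) so that the expected
pairwise divergence between ancestors equals the configured between-species
rate d exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .binqc import gc_content, quality_score
from .profiles import AbundanceMatrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# substream indices: genomes=1, bins=2, abundance=3, annotations=4, metadata=5
_STREAM_GENOMES, _STREAM_BINS, _STREAM_ABUND, _STREAM_ANNOT, _STREAM_META = 1, 2, 3, 4, 5


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the design of the emulated study where one is stated
    (30 samples from 6 regions) and otherwise sit at desk-scale values that
    keep every planted signal recoverable: within-species divergence 1 % and
    between-species divergence 10 % straddle the 95 % ANI species boundary
    with a wide margin on 100 kb genomes.
    """

    seed: int = 0
    n_species: int = 20
    copies_per_species: int = 3
    genome_length: int = 100_000
    mutation_rate_within: float = 0.01
    mutation_rate_between: float = 0.10
    n_samples: int = 30
    n_groups: int = 6
    group_effect: float = 1.0
    abundance_sigma: float = 1.0
    n_modules: int = 30
    kos_per_module: int = 5
    n_differential_modules: int = 5
    differential_effect: float = 2.0
    completeness_range: tuple[float, float] = (55.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 8.0)

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate_within < 0.05:
            raise ValueError("mutation_rate_within must lie in [0, 0.05)")
        if not 0.05 < self.mutation_rate_between <= 0.74:
            raise ValueError("mutation_rate_between must lie in (0.05, 0.74]")
        if self.genome_length < 160:  # 10 x default k-mer size
            raise ValueError("genome_length must be at least 10x the k-mer size (160)")
        if self.n_groups > self.n_samples:
            raise ValueError("n_groups may not exceed n_samples")
        if self.n_modules < self.n_differential_modules:
            raise ValueError("need n_modules >= n_differential_modules")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute a Binomial(L, rate) number of sites to a different base."""
    out = seq.copy()
    n_mut = rng.binomial(len(seq), rate)
    if n_mut == 0:
        return out
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=n_mut)) % 4
    return out


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def simulate_genomes(config: SimulationConfig
                     ) -> tuple[dict[str, str], dict[str, str]]:
    """Simulate species ancestors plus mutated within-species copies.

    Returns ``(sequences, truth)`` where truth maps genome id to its species
    label. The first copy of each species is the unmutated ancestor, so with
    within-species rate w the ancestor-copy ANI is ~100(1-w) and copy-copy
    ANI ~100(1-2w); ancestors of different species diverge at the
    between-species rate.
    """
    rng = config.rng(_STREAM_GENOMES)
    d = config.mutation_rate_between
    branch_rate = 0.75 * (1.0 - np.sqrt(1.0 - 4.0 * d / 3.0))
    root = rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)

    sequences: dict[str, str] = {}
    truth: dict[str, str] = {}
    for si in range(config.n_species):
        species = f"sp{si:03d}"
        ancestor = _mutate(root, branch_rate, rng)
        for ci in range(config.copies_per_species):
            gid = f"{species}_c{ci}"
            seq = ancestor if ci == 0 else _mutate(ancestor, config.mutation_rate_within, rng)
            sequences[gid] = _decode(seq)
            truth[gid] = species
    return sequences, truth


def _taxonomy(species: str, si: int) -> str:
    return (f"d__Bacteria;p__P{si % 4:02d};o__O{si % 6:02d};"
            f"f__F{si % 8:02d};s__{species}")


def simulate_bin_table(config: SimulationConfig, sequences: Mapping[str, str],
                       truth: Mapping[str, str]) -> pd.DataFrame:
    """Per-bin quality table emulating CheckM / depth-summary outputs.

    Completeness and contamination are drawn uniformly from the configured
    ranges, so with the defaults some bins deliberately fail the retention
    thresholds (flagged ``truth_pass_filter``). For every even-indexed
    species with at least two copies, the first two copies are planted in the
    same sample with depths 5 % apart and identical taxonomy, making them
    mergeable by construction (flagged ``truth_merge_group``).
    """
    rng = config.rng(_STREAM_BINS)
    samples = [f"samp{j:02d}" for j in range(config.n_samples)]
    rows = []
    for gid in sequences:
        species = truth[gid]
        si = int(species[2:])
        ci = int(gid.rsplit("_c", 1)[1])
        seq = sequences[gid]
        comp = rng.uniform(*config.completeness_range)
        cont = rng.uniform(*config.contamination_range)
        depth = float(np.exp(rng.normal(np.log(30.0), 0.5)))
        sample = samples[rng.integers(0, len(samples))]
        merge_group = ""
        if si % 2 == 0 and ci in (0, 1) and config.copies_per_species >= 2:
            # planted mergeable pair: shared sample, depths within 10 %
            sample = samples[si % len(samples)]
            merge_group = f"mg_{species}"
        rows.append({
            "bin_id": gid, "sample_id": sample, "length": len(seq),
            "n_contigs": int(rng.poisson(150)) + 1,
            "n50": int(np.exp(rng.normal(np.log(20_000), 0.6))),
            "completeness": round(comp, 2), "contamination": round(cont, 2),
            "mean_depth": round(depth, 3), "gc": round(gc_content(seq), 5),
            "taxonomy": _taxonomy(species, si),
            "truth_species": species, "truth_merge_group": merge_group,
        })
    df = pd.DataFrame(rows)
    # align planted pair depths after the draw so the ratio is exactly 1.05
    for _, grp in df.groupby("truth_merge_group"):
        if len(grp) == 2 and grp["truth_merge_group"].iloc[0]:
            d0 = df.loc[grp.index[0], "mean_depth"]
            df.loc[grp.index[1], "mean_depth"] = round(d0 * 1.05, 3)
    score = quality_score(df["completeness"].to_numpy(), df["contamination"].to_numpy())
    df["truth_pass_filter"] = ((df["completeness"] >= 70) & (df["contamination"] < 5)
                               & (score > 55))
    return df


def simulate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata: region (round-robin over n_groups), host, sex, altitude.

    Region 1 plays the role of the high-altitude group: its samples carry the
    planted compositional and functional shifts, and ``enrich_group`` encodes
    the two-group contrast (A = region_1, B = everything else).
    """
    rng = config.rng(_STREAM_META)
    rows = []
    for j in range(config.n_samples):
        g = j % config.n_groups
        region = f"region_{g + 1}"
        altitude = rng.normal(4500.0, 200.0) if g == 0 else rng.normal(1000.0, 300.0)
        rows.append({
            "sample_id": f"samp{j:02d}", "region": region,
            "host_species": ["O_aries", "C_hircus"][int(rng.integers(0, 2))],
            "sex": ["F", "M"][int(rng.integers(0, 2))],
            "altitude": round(max(altitude, 0.0), 1),
            "enrich_group": "A" if g == 0 else "B",
        })
    return pd.DataFrame(rows)


def simulate_abundance(config: SimulationConfig, species: list[str] | None = None
                       ) -> tuple[AbundanceMatrix, AbundanceMatrix, pd.DataFrame, dict]:
    """Sample-by-species coverage and relative-abundance matrices.

    Log-normal baseline abundances; the first fifth of the species list is
    shifted by ``exp(group_effect)`` in region_1 samples; rows of the
    relative matrix are normalised to 100. The first 30 % of species are
    planted prevalent everywhere (the core), the last species is planted in
    exactly one sample (a single-sample-unique SGB). Coverage is a saturating
    transform of abundance mass, bounded in [0, 100].

    Returns (coverage, relative, metadata, truth).
    """
    if species is None:
        species = [f"sp{si:03d}" for si in range(config.n_species)]
    metadata = simulate_metadata(config)
    rng = config.rng(_STREAM_ABUND)
    n, s = config.n_samples, len(species)
    if s < 2:
        raise ValueError("need at least two species")

    n_core = max(1, int(np.ceil(0.3 * s)))
    prevalence = rng.uniform(0.3, 1.0, size=s)
    prevalence[:n_core] = 1.0
    mu = rng.normal(0.0, 1.0, size=s)

    present = rng.random((n, s)) < prevalence
    present[:, -1] = False
    present[0, -1] = True  # planted single-sample-unique species
    raw = np.exp(mu + config.abundance_sigma * rng.normal(size=(n, s)))
    n_shift = max(1, s // 5)
    in_a = (metadata["enrich_group"] == "A").to_numpy()
    raw[np.ix_(in_a, np.arange(n_shift))] *= np.exp(config.group_effect)
    raw = np.where(present, raw, 0.0)

    rel = 100.0 * raw / raw.sum(axis=1, keepdims=True)
    cov = np.clip(100.0 * (1.0 - np.exp(-raw)), 0.0, 100.0)

    idx = metadata["sample_id"].tolist()
    coverage = AbundanceMatrix(pd.DataFrame(cov, index=idx, columns=species),
                               kind="coverage", metadata=metadata)
    relative = AbundanceMatrix(pd.DataFrame(rel, index=idx, columns=species),
                               kind="relative", metadata=metadata)
    truth = {
        "core_species": species[:n_core],
        "shifted_species": species[:n_shift],
        "unique_species": [species[-1]],
        "group_a_samples": metadata.loc[in_a, "sample_id"].tolist(),
    }
    return coverage, relative, metadata, truth


def simulate_annotations(config: SimulationConfig, truth: Mapping[str, str] | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Gene annotations, a module catalog, and a sample-by-KO abundance matrix.

    Modules are disjoint blocks of ``kos_per_module`` KOs. Each genome's KO
    set is built so the module-integrity codes {2, 1, 0} all occur with known
    truth (complete / missing exactly one / missing two or more). The first
    ``n_differential_modules`` modules have their KOs multiplied by
    ``exp(differential_effect)`` in region_1 samples of the KO abundance
    matrix before per-sample renormalisation to 100.

    Returns (annotations, module catalog, sample-by-KO relative abundance,
    truth dict with the planted integrity matrix and differential modules).
    """
    rng = config.rng(_STREAM_ANNOT)
    genomes = (sorted(set(truth.values())) if truth
               else [f"sp{si:03d}" for si in range(config.n_species)])
    n_kos = config.n_modules * config.kos_per_module
    kos = [f"K{i + 1:05d}" for i in range(n_kos)]
    module_ids = [f"M{m + 1:04d}" for m in range(config.n_modules)]
    classes = ["carbohydrate", "amino_acid", "energy", "cofactor", "lipid"]
    catalog_rows = []
    module_kos: dict[str, list[str]] = {}
    for m, mid in enumerate(module_ids):
        block = kos[m * config.kos_per_module:(m + 1) * config.kos_per_module]
        module_kos[mid] = block
        for ko in block:
            catalog_rows.append({"module_id": mid, "ko": ko,
                                 "module_class": classes[m % len(classes)]})
    modules_df = pd.DataFrame(catalog_rows)

    ann_rows = []
    integrity_truth: dict[str, dict[str, int]] = {}
    for gi, genome in enumerate(genomes):
        genome_kos: list[str] = []
        codes: dict[str, int] = {}
        for mid in module_ids:
            block = module_kos[mid]
            state = int(rng.choice([2, 1, 0], p=[0.5, 0.25, 0.25]))
            if state == 2:
                keep = list(block)
            elif state == 1:
                drop = rng.integers(0, len(block))
                keep = [k for i, k in enumerate(block) if i != drop]
            else:
                n_keep = int(rng.integers(0, max(len(block) - 1, 1)))
                keep = list(rng.choice(block, size=n_keep, replace=False))
            codes[mid] = state
            genome_kos.extend(keep)
        integrity_truth[genome] = codes
        # pad with unannotated genes to a ~60 % annotation fraction
        n_annot = len(genome_kos)
        n_total = max(n_annot, int(round(n_annot / 0.6))) if n_annot else 10
        gene_i = 0
        for ko in genome_kos:
            cazy = f"GH{int(rng.integers(1, 21))}" if rng.random() < 0.1 else ""
            ann_rows.append({"gene_id": f"{genome}_g{gene_i:05d}",
                             "genome_id": genome, "ko": ko, "cazy_family": cazy})
            gene_i += 1
        for _ in range(n_total - n_annot):
            ann_rows.append({"gene_id": f"{genome}_g{gene_i:05d}",
                             "genome_id": genome, "ko": "", "cazy_family": ""})
            gene_i += 1
        _ = gi
    annotations = pd.DataFrame(ann_rows)

    metadata = simulate_metadata(config)
    in_a = (metadata["enrich_group"] == "A").to_numpy()
    diff_modules = module_ids[:config.n_differential_modules]
    diff_kos = {ko for mid in diff_modules for ko in module_kos[mid]}
    raw = np.exp(rng.normal(0.0, 1.0, size=(config.n_samples, n_kos)))
    shift_cols = np.array([ko in diff_kos for ko in kos])
    raw[np.ix_(in_a, np.where(shift_cols)[0])] *= np.exp(config.differential_effect)
    rel = 100.0 * raw / raw.sum(axis=1, keepdims=True)
    ko_abundance = pd.DataFrame(rel, index=metadata["sample_id"].tolist(), columns=kos)

    truth_out = {
        "differential_modules": diff_modules,
        "integrity": integrity_truth,
    }
    return annotations, modules_df, ko_abundance, truth_out


def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every generator and write the standard input files to ``outdir``.

    Writes genomes.fasta, bins.tsv, metadata.tsv, coverage.tsv,
    abundance.tsv, annotations.tsv, modules.tsv, ko_abundance.tsv and
    truth.json; returns the path map.
    """
    from .io import write_fasta, write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences, truth = simulate_genomes(config)
    bins = simulate_bin_table(config, sequences, truth)
    coverage, relative, metadata, ab_truth = simulate_abundance(config)
    annotations, modules_df, ko_abundance, fn_truth = simulate_annotations(config, truth)

    paths = {name: outdir / fname for name, fname in [
        ("genomes", "genomes.fasta"), ("bins", "bins.tsv"),
        ("metadata", "metadata.tsv"), ("coverage", "coverage.tsv"),
        ("abundance", "abundance.tsv"), ("annotations", "annotations.tsv"),
        ("modules", "modules.tsv"), ("ko_abundance", "ko_abundance.tsv"),
        ("truth", "truth.json")]}
    write_fasta(sequences, paths["genomes"])
    write_table(bins, paths["bins"])
    write_table(metadata, paths["metadata"])
    coverage.to_tsv(paths["coverage"])
    relative.to_tsv(paths["abundance"])
    write_table(annotations, paths["annotations"])
    write_table(modules_df, paths["modules"])
    ko_abundance.rename_axis("sample_id").reset_index().pipe(
        lambda df: df.to_csv(paths["ko_abundance"], sep="\t", index=False,
                             float_format="%.10g"))
    with open(paths["truth"], "w") as fh:
        json.dump({"species": truth, **ab_truth, **fn_truth}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
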