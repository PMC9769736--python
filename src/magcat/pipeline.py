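"""Stage orchestration: each stage reads its input files, runs the library,
and writes its output files into the run directory.

Stages are independently re-runnable; `run_all` chains them on a simulated
input set. All randomness flows from the config seed, so a repeated run with
the same seed reproduces every output byte for byte (timings go to the log,
not to any output file).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ani import clusters_to_frame, cluster_genomes, dereplicate
from .binqc import BinQualityFilter
from .config import RunConfig
from .ecology import (PCoA, alpha_diversity, bray_curtis, diversity_comparison,
                      permanova, rarefaction)
from .enrichment import ReporterScoreEnrichment
from .functions import ModuleIntegrityEncoder, annotation_fraction, profile_counts
from .io import read_fasta, read_table, write_manifest, write_table
from .profiles import AbundanceMatrix, core_sets, presence, region_universal
from .simulate import SimulationConfig, write_simulation

logger = logging.getLogger("magcat")


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: started", stage)
            return self

        def __exit__(self, *exc):
            logger.info("stage %s: finished in %.2f s", stage,
                        time.perf_counter() - self.t0)
            return False
    return _Timer()


def stage_simulate(config: RunConfig, sim: SimulationConfig | None = None) -> dict:
    with _timed("simulate"):
        sim = sim or SimulationConfig(seed=config.seed)
        return write_simulation(sim, config.outdir)


def stage_qc(config: RunConfig) -> Path:
    """Merge compatible bins, apply the retention filter, assign MIMAG tiers."""
    with _timed("qc"):
        out = config.outdir
        bins = read_table(out / "bins.tsv", "bins")
        sequences = read_fasta(out / "genomes.fasta")
        qc = BinQualityFilter(config=config)
        mags = qc.fit_transform(bins, sequences=sequences)
        write_table(mags, out / "qc_bins.tsv")
        write_table(qc.merge_audit_, out / "merges.tsv")
        write_table(qc.rejections_, out / "rejections.tsv")
        logger.info("qc: %d bins in, %d retained, %d rejected",
                    len(bins), len(mags), len(qc.rejections_))
        return out / "qc_bins.tsv"


def stage_dereplicate(config: RunConfig) -> Path:
    """99 % collections -> MAGs, then 95 % clustering of MAGs -> SGBs."""
    with _timed("dereplicate"):
        out = config.outdir
        bins = read_table(out / "qc_bins.tsv",
                          {"bin_id": "str", "completeness": "percent",
                           "contamination": "float", "length": "int",
                           "taxonomy": "str"})
        bins["quality_score"] = (bins["completeness"] - 5 * bins["contamination"])
        sequences = read_fasta(out / "genomes.fasta")
        # merged bins concatenate their members' sequences
        merges = pd.read_csv(out / "merges.tsv", sep="\t")
        for _, row in merges.iterrows():
            members = row["members"].split(",")
            sequences[row["merged_id"]] = "".join(sequences[m] for m in members)

        mags, collections = dereplicate(
            bins, sequences, ani_threshold=config.ani_collection,
            k=config.kmer_size, min_aligned_fraction=config.min_aligned_fraction)
        write_table(mags, out / "mags.tsv")

        mag_seqs = {b: sequences[b] for b in mags["bin_id"]}
        scores = dict(zip(mags["bin_id"], mags["quality_score"]))
        sgbs = cluster_genomes(mag_seqs, config.ani_species, scores=scores,
                               k=config.kmer_size,
                               min_aligned_fraction=config.min_aligned_fraction)
        frame = pd.concat([clusters_to_frame(collections), clusters_to_frame(sgbs)],
                          ignore_index=True)
        write_table(frame, out / "sgb.tsv")

        from .ani import pairwise_ani
        write_table(pairwise_ani(mag_seqs, config.kmer_size), out / "ani.tsv")
        logger.info("dereplicate: %d bins -> %d MAGs -> %d SGBs",
                    len(bins), len(mags), len(sgbs))
        return out / "sgb.tsv"


def stage_profile(config: RunConfig) -> Path:
    """Presence, core/universal/unique sets, and region-universal species."""
    with _timed("profile"):
        out = config.outdir
        metadata = read_table(out / "metadata.tsv", "metadata")
        coverage = AbundanceMatrix.from_tsv(out / "coverage.tsv", "coverage", metadata)
        relative = AbundanceMatrix.from_tsv(out / "abundance.tsv", "relative", metadata)

        pres = presence(coverage, config.presence_coverage)
        sets = core_sets(pres, config.core_sample_fraction)
        counts = pres.sum(axis=0)
        core_df = pd.DataFrame({
            "sgb": pres.columns,
            "n_samples_present": counts.values,
            "is_core": [s in set(sets["core"]) for s in pres.columns],
            "is_universal": [s in set(sets["universal"]) for s in pres.columns],
            "is_unique": [s in set(sets["unique"]) for s in pres.columns],
        })
        write_table(core_df, out / "core.tsv")

        ru = region_universal(relative, metadata,
                              config.region_prevalence_abundance,
                              config.region_prevalence_fraction)
        rows = [{"region": r, "species": ",".join(s)} for r, s in ru["universal"].items()]
        write_table(pd.DataFrame(rows), out / "region_universal.tsv")
        write_table(pd.DataFrame(
            [{"region": r, "species": ",".join(s)} for r, s in ru["endemic"].items()]),
            out / "endemic.tsv")
        write_table(pd.DataFrame([{"set": "shared_all_regions",
                                   "n_species": len(ru["shared"]),
                                   "species": ",".join(ru["shared"])}]),
                    out / "shared_counts.tsv")
        logger.info("profile: %d core, %d universal, %d unique, %d shared",
                    len(sets["core"]), len(sets["universal"]),
                    len(sets["unique"]), len(ru["shared"]))
        return out / "core.tsv"


def stage_function(config: RunConfig) -> Path:
    """KO/CAZy counts, annotation fractions, and module-integrity matrix."""
    with _timed("function"):
        out = config.outdir
        annotations = read_table(out / "annotations.tsv", "annotations")
        modules = read_table(out / "modules.tsv", "modules", unique_key=False)
        enc = ModuleIntegrityEncoder(catalog=modules)
        integrity = enc.fit_transform(annotations)
        integrity.reset_index().to_csv(out / "integrity.tsv", sep="\t", index=False)
        write_table(profile_counts(annotations, "genome", label="ko"),
                    out / "ko_counts.tsv")
        write_table(profile_counts(annotations, "genome", label="cazy_family"),
                    out / "cazy_counts.tsv")
        frac = annotation_fraction(annotations)
        frac.rename_axis("genome_id").reset_index().to_csv(
            out / "annotation_fraction.tsv", sep="\t", index=False,
            float_format="%.10g")
        return out / "integrity.tsv"


def stage_enrich(config: RunConfig) -> Path:
    """Per-KO rank-sum tests and module reporter scores for the A/B contrast."""
    with _timed("enrich"):
        out = config.outdir
        metadata = read_table(out / "metadata.tsv", "metadata")
        modules = read_table(out / "modules.tsv", "modules", unique_key=False)
        ko_ab = pd.read_csv(out / "ko_abundance.tsv", sep="\t").set_index("sample_id")
        groups = metadata.set_index("sample_id")["enrich_group"].reindex(ko_ab.index)
        est = ReporterScoreEnrichment(
            catalog=modules, min_samples=config.min_samples_per_ko,
            threshold=config.reporter_threshold)
        est.fit(ko_ab, groups)
        write_table(est.ko_results_, out / "ko_tests.tsv")
        write_table(est.module_scores_, out / "reporter.tsv")
        logger.info("enrich: %d KOs tested, %d modules significant",
                    est.ko_results_["ko"].nunique(),
                    int(est.module_scores_["significant"].sum()))
        return out / "reporter.tsv"


def stage_ecology(config: RunConfig) -> Path:
    """Diversity, Bray-Curtis, PCoA, per-factor PERMANOVA, rarefaction."""
    with _timed("ecology"):
        out = config.outdir
        metadata = read_table(out / "metadata.tsv", "metadata")
        relative = AbundanceMatrix.from_tsv(out / "abundance.tsv", "relative", metadata)
        coverage = AbundanceMatrix.from_tsv(out / "coverage.tsv", "coverage", metadata)
        X = relative.values

        div = pd.DataFrame({
            "sample_id": X.index,
            "shannon": alpha_diversity(X, "shannon").values,
            "simpson": alpha_diversity(X, "simpson").values,
        })
        write_table(div, out / "diversity.tsv")

        D = bray_curtis(X)
        D.rename_axis("sample_id").reset_index().to_csv(
            out / "bray.tsv", sep="\t", index=False, float_format="%.10g")

        ord_res = PCoA(n_components=10).fit(D)
        coords = ord_res.coordinates_.copy()
        coords.loc["proportion_explained"] = ord_res.proportion_explained_
        coords.rename_axis("sample_id").reset_index().to_csv(
            out / "pcoa.tsv", sep="\t", index=False, float_format="%.10g")

        meta = metadata.set_index("sample_id").reindex(X.index)
        meta["altitude_class"] = pd.cut(meta["altitude"], bins=[-1, 2500, 1e9],
                                        labels=["lowland", "highland"])
        rows = []
        for factor in ["region", "host_species", "sex", "altitude_class"]:
            labels = meta[factor].astype(str)
            try:
                res = permanova(D, labels, n_perm=config.permanova_permutations,
                                seed=config.seed, factor=factor)
            except ValueError as e:   # degenerate factor (single level / singleton)
                logger.warning("permanova on %s skipped: %s", factor, e)
                continue
            rows.append({"factor": res.factor, "r2": res.r2,
                         "pseudo_f": res.pseudo_f, "p_value": res.p_value,
                         "n_permutations": res.n_permutations})
        write_table(pd.DataFrame(rows), out / "permanova.tsv")

        pres = presence(coverage, config.presence_coverage)
        write_table(rarefaction(pres, n_perm=100, seed=config.seed),
                    out / "rarefaction.tsv")

        comp = pd.concat([diversity_comparison(X, meta["region"], ix)
                          for ix in ("shannon", "simpson")], ignore_index=True)
        write_table(comp, out / "diversity_tests.tsv")
        return out / "permanova.tsv"


def run_all(config: RunConfig, sim: SimulationConfig | None = None) -> Path:
    """Run the full chain on simulated inputs and write the manifest."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    stage_simulate(config, sim)
    stage_qc(config)
    stage_dereplicate(config)
    stage_profile(config)
    stage_function(config)
    stage_enrich(config)
    stage_ecology(config)
    out = config.outdir
    inputs = {p.name: p for p in sorted(out.glob("*.tsv"))}
    inputs["genomes.fasta"] = out / "genomes.fasta"
    inputs["truth.json"] = out / "truth.json"
    write_manifest(out / "manifest.json", config, inputs)
    summary = {
        "version": __version__,
        "n_mags": int(len(pd.read_csv(out / "mags.tsv", sep="\t"))),
        "n_sgbs": int((pd.read_csv(out / "sgb.tsv", sep="\t")["level"] == "sgb_95").sum()),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out / "manifest.json"
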