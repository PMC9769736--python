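"""Readers and writers for the tabular and sequence files the pipeline touches.

Everything tabular is TSV with a header row, UTF-8, '.' decimal (taxonomy
strings contain commas, so CSV is deliberately avoided). Sequence input is
plain multi-record FASTA.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("magcat")

#: column -> dtype ("str", "float", "int", "percent") per known table
SCHEMAS: dict[str, dict[str, str]] = {
    "bins": {
        "bin_id": "str", "sample_id": "str", "length": "int", "n_contigs": "int",
        "n50": "int", "completeness": "percent", "contamination": "float",
        "mean_depth": "float", "gc": "float", "taxonomy": "str",
    },
    "annotations": {"gene_id": "str", "genome_id": "str", "ko": "str", "cazy_family": "str"},
    "modules": {"module_id": "str", "ko": "str", "module_class": "str"},
    "metadata": {"sample_id": "str", "region": "str", "host_species": "str",
                 "sex": "str", "altitude": "float", "enrich_group": "str"},
}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into ``{id: uppercase sequence}``.

    An empty file yields an empty dict with a logged warning; duplicated
    record ids are an error.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        logger.warning("FASTA file %s contained no records", path)
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    _ = width  # Biopython wraps at 60; kept for signature stability


def read_table(path: str | Path, schema: str | Mapping[str, str],
               unique_key: bool = True) -> pd.DataFrame:
    """Read and validate a TSV against a named or explicit column schema.

    Columns required by the schema must be present and typed; percent columns
    are range-checked to [0, 100]. Unknown extra columns are preserved with a
    warning (tolerant-reader contract). The first schema column is treated as
    the row key and must be unique.
    """
    cols = SCHEMAS[schema] if isinstance(schema, str) else dict(schema)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cols if c not in df.columns and cols[c] != "str"]
    missing += [c for c, t in cols.items() if t == "str" and c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(set(missing))}")
    extra = [c for c in df.columns if c not in cols]
    if extra:
        warnings.warn(f"{path}: preserving unknown column(s) {extra}", stacklevel=2)
    for col, kind in cols.items():
        if kind in ("float", "percent", "int"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            if kind == "int":
                df[col] = df[col].astype(int)
        if kind == "percent":
            bad = df[(df[col] < 0) | (df[col] > 100)]
            if len(bad):
                raise ValueError(
                    f"{path}: column {col!r} outside [0, 100] "
                    f"(first offending row key {bad.iloc[0, 0]!r})")
    key = next(iter(cols))
    if unique_key and df[key].duplicated().any():
        dup = df.loc[df[key].duplicated(), key].iloc[0]
        raise ValueError(f"{path}: duplicated {key} {dup!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV deterministically (stable float formatting, no index)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config: Any, inputs: Mapping[str, str | Path],
                   outputs: Mapping[str, str | Path] | None = None) -> None:
    """Record config, seed, and input/output checksums for provenance.

    The manifest is deterministic for a fixed seed and fixed inputs: wall
    times live in the log, not here, so repeated runs are byte-identical.
    """
    from . import __version__

    manifest = {
        "tool": "magcat",
        "version": __version__,
        "config": config.to_dict() if hasattr(config, "to_dict") else dict(config),
        "inputs": {name: sha256_of(p) for name, p in sorted(inputs.items())},
        "outputs": {name: sha256_of(p) for name, p in sorted((outputs or {}).items())},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
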