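"""Per-genome functional profiles and KEGG-module integrity coding.

Module integrity is a trichotomy on the number of the module's KOs a genome
is missing: 0 missing -> 2 (complete), exactly 1 -> 1 (partial), 2 or more ->
0 (absent). Module definitions arrive as a flat module -> KO table; Boolean
AND/OR structure in KEGG definitions is flattened to the KO union, a
documented approximation of KEGG's stepwise logic.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

COMPLETE, PARTIAL, ABSENT = 2, 1, 0


def catalog_from_table(modules: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Module catalog ``{module_id: KO set}`` from a long-format table."""
    cat = {mid: frozenset(grp["ko"]) for mid, grp in modules.groupby("module_id")}
    for mid, kos in cat.items():
        if not kos or kos == {""}:
            raise ValueError(f"module {mid!r} has an empty KO set")
    return cat


def module_integrity(genome_kos: Iterable[str],
                     catalog: Mapping[str, frozenset[str]]) -> dict[str, int]:
    """Integrity code per module for one genome's KO set."""
    if not catalog:
        raise ValueError("module catalog is empty")
    kos = set(genome_kos)
    out = {}
    for mid, members in catalog.items():
        if not members:
            raise ValueError(f"module {mid!r} has an empty KO set")
        missing = len(set(members) - kos)
        out[mid] = COMPLETE if missing == 0 else (PARTIAL if missing == 1 else ABSENT)
    return out


def genome_ko_sets(annotations: pd.DataFrame) -> dict[str, set[str]]:
    ann = annotations[annotations["ko"].fillna("") != ""]
    return {g: set(grp["ko"]) for g, grp in ann.groupby("genome_id")}


class ModuleIntegrityEncoder(BaseEstimator, TransformerMixin):
    """Transformer mapping an annotation table to a genomes x modules
    integrity matrix with values in {2, 1, 0}.

    Parameters
    ----------
    catalog : mapping of module id to KO set, or long-format DataFrame.
    """

    def __init__(self, catalog=None):
        self.catalog = catalog

    def _cat(self) -> dict[str, frozenset[str]]:
        if isinstance(self.catalog, pd.DataFrame):
            return catalog_from_table(self.catalog)
        if not self.catalog:
            raise ValueError("a module catalog is required")
        return {m: frozenset(k) for m, k in dict(self.catalog).items()}

    def fit(self, X: pd.DataFrame, y=None):
        cat = self._cat()
        ko_sets = genome_ko_sets(X)
        genomes = sorted(set(X["genome_id"]))
        rows = {g: module_integrity(ko_sets.get(g, set()), cat) for g in genomes}
        self.integrity_ = pd.DataFrame.from_dict(rows, orient="index")[sorted(cat)]
        self.integrity_.index.name = "genome_id"
        return self

    def transform(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        if not hasattr(self, "integrity_"):
            raise AttributeError("ModuleIntegrityEncoder is not fitted")
        return self.integrity_

    def fit_transform(self, X: pd.DataFrame, y=None, **fit_params) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def annotation_fraction(annotations: pd.DataFrame,
                        gene_totals: Mapping[str, int] | None = None) -> pd.Series:
    """Percent of each genome's genes carrying a KO label.

    When ``gene_totals`` is omitted the annotation table is assumed to list
    every gene (annotated rows carry a KO, unannotated rows an empty field).
    """
    has_ko = annotations["ko"].fillna("") != ""
    annotated = annotations[has_ko].groupby("genome_id").size()
    if gene_totals is None:
        totals = annotations.groupby("genome_id").size()
    else:
        totals = pd.Series(dict(gene_totals))
    if (totals == 0).any() or totals.isna().any():
        raise ValueError("every genome needs a positive total gene count")
    frac = 100.0 * annotated.reindex(totals.index, fill_value=0) / totals
    frac.name = "percent_annotated"
    return frac


def profile_counts(annotations: pd.DataFrame, grouping: str = "genome",
                   taxonomy: Mapping[str, str] | None = None,
                   label: str = "ko") -> pd.DataFrame:
    """Gene counts per functional category (KO or CAZy family) per group.

    ``grouping`` is 'genome' or a taxonomy rank prefix ('family', 'phylum'),
    in which case a genome -> taxonomy-string mapping must be supplied. Each
    labelled gene counts once per label; counts are additive over genomes.
    """
    if label not in annotations.columns:
        raise ValueError(f"no {label!r} column in the annotation table")
    ann = annotations[annotations[label].fillna("") != ""].copy()
    if grouping == "genome":
        ann["group"] = ann["genome_id"]
    elif grouping in ("family", "phylum"):
        if taxonomy is None:
            raise ValueError("taxonomy mapping required for rank grouping")
        prefix = {"family": "f__", "phylum": "p__"}[grouping]

        def rank_of(g: str) -> str:
            for part in str(taxonomy[g]).split(";"):
                if part.strip().startswith(prefix):
                    return part.strip()
            return "unclassified"

        ann["group"] = ann["genome_id"].map(rank_of)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    counts = (ann.groupby(["group", label]).size().rename("n_genes")
              .reset_index().sort_values(["group", label]).reset_index(drop=True))
    return counts


def mean_integrity_by_rank(integrity: pd.DataFrame,
                           taxonomy: Mapping[str, str], rank: str = "family"
                           ) -> pd.DataFrame:
    """Mean module-integrity matrix per taxonomy rank (heatmap input)."""
    prefix = {"family": "f__", "phylum": "p__"}[rank]

    def rank_of(g: str) -> str:
        for part in str(taxonomy[g]).split(";"):
            if part.strip().startswith(prefix):
                return part.strip()
        return "unclassified"

    groups = pd.Series({g: rank_of(g) for g in integrity.index})
    return integrity.groupby(groups).mean()
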