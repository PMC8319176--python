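"""Phenotype-guided comparative genomics over orthologous groups (OGs).

Given per-gene OG assignments for a set of genomes and a producer /
non-producer phenotype partition, the screen nominates candidate biosynthesis
genes by strict presence/absence logic: an OG qualifies when it is present in
*every* producer genome and absent from *every* non-producer genome, and its
representative annotation matches a keyword pattern (by default
acyltransferase/acetyltransferase, the enzymology expected for N-acylation of
an aminosulfonate head group).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "DEFAULT_KEYWORD_PATTERNS",
    "OGMatrix",
    "PhenotypePartition",
    "CandidateReport",
    "read_gene_records",
    "build_og_matrix",
    "core_ogs",
    "producer_unique_ogs",
    "representative_annotations",
    "filter_by_annotation",
    "run_screen",
    "load_candidate_table",
]

# Plain "acyltransferase" would miss GNAT-family acetyltransferases, which are
# plausible N-acyltransferases; both are searched case-insensitively.
DEFAULT_KEYWORD_PATTERNS = ("acyltransferase", "acetyltransferase")

RECORD_COLUMNS = ["gene_id", "genome_id", "og_id", "annotation", "cog_category"]


@dataclass
class OGMatrix:
    """Genome x OG boolean presence matrix (order-preserving)."""

    presence: pd.DataFrame  # index: genome_id, columns: og_id, dtype bool

    @property
    def genomes(self) -> list[str]:
        return list(self.presence.index)

    @property
    def ogs(self) -> list[str]:
        return list(self.presence.columns)


@dataclass(frozen=True)
class PhenotypePartition:
    producers: frozenset
    non_producers: frozenset

    def __post_init__(self):
        object.__setattr__(self, "producers", frozenset(self.producers))
        object.__setattr__(self, "non_producers", frozenset(self.non_producers))
        if not self.producers:
            raise ValueError("producer set must be non-empty")
        overlap = self.producers & self.non_producers
        if overlap:
            raise ValueError(f"genomes in both partitions: {sorted(overlap)}")


@dataclass
class CandidateReport:
    """Output of the presence/absence funnel, with Venn set sizes."""

    core_ogs: set
    shared_with_nonproducers: set
    producer_unique: set
    keyword_candidates: list  # ordered (og_id, representative annotation, locus tags)

    @property
    def venn_sizes(self) -> dict:
        return {
            "core": len(self.core_ogs),
            "shared_with_nonproducers": len(self.shared_with_nonproducers),
            "producer_unique": len(self.producer_unique),
            "keyword_candidates": len(self.keyword_candidates),
        }


def read_gene_records(path) -> pd.DataFrame:
    """Read a gene->OG assignment TSV (header with the five record columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(RECORD_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"gene-record table missing columns: {sorted(missing)}")
    return df


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("no gene records")
    bad = records.index[
        (records["gene_id"].astype(str).str.len() == 0)
        | (records["genome_id"].astype(str).str.len() == 0)
        | (records["og_id"].astype(str).str.len() == 0)
    ]
    if len(bad):
        raise ValueError(
            f"malformed gene records (empty id) at rows: {list(bad[:10])}"
        )
    return records


def build_og_matrix(records: pd.DataFrame) -> OGMatrix:
    """Collapse gene records to genome x OG presence (first-seen order)."""
    records = _validate_records(records)
    genomes = list(dict.fromkeys(records["genome_id"]))
    ogs = list(dict.fromkeys(records["og_id"]))
    presence = pd.crosstab(records["genome_id"], records["og_id"]) > 0
    presence = presence.reindex(index=genomes, columns=ogs, fill_value=False)
    return OGMatrix(presence=presence)


def core_ogs(matrix: OGMatrix, partition: PhenotypePartition) -> set:
    """OGs present in every producer genome."""
    missing = partition.producers - set(matrix.genomes)
    if missing:
        raise ValueError(f"producers absent from matrix: {sorted(missing)}")
    sub = matrix.presence.loc[sorted(partition.producers)]
    return set(sub.columns[sub.all(axis=0)])


def producer_unique_ogs(
    core: set, matrix: OGMatrix, partition: PhenotypePartition
) -> set:
    """Core OGs absent from every non-producer genome individually."""
    non = sorted(partition.non_producers & set(matrix.genomes))
    if not partition.non_producers:
        warnings.warn("no non-producer genomes: producer-unique set equals core set")
        return set(core)
    sub = matrix.presence.loc[non, sorted(core)]
    return set(sub.columns[~sub.any(axis=0)])


def representative_annotations(records: pd.DataFrame) -> pd.DataFrame:
    """Per-OG representative annotation: most frequent, ties lexicographic.

    Returns a frame indexed by og_id with ``annotation`` and ``locus_tags``
    (sorted unique gene ids carrying the OG).
    """
    records = _validate_records(records)
    if "annotation" not in records.columns:
        records = records.assign(annotation="")

    def _rep(group: pd.Series) -> str:
        counts = group.value_counts()
        top = counts.max()
        return sorted(counts.index[counts == top])[0]

    rep = records.groupby("og_id", sort=False)["annotation"].agg(_rep)
    tags = records.groupby("og_id", sort=False)["gene_id"].agg(
        lambda g: sorted(set(g))
    )
    return pd.DataFrame({"annotation": rep, "locus_tags": tags})


def filter_by_annotation(
    unique: set,
    records: pd.DataFrame,
    patterns=DEFAULT_KEYWORD_PATTERNS,
    matrix: OGMatrix | None = None,
) -> list:
    """OGs whose representative annotation matches any keyword pattern.

    Patterns are case-insensitive regular expressions (plain substrings work
    unchanged).  Output order follows the matrix OG order when a matrix is
    given, else first-seen record order.
    """
    patterns = list(patterns)
    if not patterns:
        raise ValueError("keyword pattern list must be non-empty")
    try:
        compiled = [re.compile(p, re.IGNORECASE) for p in patterns]
    except re.error as exc:
        raise ValueError(f"invalid keyword regex: {exc}") from exc
    reps = representative_annotations(records)
    order = matrix.ogs if matrix is not None else list(dict.fromkeys(records["og_id"]))
    out = []
    for og in order:
        if og not in unique or og not in reps.index:
            continue
        annotation = reps.loc[og, "annotation"]
        if any(rx.search(annotation) for rx in compiled):
            out.append((og, annotation, reps.loc[og, "locus_tags"]))
    return out


def run_screen(
    records: pd.DataFrame,
    partition: PhenotypePartition,
    patterns=DEFAULT_KEYWORD_PATTERNS,
) -> CandidateReport:
    """Compose the funnel: core -> producer-unique -> keyword candidates."""
    matrix = build_og_matrix(records)
    core = core_ogs(matrix, partition)
    unique = producer_unique_ogs(core, matrix, partition)
    candidates = filter_by_annotation(unique, records, patterns, matrix=matrix)
    return CandidateReport(
        core_ogs=core,
        shared_with_nonproducers=core - unique,
        producer_unique=unique,
        keyword_candidates=candidates,
    )


def load_candidate_table() -> pd.DataFrame:
    """The published 37-OG candidate table for SAL-producing roseobacters.

    Columns: og_id, locus_tag (Ruegeria pomeroyi DSS-3), cog_category,
    annotation.  Two rows are acyltransferase annotations (05CDD, the salA
    locus SPO0716, and 08UX5, a GNAT-family acetyltransferase).
    """
    with resources.files("salpipe.data").joinpath("candidate_ogs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)
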