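"""Marker-normalized metagenome abundance and depth-zone statistics.

Homolog abundances from gene-centric ocean surveys are made comparable
across samples by expressing them as a percentage of the median abundance of
ten prokaryotic single-copy marker genes — roughly "percent of cells carrying
the gene".  Depth zones (SRF surface, DCM deep chlorophyll maximum, MIX
mixed layer, MES mesopelagic) are compared with a Kruskal-Wallis test and
Dunn's post-hoc z tests under Holm's step-down correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEPTH_ZONES",
    "N_MARKERS",
    "DepthComparison",
    "normalize_abundance",
    "normalize_table",
    "kruskal_wallis",
    "dunn_posthoc",
    "compare_depth_zones",
    "taxonomy_fraction",
]

DEPTH_ZONES = ("SRF", "DCM", "MIX", "MES")
N_MARKERS = 10


@dataclass
class DepthComparison:
    H: float
    p: float
    pairwise: list  # (group_i, group_j, z, raw p, Holm-adjusted p)


def normalize_abundance(gene_abundance: float, marker_abundances) -> float:
    """100 x gene abundance / median of the ten marker abundances."""
    markers = np.asarray(list(marker_abundances), dtype=float)
    if markers.size != N_MARKERS:
        raise ValueError(
            f"expected {N_MARKERS} marker abundances, got {markers.size}"
        )
    if np.any(markers <= 0):
        raise ValueError("marker abundances must all be positive")
    if gene_abundance < 0:
        raise ValueError(f"negative gene abundance: {gene_abundance}")
    return 100.0 * gene_abundance / float(np.median(markers))


def normalize_table(table: pd.DataFrame, marker_columns) -> pd.DataFrame:
    """Add a ``normalized_pct`` column to a per-sample abundance table."""
    marker_columns = list(marker_columns)
    missing = [c for c in ["sample_id", "gene_abundance", *marker_columns]
               if c not in table.columns]
    if missing:
        raise ValueError(f"abundance table missing columns: {missing}")
    out = table.copy()
    out["normalized_pct"] = [
        normalize_abundance(row["gene_abundance"], [row[c] for c in marker_columns])
        for _, row in table.iterrows()
    ]
    return out


def _check_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    return arrays


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    arrays = _check_groups(groups)
    if np.ptp(np.concatenate(arrays)) == 0:
        # scipy raises on all-identical data; complete ties mean H = 0
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(groups, labels=None) -> list[tuple]:
    """Dunn's rank-sum z tests for all group pairs, Holm-adjusted.

    z_ij = (meanrank_i - meanrank_j) / sqrt[(N(N+1)/12 - T/(12(N-1)))
    (1/n_i + 1/n_j)] with tie correction T = sum(t^3 - t) over tied-value
    groups; two-sided normal p-values; Holm step-down across all pairs.
    """
    arrays = _check_groups(groups)
    if labels is None:
        labels = list(range(len(arrays)))
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    offset = 0
    for a in arrays:
        mean_ranks.append(ranks[offset: offset + a.size].mean())
        sizes.append(a.size)
        offset += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    pairs, zs, raws = [], [], []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = math.sqrt(variance_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        pairs.append((labels[i], labels[j]))
        zs.append(z)
        raws.append(2.0 * stats.norm.sf(abs(z)))
    adjusted = multipletests(raws, method="holm")[1] if raws else []
    return [
        (pi, pj, z, raw, adj)
        for (pi, pj), z, raw, adj in zip(pairs, zs, raws, adjusted)
    ]


def compare_depth_zones(
    table: pd.DataFrame,
    value_column: str = "normalized_pct",
    zone_column: str = "depth_zone",
) -> DepthComparison:
    """Kruskal-Wallis + Dunn/Holm over depth zones of a normalized table."""
    if zone_column not in table.columns or value_column not in table.columns:
        raise ValueError(
            f"table needs columns {zone_column!r} and {value_column!r}"
        )
    zones = [z for z in DEPTH_ZONES if z in set(table[zone_column])]
    zones += [z for z in dict.fromkeys(table[zone_column]) if z not in zones]
    groups = [table.loc[table[zone_column] == z, value_column].to_numpy() for z in zones]
    h, p = kruskal_wallis(groups)
    pairwise = dunn_posthoc(groups, labels=zones)
    return DepthComparison(H=h, p=p, pairwise=pairwise)


def taxonomy_fraction(
    hits: pd.DataFrame,
    rank: str,
    taxon: str,
    lineage_column: str = "lineage",
    ranks=("domain", "phylum", "class", "order", "family", "genus"),
) -> float:
    """Fraction of hits whose semicolon-delimited lineage has ``taxon`` at ``rank``."""
    if len(hits) == 0:
        raise ValueError("empty hit table")
    if rank not in ranks:
        raise ValueError(f"unknown rank {rank!r}; known: {list(ranks)}")
    idx = list(ranks).index(rank)
    matches = 0
    for lineage in hits[lineage_column]:
        fields = [f.strip() for f in str(lineage).split(";")]
        if idx < len(fields) and fields[idx] == taxon:
            matches += 1
    return matches / len(hits)
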