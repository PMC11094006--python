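"""Relative abundance bookkeeping for rMAGs and marker genes.

rMAG abundance is the fraction of a sample's mapped reads recruited by the
genome, with a strict 0.01% reporting floor (entries at or below the floor
are zeroed and the table is *not* re-normalised, so column sums may fall
short of 1).  Marker abundance is coverage-based: coverage = recruited
reads / gene length, and a marker's relative abundance is its coverage
divided by the summed coverage of all markers in the sample.  Linkage
metrics quantify how much of the marker-derived community the genome
catalogue captures, by representative count and by coverage weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .lineage import Lineage, rank_index
from .markers import MarkerCluster


@dataclass
class AbundanceMatrix:
    """Features x samples relative-abundance table with sample metadata."""

    data: pd.DataFrame  # rows = features, columns = samples
    metadata: Optional[pd.DataFrame] = field(default=None)  # indexed by sample

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    def to_long(self) -> pd.DataFrame:
        long = self.data.stack().rename("value").reset_index()
        long.columns = ["feature_id", "sample_id", "value"]
        return long


def rmag_abundance(
    mapped_reads: pd.DataFrame,
    total_reads: pd.Series,
    floor: float = 0.0001,
    metadata: Optional[pd.DataFrame] = None,
) -> AbundanceMatrix:
    """Read-mapping relative abundance of rMAGs with a strict floor.

    ``mapped_reads`` is rMAG x sample; abundance = mapped / total per
    sample.  Entries <= ``floor`` (i.e. not strictly *more than* 0.01% at
    the default) are set to 0; no re-normalisation afterwards.
    """
    totals = total_reads.reindex(mapped_reads.columns)
    if totals.isna().any():
        missing = totals[totals.isna()].index.tolist()
        raise ValueError(f"missing total read counts for samples: {missing}")
    if (totals <= 0).any():
        raise ValueError("total read counts must be positive")
    if (mapped_reads.values < 0).any():
        raise ValueError("mapped read counts must be non-negative")
    if (mapped_reads.gt(totals, axis=1)).any().any():
        raise ValueError("mapped reads exceed total reads in some sample")
    ab = mapped_reads.div(totals, axis=1).astype(float)
    ab[ab <= floor] = 0.0
    return AbundanceMatrix(data=ab, metadata=metadata)


def marker_abundance(
    read_counts: pd.DataFrame,
    gene_lengths: pd.Series,
    metadata: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, AbundanceMatrix]:
    """Coverage and coverage-normalised relative abundance of markers.

    ``read_counts`` is marker x sample; coverage = reads / gene length
    (bp), relative abundance = coverage / summed coverage per sample.
    Samples with zero total coverage get NaN abundances and a warning.
    """
    lengths = gene_lengths.reindex(read_counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"missing gene lengths for markers: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    coverage = read_counts.div(lengths, axis=0).astype(float)
    totals = coverage.sum(axis=0)
    dead = totals[totals == 0].index.tolist()
    if dead:
        warnings.warn(
            f"samples with zero marker coverage reported as missing: {dead}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = coverage.div(totals.replace(0, np.nan), axis=1)
    return coverage, AbundanceMatrix(data=rel.fillna(np.nan), metadata=metadata)


def linkage_metrics(
    mag_genes: Mapping[str, set[str]],
    clusters: Sequence[MarkerCluster],
    coverages: pd.Series,
) -> dict[str, float]:
    """How well the MAG catalogue captures the marker-derived community.

    ``mag_genes`` maps each MAG to the gene ids it contains; a cluster
    representative counts as "contained" if any of its member genes occurs
    in at least one MAG.  Returns percentages:

    - ``pct_mags_with_marker``: MAGs containing any representative's member
    - ``pct_markers_in_mags_by_count``: contained representatives / all
    - ``pct_markers_in_mags_by_coverage``: coverage-weighted version, with
      ``coverages`` indexed by centroid gene id
    """
    if not clusters:
        raise ValueError("representative set is empty")
    all_mag_genes = set().union(*mag_genes.values()) if mag_genes else set()
    contained = []
    for cl in clusters:
        members = set(cl.members)
        contained.append(bool(members & all_mag_genes))
    n_contained = sum(contained)
    cov = coverages.reindex([cl.centroid.gene_id for cl in clusters]).fillna(0.0)
    total_cov = float(cov.sum())
    cov_contained = float(cov[np.array(contained, dtype=bool)].sum())
    member_pool = set().union(*(set(cl.members) for cl in clusters))
    n_mags_with = sum(1 for genes in mag_genes.values() if genes & member_pool)
    return {
        "pct_mags_with_marker": 100.0 * n_mags_with / len(mag_genes)
        if mag_genes
        else 0.0,
        "pct_markers_in_mags_by_count": 100.0 * n_contained / len(clusters),
        "pct_markers_in_mags_by_coverage": 100.0 * cov_contained / total_cov
        if total_cov > 0
        else 0.0,
    }


def aggregate_by_rank(
    matrix: AbundanceMatrix,
    lineages: Mapping[str, Lineage],
    rank: str,
) -> AbundanceMatrix:
    """Sum feature abundances by their label at ``rank``.

    Features whose lineage stops above the rank (or that lack a lineage)
    pool into ``"Unclassified"``.  Per-sample column sums are preserved.
    """
    rank_index(rank)  # validates the rank name
    labels = []
    for feat in matrix.features:
        lin = lineages.get(feat)
        lab = lin.label_at(rank) if lin is not None else None
        labels.append(lab if lab is not None else "Unclassified")
    out = matrix.data.groupby(pd.Index(labels, name=rank)).sum()
    return AbundanceMatrix(data=out, metadata=matrix.metadata)


def fpkm(
    fragment_counts: pd.Series | pd.DataFrame,
    gene_lengths: pd.Series,
    library_size: float | pd.Series,
) -> pd.Series | pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM = count / (length_kb x library_size / 1e6).
    """
    lengths = gene_lengths.reindex(fragment_counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("all genes need positive lengths")
    if np.any(np.asarray(library_size) <= 0):
        raise ValueError("library size must be positive")
    length_kb = lengths / 1000.0
    if isinstance(fragment_counts, pd.DataFrame):
        per_kb = fragment_counts.div(length_kb, axis=0)
        return per_kb.div(pd.Series(library_size) / 1e6, axis=1)
    return fragment_counts / length_kb / (library_size / 1e6)
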