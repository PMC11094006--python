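"""Ribosomal-protein S3 (rpS3) marker identification and clustering.

rpS3 is a universal single-copy gene that doubles as a community-profiling
marker: every cell carries exactly one copy, so the set of distinct rpS3
sequences in a metagenome approximates the set of species present.  This
module takes *candidate* rpS3 gene calls (sequence + an upstream search
score, both inputs) through a three-step screen — score filter, translated
length filter, confirmation against a labelled reference set — and collapses
the confirmed genes into species-level representatives by greedy centroid
clustering at high nucleotide identity (99% by default, i.e. roughly the
species boundary for this gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align

VALID_BASES = frozenset("ACGT")

#: Alignment scoring used throughout: match +1, mismatch -1, gap -2.
_MATCH, _MISMATCH, _GAP = 1.0, -1.0, -2.0


@dataclass
class MarkerRecord:
    """One candidate or confirmed rpS3 gene observed in one sample."""

    gene_id: str
    sample_id: str
    sequence: str
    score: float
    read_count: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty sequence")
        if self.score < 0:
            raise ValueError(f"{self.gene_id}: negative search score")
        if self.read_count < 0:
            raise ValueError(f"{self.gene_id}: negative read count")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def length_aa(self) -> int:
        """Translated length in amino acids (frame 1, standard code)."""
        return len(self.sequence) // 3

    def coverage(self, read_length: int = 150) -> float:
        """Read coverage of the gene: reads x read_length / gene_length."""
        return self.read_count * read_length / self.length_bp


@dataclass
class MarkerCluster:
    """A species-level representative and its member genes."""

    centroid: MarkerRecord
    members: list[str] = field(default_factory=list)
    threshold: float = 0.99

    @property
    def size(self) -> int:
        return len(self.members)


def _check_sequence(seq: str, name: str = "sequence") -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(
            f"{name} contains invalid characters {sorted(bad)}; "
            "only uppercase A/C/G/T are accepted"
        )


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = _MATCH
    aligner.mismatch_score = _MISMATCH
    aligner.open_gap_score = _GAP
    aligner.extend_gap_score = _GAP
    return aligner


_GLOBAL_ALIGNER = _aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment nucleotide identity between two sequences.

    Identity is counted over *all* columns of an optimal Needleman-Wunsch
    alignment (match +1, mismatch -1, gap -2), with gap columns counting as
    mismatches, so the value lies in [0, 1] and ``identity(a, a) == 1``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_sequence(a, "first sequence")
    _check_sequence(b, "second sequence")
    if a == b:
        return 1.0
    alignment = _GLOBAL_ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def screen_candidates(
    candidates: Sequence[MarkerRecord],
    score_min: float = 40.0,
    len_min_aa: int = 60,
) -> list[MarkerRecord]:
    """Score and translated-length screen for candidate rpS3 genes.

    Keeps records with search score >= ``score_min`` *and* translated length
    >= ``len_min_aa`` amino acids (both filters drop strictly-below values,
    so the boundary values themselves pass).  Input order is preserved.
    """
    if score_min <= 0 or len_min_aa <= 0:
        raise ValueError("screening thresholds must be positive")
    return [
        rec
        for rec in candidates
        if rec.score >= score_min and rec.length_aa >= len_min_aa
    ]


def confirm_markers(
    screened: Sequence[MarkerRecord],
    reference_markers: Iterable[tuple[str, str]],
    min_identity: float = 0.60,
) -> list[MarkerRecord]:
    """Keep screened records whose best identity to any reference passes.

    ``reference_markers`` yields ``(ref_id, sequence)`` pairs; a record is
    confirmed as rpS3 iff its best global-alignment identity to any
    reference sequence is >= ``min_identity``.
    """
    refs = [seq for _, seq in reference_markers]
    if not refs:
        raise ValueError("reference marker set is empty")
    confirmed = []
    for rec in screened:
        best = 0.0
        for ref in refs:
            best = max(best, pairwise_identity(rec.sequence, ref))
            if best >= min_identity:
                break
        if best >= min_identity:
            confirmed.append(rec)
    return confirmed


def cluster_representatives(
    confirmed: Sequence[MarkerRecord],
    identity: float = 0.99,
) -> list[MarkerCluster]:
    """Greedy length-sorted centroid clustering of confirmed markers.

    Records are processed by decreasing sequence length (ties broken by
    lexicographic gene_id for reproducibility).  Each record is compared
    exhaustively against every existing centroid and joins the
    earliest-founded centroid with identity >= the threshold; otherwise it
    founds a new cluster.  The result is a partition of the input.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity threshold must lie in (0, 1]")
    ordered = sorted(confirmed, key=lambda r: (-r.length_bp, r.gene_id))
    clusters: list[MarkerCluster] = []
    for rec in ordered:
        _check_sequence(rec.sequence, rec.gene_id)
        home = None
        for cluster in clusters:
            if pairwise_identity(rec.sequence, cluster.centroid.sequence) >= identity:
                home = cluster
                break
        if home is None:
            clusters.append(
                MarkerCluster(centroid=rec, members=[rec.gene_id], threshold=identity)
            )
        else:
            home.members.append(rec.gene_id)
    return clusters
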