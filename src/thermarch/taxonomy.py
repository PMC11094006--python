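"""Self-consistent marker taxonomy: curation, classification, LCA fallback.

The reference database is curated in four ordered stages before any query
is classified: a strict length floor (> 300 bp), exact-duplicate collapse,
a leave-one-out self-consistency screen (each sequence is classified
against the database *without itself*; it is discarded if any rank
assigned with confidence >= 0.60 disagrees with its recorded lineage — a
guard against mislabelled references), and finally 99%-identity clustering
down to species-level representatives.

Classification follows the classic RDP naive-Bayes recipe: overlapping
8-mers are the features, each bootstrap replicate scores ceil(W/8) words
resampled with replacement from the query's W words, and the per-rank
confidence is the fraction of replicates whose winning reference agrees
with the full-data winner at that rank.  Queries whose phylum cannot be
assigned confidently fall back to a top-k best-hit search: the deepest
rank on which the top five hits (by global-alignment identity) concord.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .lineage import RANKS, Lineage, deepest_concordant
from .markers import MarkerRecord, cluster_representatives, pairwise_identity

WORD_SIZE = 8


@dataclass
class RefEntry:
    ref_id: str
    sequence: str
    lineage: Lineage


@dataclass
class CuratedReferenceDB:
    """Species-level representative sequences with lineages and a curation log."""

    entries: list[RefEntry]
    curation_log: dict[str, int] = field(default_factory=dict)
    word_size: int = WORD_SIZE

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference database is empty")
        self._words = [
            _word_set(e.sequence, self.word_size) for e in self.entries
        ]

    def __len__(self) -> int:
        return len(self.entries)

    def word_sets(self) -> list[set[str]]:
        return self._words


def _word_set(sequence: str, k: int) -> set[str]:
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than the word size ({k})")
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


def _log_word_probs(
    query_words: list[str], ref_words: Sequence[set[str]]
) -> np.ndarray:
    """log P(word | reference) matrix, shape (n_refs, n_query_words).

    Word priors follow the RDP formulation: for a word seen in n of N
    references, the prior is (n + 0.5) / (N + 1); the per-reference
    conditional is (m + prior) / (M + 1) with m in {0, 1} occurrences in
    the reference's M = 1 sequence.
    """
    n_refs = len(ref_words)
    priors = np.array(
        [
            (sum(1 for ws in ref_words if w in ws) + 0.5) / (n_refs + 1.0)
            for w in query_words
        ]
    )
    contains = np.array(
        [[w in ws for w in query_words] for ws in ref_words], dtype=float
    )
    return np.log((contains + priors) / 2.0)


def _bootstrap_classify(
    query: str,
    entries: Sequence[RefEntry],
    ref_words: Sequence[set[str]],
    confidence: float,
    bootstraps: int,
    seed: int,
) -> Lineage:
    if len(query) < WORD_SIZE:
        raise ValueError("query shorter than the classifier word size (8)")
    query_words = sorted(_word_set(query, WORD_SIZE))
    logp = _log_word_probs(query_words, ref_words)
    full_scores = logp.sum(axis=1)
    winner = int(np.argmax(full_scores))
    winner_lineage = entries[winner].lineage

    rng = np.random.default_rng(seed)
    n_words = len(query_words)
    n_sub = math.ceil(n_words / WORD_SIZE)
    agree = np.zeros(len(RANKS))
    for _ in range(bootstraps):
        idx = rng.integers(0, n_words, size=n_sub)
        rep_winner = int(np.argmax(logp[:, idx].sum(axis=1)))
        rep_lineage = entries[rep_winner].lineage
        for r in range(len(RANKS)):
            if (
                r < rep_lineage.depth
                and r < winner_lineage.depth
                and rep_lineage.labels[r] == winner_lineage.labels[r]
            ):
                agree[r] += 1
    conf = agree / bootstraps
    depth = 0
    for r in range(winner_lineage.depth):
        if conf[r] >= confidence:
            depth = r + 1
        else:
            break
    return Lineage(
        winner_lineage.labels[:depth], tuple(round(c, 4) for c in conf[:depth])
    )


def classify_rdp(
    query: str,
    db: CuratedReferenceDB,
    confidence: float = 0.60,
    bootstraps: int = 100,
    seed: int = 0,
) -> Lineage:
    """Naive-Bayes bootstrap classification of a query marker sequence.

    Returns the full-data winner's lineage truncated at the deepest rank
    whose bootstrap confidence meets the threshold, with per-rank
    confidences attached.  Deterministic for a fixed seed.
    """
    return _bootstrap_classify(
        query, db.entries, db.word_sets(), confidence, bootstraps, seed
    )


def assign_lca_topk(query: str, db: CuratedReferenceDB, k: int = 5) -> Lineage:
    """Deepest concordant rank of the top-k hits by alignment identity.

    With fewer than k references all are used; identity ties at the k-th
    position include every tied hit (the conservative, shallower choice).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    scored = sorted(
        ((pairwise_identity(query, e.sequence), e) for e in db.entries),
        key=lambda t: (-t[0], t[1].ref_id),
    )
    kk = min(k, len(scored))
    cutoff = scored[kk - 1][0]
    top = [e for ident, e in scored if ident >= cutoff]
    return deepest_concordant(e.lineage for e in top)


@dataclass
class TaxonomyAssignment:
    lineage: Lineage
    method: str  # "rdp" | "lca"


def assign_taxonomy(
    query: str,
    db: CuratedReferenceDB,
    confidence: float = 0.60,
    k: int = 5,
    bootstraps: int = 100,
    seed: int = 0,
) -> TaxonomyAssignment:
    """Bootstrap classification with a top-k LCA fallback.

    If the classifier cannot assign the query at the phylum level or
    deeper with the required confidence, the top-k concordance assignment
    is returned instead.
    """
    lineage = classify_rdp(query, db, confidence, bootstraps, seed)
    if lineage.depth >= 2:
        return TaxonomyAssignment(lineage=lineage, method="rdp")
    return TaxonomyAssignment(lineage=assign_lca_topk(query, db, k), method="lca")


def curate_reference_db(
    raw: Iterable[RefEntry] | Iterable,
    min_len_bp: int = 300,
    species_identity: float = 0.99,
    confidence: float = 0.60,
    bootstraps: int = 100,
    seed: int = 0,
) -> CuratedReferenceDB:
    """Build a self-consistent species-level reference database.

    Stages, in order: strict length filter (> min_len_bp), exact-duplicate
    collapse, leave-one-out self-consistency screen, and greedy
    99%-identity clustering to species-level representatives.  Raises if
    no sequence survives, with per-stage removal counts in the message.
    """
    entries = [
        e if isinstance(e, RefEntry) else RefEntry(e.ref_id, e.sequence, e.lineage)
        for e in raw
    ]
    if not entries:
        raise ValueError("raw reference set is empty")
    for e in entries:
        if not e.lineage.is_complete():
            raise ValueError(f"{e.ref_id}: reference lineages must be 7-rank complete")
    log = {"input": len(entries)}

    kept = [e for e in entries if len(e.sequence) > min_len_bp]
    log["removed_length"] = len(entries) - len(kept)

    seen: dict[str, RefEntry] = {}
    for e in sorted(kept, key=lambda e: e.ref_id):
        seen.setdefault(e.sequence, e)
    deduped = sorted(seen.values(), key=lambda e: e.ref_id)
    log["removed_duplicate"] = len(kept) - len(deduped)

    consistent: list[RefEntry] = []
    if len(deduped) > 1:
        words = [_word_set(e.sequence, WORD_SIZE) for e in deduped]
        for i, e in enumerate(deduped):
            rest = deduped[:i] + deduped[i + 1 :]
            rest_words = words[:i] + words[i + 1 :]
            assigned = _bootstrap_classify(
                e.sequence, rest, rest_words, confidence, bootstraps, seed + i
            )
            # Species-level labels are exempt: with one representative per
            # species, a leave-one-out assign-back can never return the
            # withheld species itself, so only genus and above are checked.
            ok = all(
                assigned.labels[r] == e.lineage.labels[r]
                for r in range(min(assigned.depth, e.lineage.depth, 6))
            )
            if ok:
                consistent.append(e)
    else:
        consistent = deduped
    log["removed_inconsistent"] = len(deduped) - len(consistent)

    if not consistent:
        raise ValueError(f"all references discarded during curation: {log}")

    records = [
        MarkerRecord(gene_id=e.ref_id, sample_id="db", sequence=e.sequence, score=0.0)
        for e in consistent
    ]
    by_id = {e.ref_id: e for e in consistent}
    clusters = cluster_representatives(records, identity=species_identity)
    reps = [by_id[c.centroid.gene_id] for c in clusters]
    log["species_representatives"] = len(reps)
    return CuratedReferenceDB(entries=reps, curation_log=log)
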