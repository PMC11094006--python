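"""Seven-rank GTDB-style taxonomic lineages.

A lineage is an ordered path ``domain -> phylum -> class -> order -> family ->
genus -> species`` in which ranks are filled contiguously from the domain
downward (a lineage may stop early, e.g. at the family level, but can never
skip a rank).  Labels carry the conventional one-letter prefixes
``d__, p__, c__, o__, f__, g__, s__``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
PREFIXES: tuple[str, ...] = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


def rank_index(rank: str) -> int:
    """Position of *rank* in the seven-rank hierarchy (domain = 0)."""
    try:
        return _RANK_INDEX[rank]
    except KeyError:
        raise ValueError(
            f"unknown rank {rank!r}; expected one of {', '.join(RANKS)}"
        ) from None


@dataclass(frozen=True)
class Lineage:
    """An ordered, contiguous rank-label path with optional confidences.

    Parameters
    ----------
    labels:
        Bare labels (without prefixes), domain first, at most seven.
    confidences:
        Optional per-rank assignment confidences in [0, 1], aligned with
        ``labels``.
    """

    labels: tuple[str, ...]
    confidences: Optional[tuple[float, ...]] = field(default=None)

    def __post_init__(self) -> None:
        if len(self.labels) > len(RANKS):
            raise ValueError("a lineage has at most seven ranks")
        if any(not lab for lab in self.labels):
            raise ValueError("rank labels must be non-empty and contiguous")
        if self.confidences is not None:
            if len(self.confidences) != len(self.labels):
                raise ValueError("confidences must align with labels")
            if any(not 0.0 <= c <= 1.0 for c in self.confidences):
                raise ValueError("confidences must lie in [0, 1]")

    @property
    def depth(self) -> int:
        """Number of assigned ranks (0 = unassigned, 7 = species-level)."""
        return len(self.labels)

    @property
    def deepest_rank(self) -> Optional[str]:
        return RANKS[self.depth - 1] if self.depth else None

    def label_at(self, rank: str) -> Optional[str]:
        """Label at *rank*, or ``None`` if the lineage stops above it."""
        i = rank_index(rank)
        return self.labels[i] if i < self.depth else None

    def truncate(self, rank: str) -> "Lineage":
        """Lineage cut down to *rank* (inclusive)."""
        n = rank_index(rank) + 1
        conf = self.confidences[:n] if self.confidences is not None else None
        return Lineage(self.labels[:n], conf)

    def is_complete(self) -> bool:
        return self.depth == len(RANKS)

    def to_string(self) -> str:
        """Semicolon-joined GTDB-style string, e.g. ``d__Archaea;p__...``."""
        return ";".join(p + lab for p, lab in zip(PREFIXES, self.labels))

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        labels = []
        parts = [p for p in text.strip().split(";") if p]
        for i, part in enumerate(parts):
            part = part.strip()
            if i >= len(PREFIXES):
                raise ValueError(f"too many ranks in {text!r}")
            if not part.startswith(PREFIXES[i]):
                raise ValueError(
                    f"rank {i} of {text!r} lacks the {PREFIXES[i]!r} prefix"
                )
            labels.append(part[len(PREFIXES[i]):])
        return cls(tuple(labels))

    def __iter__(self):
        return iter(self.labels)


def deepest_concordant(lineages: Iterable[Lineage]) -> Lineage:
    """Lowest common ancestor of several lineages.

    Returns the lineage truncated at the deepest rank on which every input
    carries the same label, with all shallower ranks filled.  An empty input
    or immediate disagreement at the domain yields an empty lineage.
    """
    lins = list(lineages)
    if not lins:
        return Lineage(())
    shared: list[str] = []
    for i in range(min(l.depth for l in lins)):
        labels = {l.labels[i] for l in lins}
        if len(labels) != 1:
            break
        shared.append(next(iter(labels)))
    return Lineage(tuple(shared))
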