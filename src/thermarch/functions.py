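"""Order-level pathway presence, metabolic-weight scores, CAZyme summaries.

A pathway is *complete* in an archaeal order if at least one of the
order's reliable rMAGs (those with fewer than 200 scaffolds) carries every
required gene; *partial* if any required gene occurs anywhere in the
order's reliable rMAGs but no single genome has the full set; *absent*
otherwise.  Pathway definitions are flat KO lists shipped as an editable
TSV — configuration, not biology claims.

The metabolic-weight (MW) score expresses the contribution of one function
relative to all functions in the community: for function f in sample s,

    MW(f, s) = 100 x sum_{g encodes f} a(g, s) / sum_{f'} sum_{g encodes f'} a(g, s)

where a(g, s) is the relative abundance of genome g.  A genome encoding
several functions contributes to each of their numerators, and scores sum
to 100 per sample.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .lineage import Lineage

_KO_RE = re.compile(r"^K\d{5}$")

#: Tri-state presence codes used in the emitted matrix.
COMPLETE, PARTIAL, ABSENT = 2, 1, 0


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    name: str
    kos: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.kos:
            raise ValueError(f"{self.pathway_id}: empty required gene set")
        bad = [k for k in self.kos if not _KO_RE.match(k)]
        if bad:
            raise ValueError(f"{self.pathway_id}: malformed KO ids {bad}")


def load_pathways(path: Optional[Path | str] = None) -> list[PathwayDefinition]:
    """Load pathway definitions from TSV (pathway_id, name, comma-joined kos).

    With no path, the small bundled default set is used.
    """
    if path is None:
        with resources.files("thermarch.data").joinpath("pathways.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        PathwayDefinition(
            pathway_id=row.pathway_id,
            name=row.name,
            kos=tuple(k.strip() for k in str(row.kos).split(",") if k.strip()),
        )
        for row in df.itertuples(index=False)
    ]


def pathway_presence(
    annotations: pd.DataFrame,
    lineages: Mapping[str, Lineage],
    pathways: Sequence[PathwayDefinition],
    scaffold_counts: Mapping[str, int],
    max_scaffolds: int = 200,
) -> pd.DataFrame:
    """Order x pathway tri-state presence matrix (2 complete, 1 partial, 0 absent).

    ``annotations`` needs columns ``rmag_id`` and ``ko``; rMAGs with
    ``scaffold_counts`` >= ``max_scaffolds`` are excluded from evaluation
    (strictly fewer than 200 scaffolds qualify, by default).  Every rMAG
    must have an order assignment in ``lineages``.
    """
    if not pathways:
        raise ValueError("no pathway definitions supplied")
    rmags = sorted(set(annotations["rmag_id"]))
    missing = [r for r in rmags if r not in scaffold_counts]
    if missing:
        raise ValueError(f"missing scaffold counts for rMAGs: {missing[:5]}")
    orders: dict[str, str] = {}
    for rmag in rmags:
        lin = lineages.get(rmag)
        order = lin.label_at("order") if lin is not None else None
        if order is None:
            raise ValueError(f"{rmag}: no order-level lineage")
        orders[rmag] = order
    qualifying = [r for r in rmags if scaffold_counts[r] < max_scaffolds]
    ko_by_rmag = {
        rmag: set(sub["ko"].replace("", np.nan).dropna())
        for rmag, sub in annotations.groupby("rmag_id")
    }
    order_labels = sorted(set(orders.values()))
    out = pd.DataFrame(
        ABSENT, index=order_labels, columns=[p.pathway_id for p in pathways], dtype=int
    )
    out.index.name = "order"
    for pw in pathways:
        required = set(pw.kos)
        for order in order_labels:
            members = [r for r in qualifying if orders[r] == order]
            if any(required <= ko_by_rmag.get(r, set()) for r in members):
                out.loc[order, pw.pathway_id] = COMPLETE
            elif any(required & ko_by_rmag.get(r, set()) for r in members):
                out.loc[order, pw.pathway_id] = PARTIAL
    return out


def mw_score(
    function_map: Mapping[str, set[str]] | pd.DataFrame,
    abundance: AbundanceMatrix,
) -> pd.DataFrame:
    """Metabolic-weight scores (percent) per function per sample.

    ``function_map`` maps each genome to the functions it encodes (or is
    an annotation frame with ``rmag_id`` and ``ko`` columns, in which case
    KOs are the functions).  Scores within a sample sum to 100; samples
    with no annotated abundance are dropped with a warning.
    """
    if isinstance(function_map, pd.DataFrame):
        function_map = {
            rmag: set(sub["ko"].replace("", np.nan).dropna())
            for rmag, sub in function_map.groupby("rmag_id")
        }
    functions = sorted(set().union(*function_map.values())) if function_map else []
    if not functions:
        raise ValueError("no functions found in the annotation map")
    raw = pd.DataFrame(0.0, index=functions, columns=abundance.samples)
    for genome, funcs in function_map.items():
        if genome not in abundance.data.index:
            continue
        for f in funcs:
            raw.loc[f] += abundance.data.loc[genome]
    totals = raw.sum(axis=0)
    dead = totals[totals == 0].index.tolist()
    if dead:
        warnings.warn(
            f"samples with no annotated abundance dropped from MW-scores: {dead}",
            stacklevel=2,
        )
        raw = raw.drop(columns=dead)
        totals = totals.drop(dead)
    return 100.0 * raw.div(totals, axis=1)


def cazyme_summary(
    annotations: pd.DataFrame,
    rmag_groups: Mapping[str, str],
) -> tuple[pd.Series, pd.Series]:
    """CAZyme family richness per spring group and gene counts per rMAG.

    ``annotations`` needs ``rmag_id`` and ``cazy_family`` columns;
    ``rmag_groups`` maps each rMAG to its spring group (e.g. the pH class
    of its sample of origin).  Returns (distinct families per group,
    CAZyme gene count per rMAG); a group's family set is the union over
    its member rMAGs.
    """
    caz = annotations[annotations["cazy_family"].astype(str) != ""].copy()
    caz = caz.dropna(subset=["cazy_family"])
    per_rmag = (
        caz.groupby("rmag_id")["cazy_family"].size()
        .reindex(sorted(set(annotations["rmag_id"])), fill_value=0)
        .rename("n_cazymes")
    )
    caz["group"] = caz["rmag_id"].map(rmag_groups)
    families = (
        caz.dropna(subset=["group"])
        .groupby("group")["cazy_family"]
        .nunique()
        .rename("n_families")
    )
    return families, per_rmag
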