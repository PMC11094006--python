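"""Synthetic geothermal-spring communities with planted ground truth.

Every input the pipeline consumes can be generated here: a reference
taxonomy with rank-structured sequence divergence, labelled marker-gene
references, per-sample marker observations with planted compositions,
genome bins with known completeness/contamination and planted depth
outliers, annotation tables with planted pathway content, and compositional
count tables with planted basis correlations for network inference.

Sequence evolution uses a Jukes-Cantor "scatter" parameterisation: along a
branch with retention factor ``lam``, each site is redrawn uniformly from
ACGT with probability ``1 - lam``.  Retention factors compose
multiplicatively along paths, and the expected identity between two leaves
whose last common ancestor has leaf-retention ``lam`` is exactly
``1/4 + (3/4) lam**2`` (uniform redraws can restore the original base, so
homoplasy is accounted for analytically).  Per-rank sibling-identity
targets are inverted through this formula, which keeps realized pairwise
identities within a few points of their targets at any divergence depth.

The generator is deterministic: a fixed seed yields byte-identical output
files.  Sequences are uppercase ACGT only; no indels are introduced by
default (``indel_rate`` exercises the aligner when set).  Read-level error
models, assembly and binning artefacts are deliberately not emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lineage import RANKS, Lineage
from .qc import DPANN_MARKERS_48, STANDARD_MARKERS_122, GenomeBin, Scaffold

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Expected sequence identity between siblings at each rank (fraction).
#: "Siblings at the genus rank" are two species of the same genus, and so
#: on upward; values must strictly decrease from species toward domain.
DEFAULT_SIBLING_IDENTITY: dict[str, float] = {
    "species": 0.995,
    "genus": 0.97,
    "family": 0.93,
    "order": 0.89,
    "class": 0.85,
    "phylum": 0.80,
    "domain": 0.74,
}

_RANK_LABEL_STEMS = {
    "domain": "Archaea",
    "phylum": "Phy",
    "class": "Cla",
    "order": "Ord",
    "family": "Fam",
    "genus": "Gen",
    "species": "Sp",
}


# ---------------------------------------------------------------------------
# sequence helpers


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        codes[arr == b] = i
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return codes


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT sequence of the given length."""
    if length <= 0:
        raise ValueError("length must be positive")
    return _decode(rng.integers(0, 4, size=length).astype(np.uint8))


def _jc_scatter(codes: np.ndarray, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve along one branch: redraw each site uniformly with prob 1-lam."""
    out = codes.copy()
    mask = rng.random(codes.size) >= lam
    n = int(mask.sum())
    if n:
        out[mask] = rng.integers(0, 4, size=n).astype(np.uint8)
    return out


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site to a *different* base with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    codes = _encode(seq)
    mask = rng.random(codes.size) < rate
    n = int(mask.sum())
    if n:
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return _decode(codes)


def _lam_for_identity(t: float) -> float:
    """Invert expected leaf-pair identity t = 1/4 + (3/4) lam^2."""
    if not 0.25 < t <= 1.0:
        raise ValueError("sibling identity must lie in (0.25, 1]")
    return math.sqrt((t - 0.25) / 0.75)


# ---------------------------------------------------------------------------
# reference taxonomy


@dataclass
class ReferenceTaxonomy:
    """Species entries with full 7-rank lineages forming a tree."""

    lineages: tuple[Lineage, ...]
    sibling_identity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIBLING_IDENTITY)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.lineages:
            raise ValueError("taxonomy must contain at least one species")
        parent: dict[tuple[str, str], str] = {}
        for lin in self.lineages:
            if not lin.is_complete():
                raise ValueError(f"lineage {lin.to_string()} is not 7-rank complete")
            for i in range(1, lin.depth):
                key = (RANKS[i], lin.labels[i])
                if parent.setdefault(key, lin.labels[i - 1]) != lin.labels[i - 1]:
                    raise ValueError(
                        f"label {lin.labels[i]!r} has two parents; not a tree"
                    )
        species = [l.labels[-1] for l in self.lineages]
        if len(species) != len(set(species)):
            raise ValueError("species labels must be unique")
        vals = [self.sibling_identity[r] for r in RANKS]
        # RANKS runs domain->species, so identities must strictly increase.
        if any(a >= b for a, b in zip(vals, vals[1:])):
            raise ValueError(
                "sibling identities must strictly decrease from species toward domain"
            )

    @property
    def species(self) -> list[str]:
        return [l.labels[-1] for l in self.lineages]

    def lineage_of(self, species: str) -> Lineage:
        for lin in self.lineages:
            if lin.labels[-1] == species:
                return lin
        raise KeyError(species)


def _partition(
    items: list[int], n_groups: int, rng: np.random.Generator
) -> list[list[int]]:
    """Random partition of items into exactly n_groups non-empty groups."""
    order = [items[i] for i in rng.permutation(len(items))]
    groups: list[list[int]] = [[order[g]] for g in range(n_groups)]
    for it in order[n_groups:]:
        groups[int(rng.integers(0, n_groups))].append(it)
    for g in groups:
        g.sort()
    return groups


def make_reference_taxonomy(
    n_phyla: int,
    n_species: int,
    seed: int,
    sibling_identity: Optional[dict[str, float]] = None,
) -> ReferenceTaxonomy:
    """Random single-domain taxonomy with n_species leaves over n_phyla phyla.

    Below the phylum level, each group is recursively split into a random
    number of children at the next rank, so intermediate ranks have
    realistic, uneven sizes.  Deterministic for a fixed seed.
    """
    if n_phyla < 1 or n_species < n_phyla:
        raise ValueError("need n_species >= n_phyla >= 1")
    rng = np.random.default_rng(seed)
    counters = {r: 0 for r in RANKS}

    def fresh_label(rank: str) -> str:
        counters[rank] += 1
        stem = _RANK_LABEL_STEMS[rank]
        return f"{stem}{counters[rank]:03d}" if rank != "domain" else stem

    species_idx = list(range(n_species))
    labels_by_species: dict[int, list[str]] = {i: ["Archaea"] for i in species_idx}

    def split(group: list[int], rank_i: int) -> None:
        rank = RANKS[rank_i]
        if rank == "species":
            for sp in group:
                labels_by_species[sp].append(fresh_label("species"))
            return
        if rank_i == 1 and rank == "phylum":
            n_children = n_phyla
        else:
            n_children = 1 + int(rng.binomial(min(len(group), 4) - 1, 0.5))
        for child in _partition(group, n_children, rng):
            lab = fresh_label(rank)
            for sp in child:
                labels_by_species[sp].append(lab)
            split(child, rank_i + 1)

    split(species_idx, 1)
    lineages = tuple(
        Lineage(tuple(labels_by_species[i])) for i in sorted(labels_by_species)
    )
    ident = dict(sibling_identity) if sibling_identity else dict(DEFAULT_SIBLING_IDENTITY)
    return ReferenceTaxonomy(lineages=lineages, sibling_identity=ident)


# ---------------------------------------------------------------------------
# marker references


@dataclass
class ReferenceMarker:
    ref_id: str
    sequence: str
    lineage: Lineage


@dataclass
class MarkerReferenceSet:
    """Labelled species-level marker sequences (a curated-database stand-in)."""

    markers: list[ReferenceMarker]

    def __post_init__(self) -> None:
        self._by_species = {m.lineage.labels[-1]: m for m in self.markers}

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def pairs(self) -> list[tuple[str, str]]:
        return [(m.ref_id, m.sequence) for m in self.markers]

    def by_species(self, species: str) -> ReferenceMarker:
        return self._by_species[species]

    def lineage_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ref_id": [m.ref_id for m in self.markers],
                "lineage": [m.lineage.to_string() for m in self.markers],
            }
        )

    def write_fasta(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            for m in self.markers:
                fh.write(f">{m.ref_id}\n{m.sequence}\n")

    def write_tsv(self, path: Path | str) -> None:
        self.lineage_table().to_csv(path, sep="\t", index=False)


def _evolve_over_tree(
    taxonomy: ReferenceTaxonomy,
    length: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One sequence per species, evolved down the taxonomy's rank tree.

    A node at rank r carries the leaf-retention factor lam_r derived from
    the sibling-identity target at r; the branch into a child at rank r+1
    applies retention lam_r / lam_(r+1) so that leaf-to-leaf retention for
    a pair diverging at rank r composes to exactly lam_r**2.
    """
    ident = taxonomy.sibling_identity
    lam = {r: _lam_for_identity(ident[r]) for r in RANKS[:-1]}  # domain..genus

    root = rng.integers(0, 4, size=length).astype(np.uint8)
    node_seq: dict[tuple[str, str], np.ndarray] = {("domain", "Archaea"): root}
    leaf_seq: dict[str, np.ndarray] = {}

    # Children of each node, in the deterministic order of the lineage list.
    children: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for lin in taxonomy.lineages:
        for i in range(1, lin.depth):
            parent = (RANKS[i - 1], lin.labels[i - 1])
            child = (RANKS[i], lin.labels[i])
            sibs = children.setdefault(parent, [])
            if child not in sibs:
                sibs.append(child)

    def walk(node: tuple[str, str]) -> None:
        rank, _ = node
        for child in children.get(node, []):
            crank = child[0]
            if crank == "species":
                branch = lam[rank]  # remaining retention down to the leaf
                leaf_seq[child[1]] = _jc_scatter(node_seq[node], branch, rng)
            else:
                branch = lam[rank] / lam[crank]
                node_seq[child] = _jc_scatter(node_seq[node], branch, rng)
                walk(child)

    walk(("domain", "Archaea"))
    return leaf_seq


def synthesize_marker_references(
    taxonomy: ReferenceTaxonomy,
    gene_length: int = 900,
    seed: int = 0,
    indel_rate: float = 0.0,
) -> MarkerReferenceSet:
    """One nucleotide marker sequence per species, rank-structured.

    Realized pairwise identities follow the taxonomy's sibling-identity
    parameters: same-genus pairs are more identical than
    same-family-different-genus pairs, and so on.  ``indel_rate`` optionally
    deletes that fraction of sites independently per species (default 0) to
    exercise gapped alignment downstream.
    """
    if gene_length < 3:
        raise ValueError("gene_length must be at least one codon (3 bp)")
    rng = np.random.default_rng(seed)
    leaves = _evolve_over_tree(taxonomy, gene_length, rng)
    markers = []
    for lin in taxonomy.lineages:
        sp = lin.labels[-1]
        codes = leaves[sp]
        if indel_rate > 0.0:
            keep = rng.random(codes.size) >= indel_rate
            if not keep.any():
                keep[0] = True
            codes = codes[keep]
        markers.append(
            ReferenceMarker(ref_id=f"REF_{sp}", sequence=_decode(codes), lineage=lin)
        )
    return MarkerReferenceSet(markers=markers)


# ---------------------------------------------------------------------------
# scenario containers


@dataclass
class SampleMeta:
    sample_id: str
    ph: float
    temperature_c: float
    season: str
    archaeal_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"{self.sample_id}: pH outside [0, 14]")
        if self.temperature_c < 0.0:
            raise ValueError(f"{self.sample_id}: negative temperature")
        if not 0.0 <= self.archaeal_fraction <= 1.0:
            raise ValueError(f"{self.sample_id}: archaeal fraction outside [0, 1]")


@dataclass
class BinSpec:
    """Planted genome bin: realized quality is exactly reconstructable."""

    bin_id: str
    sample_id: str
    species: str
    completeness: float
    contamination: float = 0.0
    n_depth_outliers: int = 0
    n_scaffolds: int = 20
    is_dpann: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.completeness <= 100.0:
            raise ValueError(f"{self.bin_id}: completeness outside (0, 100]")
        if self.contamination < 0.0:
            raise ValueError(f"{self.bin_id}: negative contamination")
        if self.n_scaffolds < 1:
            raise ValueError(f"{self.bin_id}: need at least one scaffold")


@dataclass
class SyntheticScenario:
    """Full description of a planted multi-sample spring study."""

    samples: list[SampleMeta]
    composition: dict[str, dict[str, float]]
    bin_specs: list[BinSpec] = field(default_factory=list)
    pathway_content: dict[str, tuple[str, ...]] = field(default_factory=dict)
    cazyme_content: dict[str, tuple[str, ...]] = field(default_factory=dict)
    n_marker_reads: int = 100_000
    gene_length: int = 900
    read_length: int = 150
    genome_length: int = 24_000
    within_species_rate: float = 0.002
    n_decoys: int = 3
    seed: int = 0

    def validate(self) -> None:
        sample_ids = {s.sample_id for s in self.samples}
        if len(sample_ids) != len(self.samples):
            raise ValueError("sample ids must be unique")
        if set(self.composition) != sample_ids:
            raise ValueError("composition must cover exactly the scenario samples")
        for sid, comp in self.composition.items():
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{sid}: composition sums to {total!r}, not 1 +/- 1e-9"
                )
            if any(v < 0 for v in comp.values()):
                raise ValueError(f"{sid}: negative planted abundance")
        for spec in self.bin_specs:
            if spec.sample_id not in sample_ids:
                raise ValueError(f"{spec.bin_id}: unknown sample {spec.sample_id}")


def spring_scenario(
    taxonomy: ReferenceTaxonomy,
    n_acidic: int = 6,
    n_alkaline: int = 6,
    n_neutral: int = 0,
    seed: int = 0,
    n_marker_reads: int = 100_000,
    bins_per_sample: int = 2,
) -> SyntheticScenario:
    """A two- or three-group spring survey with planted group structure.

    Acid-associated and alkaline-associated species are disjoint halves of
    the taxonomy; each sample's composition is a Dirichlet draw
    concentrated on its group's species, so acidic and alkaline
    communities differ strongly (neutral samples, if any, mix both pools).
    The archaeal fraction of each community rises toward the pH extremes,
    mirroring the observation that extreme springs favour Archaea.
    """
    rng = np.random.default_rng(seed)
    species = taxonomy.species
    if len(species) < 4:
        raise ValueError("need at least 4 species for a group scenario")
    half = len(species) // 2
    pools = {"acidic": species[:half], "alkaline": species[half:]}

    samples: list[SampleMeta] = []
    composition: dict[str, dict[str, float]] = {}
    bin_specs: list[BinSpec] = []
    groups = (
        [("acidic", i) for i in range(n_acidic)]
        + [("alkaline", i) for i in range(n_alkaline)]
        + [("neutral", i) for i in range(n_neutral)]
    )
    completeness_grid = [100.0, 93.75, 87.5, 75.0]  # multiples of 1/48 and 1/4
    for group, i in groups:
        sid = f"{group[:3].upper()}-{i + 1:02d}"
        if group == "acidic":
            ph = float(rng.uniform(2.0, 4.8))
            frac = 0.95 - 0.08 * (ph - 2.0)
        elif group == "alkaline":
            ph = float(rng.uniform(8.6, 9.9))
            frac = 0.55 + 0.3 * (ph - 8.6)
        else:
            ph = float(rng.uniform(6.0, 8.0))
            frac = float(rng.uniform(0.2, 0.4))
        temp = float(rng.uniform(40.0, 95.0))
        season = "summer" if i % 2 == 0 else "winter"
        samples.append(
            SampleMeta(
                sample_id=sid,
                ph=round(ph, 2),
                temperature_c=round(temp, 1),
                season=season,
                archaeal_fraction=round(float(frac), 3),
            )
        )
        pool = pools["acidic"] if group == "acidic" else pools["alkaline"]
        other = [s for s in species if s not in pool]
        alpha = np.concatenate(
            [np.full(len(pool), 6.0), np.full(len(other), 0.08)]
        )
        if group == "neutral":
            alpha = np.full(len(pool) + len(other), 1.5)
        w = rng.dirichlet(alpha)
        comp = dict(zip(list(pool) + other, w.tolist()))
        # exact renormalisation guards against float drift
        total = sum(comp.values())
        comp = {k: v / total for k, v in comp.items()}
        composition[sid] = comp

        top = sorted(comp, key=comp.get, reverse=True)[:bins_per_sample]
        for j, sp in enumerate(top):
            bin_specs.append(
                BinSpec(
                    bin_id=f"{sid}_bin{j + 1}",
                    sample_id=sid,
                    species=sp,
                    completeness=float(rng.choice(completeness_grid)),
                    contamination=float(rng.choice([0.0, 2.0, 4.0])),
                    n_depth_outliers=int(rng.integers(0, 3)),
                    is_dpann=bool(j == bins_per_sample - 1 and rng.random() < 0.3),
                )
            )

    pathway_content = {}
    cazyme_content = {}
    kos = [f"K{n:05d}" for n in range(1, 31)]
    cazys = ["GH5", "GH13", "GT2", "GT4", "PL1", "CE1", "AA3", "CBM48"]
    for idx, sp in enumerate(species):
        n_kos = 4 + int(rng.integers(0, 6))
        pathway_content[sp] = tuple(
            sorted(rng.choice(kos, size=n_kos, replace=False).tolist())
        )
        n_caz = int(rng.integers(0, 5))
        cazyme_content[sp] = tuple(rng.choice(cazys, size=n_caz, replace=True).tolist())

    return SyntheticScenario(
        samples=samples,
        composition=composition,
        bin_specs=bin_specs,
        pathway_content=pathway_content,
        cazyme_content=cazyme_content,
        n_marker_reads=n_marker_reads,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# dataset simulation


@dataclass
class SyntheticDataset:
    """All pipeline inputs for one simulated study, plus ground truth."""

    references: MarkerReferenceSet
    genes: dict[str, str]
    candidates: pd.DataFrame
    bins: list[GenomeBin]
    scaffold_depths: pd.DataFrame
    mag_read_counts: pd.DataFrame
    total_reads: pd.Series
    annotations: pd.DataFrame
    metadata: pd.DataFrame
    truth: dict[str, pd.DataFrame]

    def write(self, out_dir: Path | str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.references.write_fasta(out / "reference_markers.fna")
        self.references.write_tsv(out / "reference_lineages.tsv")
        with open(out / "genes.fna", "w") as fh:
            for gid in sorted(self.genes):
                fh.write(f">{gid}\n{self.genes[gid]}\n")
        self.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        self.scaffold_depths.to_csv(out / "scaffold_depths.tsv", sep="\t", index=False)
        self.mag_read_counts.to_csv(out / "mag_read_counts.tsv", sep="\t")
        self.total_reads.rename("total_reads").to_csv(out / "total_reads.tsv", sep="\t")
        self.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        bins_dir = out / "bins"
        bins_dir.mkdir(exist_ok=True)
        for b in self.bins:
            with open(bins_dir / f"{b.bin_id}.fna", "w") as fh:
                for s in b.scaffolds:
                    fh.write(f">{s.scaffold_id}\n{s.sequence}\n")
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        for name, df in self.truth.items():
            df.to_csv(truth_dir / f"{name}.tsv", sep="\t", index=True)


def _planted_depths(
    n_inliers: int, n_outliers: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Inlier depths inside the Tukey fences, outliers strictly outside.

    Drawn by rejection so that, on the combined vector, the planted
    outliers and only they fall outside the fences.
    """
    base = float(rng.uniform(10.0, 60.0))
    for _ in range(200):
        inliers = base * rng.uniform(0.9, 1.1, size=n_inliers)
        signs = rng.random(n_outliers) < 0.5
        outliers = np.where(
            signs,
            base * rng.uniform(2.5, 4.0, size=n_outliers),
            base * rng.uniform(0.05, 0.3, size=n_outliers),
        )
        combined = np.concatenate([inliers, outliers])
        q1, q3 = np.percentile(combined, [25.0, 75.0])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        in_ok = np.all((inliers >= lo) & (inliers <= hi))
        out_ok = np.all((outliers < lo) | (outliers > hi)) if n_outliers else True
        if in_ok and out_ok:
            return np.round(inliers, 3), np.round(outliers, 3)
    raise RuntimeError("could not realize planted depth outliers")


def simulate_springs(
    taxonomy: ReferenceTaxonomy,
    scenario: SyntheticScenario,
    references: Optional[MarkerReferenceSet] = None,
) -> SyntheticDataset:
    """Generate the full input bundle for one planted spring study.

    Marker read counts are multinomial over genes with probabilities
    proportional to planted abundance x gene length (lengths are equal, so
    expected marker relative abundance equals the planted composition).
    Bins realize their specified completeness/contamination exactly through
    marker inclusion/exclusion, and planted depth-outlier scaffolds fall
    outside the Tukey fences of their bin by construction.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    if references is None:
        references = synthesize_marker_references(
            taxonomy, gene_length=scenario.gene_length, seed=scenario.seed
        )

    # per-species genome sequences, rank-structured like the markers
    genome_rng = np.random.default_rng(scenario.seed + 1)
    genomes = {
        sp: _decode(codes)
        for sp, codes in _evolve_over_tree(
            taxonomy, scenario.genome_length, genome_rng
        ).items()
    }

    genes: dict[str, str] = {}
    cand_rows = []
    gene_truth_rows = []
    for meta in scenario.samples:
        sid = meta.sample_id
        comp = scenario.composition[sid]
        present = [sp for sp, ab in sorted(comp.items()) if ab > 0]
        gene_ids, probs = [], []
        for i, sp in enumerate(present):
            gid = f"{sid}_g{i + 1:03d}"
            seq = mutate_sequence(
                references.by_species(sp).sequence, scenario.within_species_rate, rng
            )
            genes[gid] = seq
            gene_ids.append(gid)
            probs.append(comp[sp] * len(seq))
            gene_truth_rows.append({"gene_id": gid, "sample_id": sid, "species": sp})
        p = np.asarray(probs) / sum(probs)
        counts = rng.multinomial(scenario.n_marker_reads, p)
        for gid, sp, n in zip(gene_ids, present, counts):
            cand_rows.append(
                {
                    "gene_id": gid,
                    "sample_id": sid,
                    "score": round(float(rng.uniform(150.0, 400.0)), 1),
                    "read_count": int(n),
                }
            )
        # decoys: short ORF, low-score hit, and an off-target passer
        for d in range(scenario.n_decoys):
            gid = f"{sid}_decoy{d + 1}"
            kind = d % 3
            if kind == 0:
                genes[gid] = random_sequence(150, rng)  # 50 aa: fails length
                score = round(float(rng.uniform(60.0, 120.0)), 1)
            elif kind == 1:
                genes[gid] = random_sequence(scenario.gene_length, rng)
                score = round(float(rng.uniform(5.0, 39.9)), 1)  # fails score
            else:
                genes[gid] = random_sequence(scenario.gene_length, rng)
                score = round(float(rng.uniform(60.0, 120.0)), 1)  # fails identity
            cand_rows.append(
                {"gene_id": gid, "sample_id": sid, "score": score, "read_count": 0}
            )

    candidates = pd.DataFrame(cand_rows)

    # genome bins with planted quality and depth outliers
    bins: list[GenomeBin] = []
    depth_rows = []
    bin_truth_rows = []
    ann_rows = []
    for spec in scenario.bin_specs:
        marker_set = DPANN_MARKERS_48 if spec.is_dpann else STANDARD_MARKERS_122
        n_exp = len(marker_set)
        n_present = int(round(spec.completeness / 100.0 * n_exp))
        n_present = max(1, min(n_exp, n_present))
        n_extra = int(round(spec.contamination / 100.0 * n_exp))
        chosen = sorted(
            rng.choice(n_exp, size=n_present, replace=False).tolist()
        )
        markers = {marker_set[i]: 1 for i in chosen}
        dup = rng.choice(chosen, size=min(n_extra, n_present), replace=False)
        for i in dup.tolist():
            markers[marker_set[i]] += 1
        realized_completeness = 100.0 * n_present / n_exp
        realized_contamination = 100.0 * len(dup) / n_exp

        genome = mutate_sequence(genomes[spec.species], 0.001, rng)
        n_in = spec.n_scaffolds
        inliers, outliers = _planted_depths(n_in, spec.n_depth_outliers, rng)
        piece = max(200, len(genome) // max(1, n_in + spec.n_depth_outliers))
        scaffolds = []
        pos = 0
        for k, depth in enumerate(np.concatenate([inliers, outliers])):
            is_outlier = k >= n_in
            seq = genome[pos : pos + piece]
            if len(seq) < 50:  # wrap around for tiny remainders
                seq = genome[:piece]
            pos += piece
            scaf_id = f"{spec.bin_id}_scf{k + 1:03d}"
            scaffolds.append(
                Scaffold(
                    scaffold_id=scaf_id,
                    length_bp=len(seq),
                    depth=float(depth),
                    sequence=seq,
                )
            )
            depth_rows.append(
                {
                    "bin_id": spec.bin_id,
                    "scaffold_id": scaf_id,
                    "length_bp": len(seq),
                    "depth": float(depth),
                }
            )
            if is_outlier:
                bin_truth_rows.append(
                    {
                        "bin_id": spec.bin_id,
                        "field": "outlier_scaffold",
                        "value": scaf_id,
                    }
                )
        bins.append(
            GenomeBin(
                bin_id=spec.bin_id,
                sample_id=spec.sample_id,
                scaffolds=scaffolds,
                markers=markers,
                is_dpann=spec.is_dpann,
            )
        )
        for fieldname, value in [
            ("species", spec.species),
            ("completeness", realized_completeness),
            ("contamination", realized_contamination),
            ("n_depth_outliers", spec.n_depth_outliers),
        ]:
            bin_truth_rows.append(
                {"bin_id": spec.bin_id, "field": fieldname, "value": value}
            )

        # functional annotations from the planted pathway/CAZyme content
        orf = 0
        for ko in scenario.pathway_content.get(spec.species, ()):
            orf += 1
            ann_rows.append(
                {
                    "rmag_id": spec.bin_id,
                    "gene_id": f"{spec.bin_id}_orf{orf:04d}",
                    "ko": ko,
                    "cazy_family": "",
                    "scaffold_id": scaffolds[int(rng.integers(0, n_in))].scaffold_id,
                }
            )
        for fam in scenario.cazyme_content.get(spec.species, ()):
            orf += 1
            ann_rows.append(
                {
                    "rmag_id": spec.bin_id,
                    "gene_id": f"{spec.bin_id}_orf{orf:04d}",
                    "ko": "",
                    "cazy_family": fam,
                    "scaffold_id": scaffolds[int(rng.integers(0, n_in))].scaffold_id,
                }
            )

    # read mapping of whole communities onto bins (for rMAG abundance)
    sample_ids = [m.sample_id for m in scenario.samples]
    bin_ids = [s.bin_id for s in scenario.bin_specs]
    mag_counts = pd.DataFrame(0, index=bin_ids, columns=sample_ids, dtype=int)
    total = pd.Series(
        {m.sample_id: scenario.n_marker_reads * 10 for m in scenario.samples}
    )
    for meta in scenario.samples:
        sid = meta.sample_id
        comp = scenario.composition[sid]
        for spec in scenario.bin_specs:
            frac = comp.get(spec.species, 0.0) * meta.archaeal_fraction
            if frac > 0:
                mag_counts.loc[spec.bin_id, sid] = int(
                    rng.binomial(int(total[sid]), frac)
                )

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "pH": [m.ph for m in scenario.samples],
            "temperature_C": [m.temperature_c for m in scenario.samples],
            "season": [m.season for m in scenario.samples],
        }
    )

    comp_truth = pd.DataFrame(
        {sid: scenario.composition[sid] for sid in sample_ids}
    ).fillna(0.0)
    comp_truth.index.name = "species"
    truth = {
        "composition": comp_truth,
        "genes": pd.DataFrame(gene_truth_rows).set_index("gene_id"),
        "bins": pd.DataFrame(bin_truth_rows).set_index("bin_id"),
        "archaeal_fraction": pd.DataFrame(
            {
                "sample_id": sample_ids,
                "archaeal_fraction": [m.archaeal_fraction for m in scenario.samples],
            }
        ).set_index("sample_id"),
    }
    annotations = pd.DataFrame(
        ann_rows, columns=["rmag_id", "gene_id", "ko", "cazy_family", "scaffold_id"]
    )
    return SyntheticDataset(
        references=references,
        genes=genes,
        candidates=candidates,
        bins=bins,
        scaffold_depths=pd.DataFrame(depth_rows),
        mag_read_counts=mag_counts,
        total_reads=total,
        annotations=annotations,
        metadata=metadata,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# compositional counts with planted basis correlations


def simulate_correlated_counts(
    n_features: int,
    n_samples: int,
    seed: int,
    correlated_pairs: Sequence[tuple[int, int, float]] = (),
    depth: int = 50_000,
    sigma: float = 1.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Multinomial count table with planted log-basis correlations.

    Log basis abundances are multivariate normal with unit marginal
    variance (scaled by ``sigma``) and correlation ``rho`` for each planted
    ``(i, j, rho)`` pair; counts are multinomial draws of size ``depth``
    from the closed (normalised) abundances of each sample.  Returns the
    feature x sample count table and the planted basis correlation matrix.
    """
    if n_features < 2 or n_samples < 2:
        raise ValueError("need at least 2 features and 2 samples")
    corr = np.eye(n_features)
    for i, j, rho in correlated_pairs:
        if not -1.0 < rho < 1.0:
            raise ValueError("planted correlations must lie in (-1, 1)")
        corr[i, j] = corr[j, i] = rho
    # verify positive definiteness via Cholesky
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("planted correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, 1.0, size=n_features)
    z = rng.standard_normal(size=(n_samples, n_features)) @ chol.T
    log_abund = mu + sigma * z
    fractions = np.exp(log_abund)
    fractions /= fractions.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p) for p in fractions]).T
    table = pd.DataFrame(
        counts,
        index=[f"F{i + 1:03d}" for i in range(n_features)],
        columns=[f"S{j + 1:03d}" for j in range(n_samples)],
    )
    return table, corr
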