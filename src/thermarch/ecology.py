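"""Community-ecology statistics: grouping, Bray-Curtis, PCoA, ANOSIM.

Samples are classed by the spring-survey conventions — acidic (pH < 5.5),
neutral (5.5 <= pH < 8.5), alkaline (pH >= 8.5); mesothermal (< 60 °C),
thermal (60-80 °C), hyperthermal (>= 80 °C) — and compared on Bray-Curtis
dissimilarities of their community (or function) profiles.  Ordination is
classical principal-coordinates analysis; group separation is tested with
the rank-based ANOSIM permutation statistic, and environmental gradients
with the Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, rankdata
from skbio import DistanceMatrix

from .abundance import AbundanceMatrix

PH_BOUNDS = (5.5, 8.5)
TEMP_BOUNDS = (60.0, 80.0)


def assign_groups(metadata: pd.DataFrame) -> pd.DataFrame:
    """Classify samples by pH and temperature.

    Expects columns ``pH`` and ``temperature_C`` (a ``season`` column is
    carried through if present); returns a frame indexed like the input
    with ``ph_class`` and ``temp_class`` columns.  Boundary values go to
    the upper class (5.5 -> neutral, 8.5 -> alkaline, 60 -> thermal,
    80 -> hyperthermal); samples with missing values are left unclassed
    (NaN) and flagged in the ``ungrouped`` column.
    """
    df = metadata.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    ph = pd.to_numeric(df["pH"], errors="coerce")
    temp = pd.to_numeric(df["temperature_C"], errors="coerce")
    if ((ph < 0) | (ph > 14)).any():
        raise ValueError("pH outside [0, 14]")
    if (temp < 0).any():
        raise ValueError("negative temperature")
    ph_class = pd.cut(
        ph,
        bins=[-np.inf, PH_BOUNDS[0], PH_BOUNDS[1], np.inf],
        labels=["acidic", "neutral", "alkaline"],
        right=False,
    )
    temp_class = pd.cut(
        temp,
        bins=[-np.inf, TEMP_BOUNDS[0], TEMP_BOUNDS[1], np.inf],
        labels=["mesothermal", "thermal", "hyperthermal"],
        right=False,
    )
    out = pd.DataFrame(
        {
            "ph_class": ph_class.astype(object),
            "temp_class": temp_class.astype(object),
        },
        index=df.index,
    )
    if "season" in df.columns:
        out["season"] = df["season"]
    out["ungrouped"] = ph.isna() | temp.isna()
    return out


def bray_curtis(matrix: AbundanceMatrix | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); values lie in [0, 1].
    The input is features x samples; all-zero samples are rejected.
    """
    data = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
    profiles = data.T  # samples x features
    if (profiles.values < 0).any():
        raise ValueError("abundances must be non-negative")
    dead = profiles.index[(profiles.sum(axis=1) == 0)].tolist()
    if dead:
        raise ValueError(f"all-zero samples have undefined dissimilarity: {dead}")
    condensed = pdist(profiles.values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(profiles.index))


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray  # magnitudes of dropped negatives


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    The squared distances are double-centred (Gower), the centred matrix
    eigendecomposed, and coordinates built from the positive eigenvalues
    only; negative eigenvalues (possible for non-Euclidean inputs such as
    Bray-Curtis) are dropped with their magnitudes reported.
    """
    d = dm.data
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-12 * max(abs(eigvals[0]), 1.0)
    pos = eigvals > tol
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    axes = [f"PC{i + 1}" for i in range(lam.size)]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=lam,
        proportion_explained=lam / lam.sum() if lam.size else lam,
        negative_eigenvalues=np.abs(eigvals[eigvals < -tol]),
    )


def anosim(
    dm: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series,
    permutations: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """Analysis of similarities on a distance matrix.

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (M / 2) with M = n(n-1)/2 pairwise distances ranked with
    midranks for ties.  The p-value permutes group labels and uses the
    add-one estimator p = (1 + #{R_perm >= R_obs}) / (1 + permutations),
    so it is never exactly zero.
    """
    labels = pd.Series(groups).reindex(list(dm.ids))
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 members each")
    d = squareform(dm.data, checks=False)
    ranks = rankdata(d)  # midranks
    n = len(labels)
    m = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    lab = labels.to_numpy()

    def r_stat(lab_vec: np.ndarray) -> float:
        within = lab_vec[iu[0]] == lab_vec[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    observed = r_stat(lab)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if r_stat(lab[rng.permutation(n)]) >= observed:
            hits += 1
    return {
        "R": float(observed),
        "p": (1.0 + hits) / (1.0 + permutations),
        "permutations": permutations,
    }


def pearson_test(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Pearson correlation with a two-sided t-distribution p-value."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("Pearson correlation undefined for zero variance")
    r, p = pearsonr(xa, ya)
    return {"r": float(r), "p": float(p)}
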