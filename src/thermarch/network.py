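"""Co-occurrence networks for Archaea-dominant springs via SparCC.

Relative-abundance data are compositional: ordinary correlations between
fractions are distorted by the unit-sum constraint.  SparCC instead works
from log-ratio variances t_ij = var(log(x_i/x_j)), which are invariant to
per-sample scaling, and solves the approximate linear system relating
them to the unobserved *basis* variances under a sparsity assumption;
basis correlations follow from

    rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).

Strongly correlated pairs violate the sparsity assumption, so the pair
with the largest |rho| above an exclusion threshold is iteratively removed
from the system and the solve repeated.  Counts are smoothed by sampling
component fractions from a posterior Dirichlet (counts + 1) and the final
matrix is the median over draws.  Pseudo-p values come from a
permutation-style null: each feature's counts are shuffled across samples
independently (destroying covariance while keeping margins), correlations
recomputed, and the two-sided add-one estimator applied.  Edges require
|r| > 0.6 and p < 0.05, both strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd


def select_archaea_dominant(
    archaeal_fraction: pd.Series, threshold: float = 0.5
) -> list[str]:
    """Samples whose archaeal read fraction strictly exceeds the threshold."""
    frac = archaeal_fraction.astype(float)
    return frac[frac > threshold].index.tolist()


def prevalence_filter(
    counts: pd.DataFrame, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Drop features occurring in fewer than half (by default) of samples.

    A feature is present in a sample when its count is > 0; it is kept
    when present in at least ceil(min_fraction x n_samples) samples.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    need = math.ceil(min_fraction * counts.shape[1])
    present = (counts > 0).sum(axis=1)
    out = counts.loc[present >= need]
    if out.empty:
        import warnings

        warnings.warn("prevalence filter removed every feature", stacklevel=2)
    return out


def _log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """t_ij = var(log(x_i / x_j)) from a d x n fraction matrix."""
    logf = np.log(fractions)
    cov = np.cov(logf)
    diag = np.diag(cov)
    return diag[:, None] + diag[None, :] - 2.0 * cov


def _basis_correlations(
    t: np.ndarray, exclusion_iterations: int, exclusion_threshold: float
) -> np.ndarray:
    """Solve the SparCC basis-variance system with iterative pair exclusion."""
    d = t.shape[0]
    m = np.ones((d, d)) + (d - 2.0) * np.eye(d)
    tvec = t.sum(axis=1)
    excluded = np.zeros((d, d), dtype=bool)
    n_excluded = np.zeros(d, dtype=int)

    def solve() -> np.ndarray:
        try:
            w = np.linalg.solve(m, tvec)
        except np.linalg.LinAlgError:
            w = np.linalg.lstsq(m, tvec, rcond=None)[0]
        w = np.clip(w, 1e-12, None)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return rho

    rho = solve()
    for _ in range(exclusion_iterations):
        masked = np.abs(rho.copy())
        np.fill_diagonal(masked, 0.0)
        masked[excluded] = 0.0
        # components already stripped of most of their pairs are capped,
        # keeping the linear system non-singular
        capped = n_excluded >= d - 3
        masked[capped, :] = 0.0
        masked[:, capped] = 0.0
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        n_excluded[i] += 1
        n_excluded[j] += 1
        tvec[i] -= t[i, j]
        tvec[j] -= t[i, j]
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        rho = solve()
    return rho


def _posterior_fractions(
    counts: np.ndarray, seed: int, n_draws: int
) -> np.ndarray:
    """Dirichlet(counts + 1) posterior fraction draws, shape (draws, d, n).

    Randomness is keyed to each sample's count *content* (not its column
    position), so permuting sample order permutes the draws identically
    and the downstream correlation matrix is exactly order-invariant.
    """
    import hashlib

    d, n = counts.shape
    fractions = np.empty((n_draws, d, n))
    for j in range(n):
        col = np.ascontiguousarray(counts[:, j])
        key = hashlib.blake2b(col.tobytes(), digest_size=8).digest()
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, int.from_bytes(key, "little")])
        )
        gamma = rng.gamma(np.tile(col + 1.0, (n_draws, 1)))
        fractions[:, :, j] = gamma / gamma.sum(axis=1, keepdims=True)
    return fractions


def _sparcc_matrix(
    counts: np.ndarray,
    seed: int,
    n_dirichlet_draws: int,
    exclusion_iterations: int,
    exclusion_threshold: float,
) -> np.ndarray:
    fractions = _posterior_fractions(counts, seed, n_dirichlet_draws)
    draws = []
    for k in range(n_dirichlet_draws):
        t = _log_ratio_variances(fractions[k])
        draws.append(
            _basis_correlations(t, exclusion_iterations, exclusion_threshold)
        )
    rho = np.median(np.stack(draws), axis=0)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return (rho + rho.T) / 2.0


def sparcc_correlations(
    counts: pd.DataFrame,
    n_dirichlet_draws: int = 20,
    exclusion_iterations: int = 10,
    exclusion_threshold: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """SparCC basis-correlation matrix for a feature x sample count table.

    Defaults follow the method's published settings: 20 posterior
    Dirichlet draws, up to 10 strong-pair exclusion iterations at
    threshold 0.1, median-aggregated.  Requires at least 4 features (the
    basis-variance system is underdetermined below that) and 10 samples.
    """
    d, n = counts.shape
    if d < 4:
        raise ValueError(
            f"SparCC needs at least 4 features to identify basis variances; got {d}"
        )
    if n < 10:
        raise ValueError(f"SparCC needs at least 10 samples; got {n}")
    rho = _sparcc_matrix(
        counts.to_numpy(dtype=float),
        seed,
        n_dirichlet_draws,
        exclusion_iterations,
        exclusion_threshold,
    )
    return pd.DataFrame(rho, index=counts.index, columns=counts.index)


def bootstrap_pvalues(
    counts: pd.DataFrame,
    observed_r: pd.DataFrame,
    B: int = 100,
    seed: int = 0,
    n_dirichlet_draws: int = 20,
    exclusion_iterations: int = 10,
    exclusion_threshold: float = 0.1,
) -> pd.DataFrame:
    """Two-sided pseudo-p values from a feature-shuffled SparCC null.

    Each of the B null datasets permutes every feature's counts across
    samples independently, the SparCC matrix is recomputed, and
    p_ij = (1 + #{|r_null| >= |r_obs|}) / (1 + B), so p is in (0, 1] and
    never exactly zero.
    """
    if B < 1:
        raise ValueError("need at least one null replicate")
    x = counts.to_numpy(dtype=float)
    obs = np.abs(observed_r.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    hits = np.zeros_like(obs)
    d, n = x.shape
    for b in range(B):
        shuffled = np.empty_like(x)
        for i in range(d):
            shuffled[i] = x[i, rng.permutation(n)]
        null_rho = _sparcc_matrix(
            shuffled,
            seed + 1 + b,
            n_dirichlet_draws,
            exclusion_iterations,
            exclusion_threshold,
        )
        hits += np.abs(null_rho) >= obs
    p = (1.0 + hits) / (1.0 + B)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=observed_r.index, columns=observed_r.columns)


@dataclass
class CooccurrenceNetwork:
    """Thresholded co-occurrence graph with node metadata."""

    graph: nx.Graph
    r_min: float
    alpha: float

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {
                "node_i": i,
                "node_j": j,
                "r": data["r"],
                "p": data["p"],
                "sign": data["sign"],
            }
            for i, j, data in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "r", "p", "sign"])

    @property
    def isolates(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("isolate")]

    def write_graphml(self, path: Path | str) -> None:
        nx.write_graphml(self.graph, str(path))

    def write_edges(self, path: Path | str) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def build_network(
    r_matrix: pd.DataFrame,
    p_matrix: pd.DataFrame,
    node_meta: Optional[pd.DataFrame] = None,
    r_min: float = 0.6,
    alpha: float = 0.05,
) -> CooccurrenceNetwork:
    """Edge construction: |r| > r_min and p < alpha, both strict.

    Nodes without any passing edge are retained as flagged isolates.
    ``node_meta`` (indexed by node id, e.g. columns ``order`` and
    ``max_abundance``) is attached as node attributes when given.
    """
    if list(r_matrix.index) != list(p_matrix.index) or list(
        r_matrix.columns
    ) != list(p_matrix.columns):
        raise ValueError("r and p matrices must share index and columns")
    nodes = list(r_matrix.index)
    g = nx.Graph()
    for node in nodes:
        attrs = {}
        if node_meta is not None and node in node_meta.index:
            attrs = {
                k: v for k, v in node_meta.loc[node].items() if pd.notna(v)
            }
        g.add_node(node, **attrs)
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            r = float(r_matrix.iat[a, b])
            p = float(p_matrix.iat[a, b])
            if abs(r) > r_min and p < alpha:
                g.add_edge(
                    nodes[a],
                    nodes[b],
                    r=r,
                    p=p,
                    sign="positive" if r > 0 else "negative",
                )
    for node in nodes:
        g.nodes[node]["isolate"] = g.degree(node) == 0
    return CooccurrenceNetwork(graph=g, r_min=r_min, alpha=alpha)


def connected_component_summary(network: CooccurrenceNetwork) -> pd.DataFrame:
    """Optional module summary: connected components of the edge graph."""
    sub = network.graph.edge_subgraph(network.graph.edges).copy()
    rows = [
        {"component": idx + 1, "size": len(comp), "members": ";".join(sorted(comp))}
        for idx, comp in enumerate(nx.connected_components(sub))
    ]
    return pd.DataFrame(rows, columns=["component", "size", "members"])
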