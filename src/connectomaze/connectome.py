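"""Functional-connectome graph construction and metrics.

Correlation matrices (Fisher-z of pairwise Pearson r, first nine volumes
dropped) are proportionally thresholded to a fixed edge density (top 15% of
all n(n-1)/2 pairs by default), weights normalized by the largest retained
z so every graph spans [0, 1].  On these weighted graphs the module computes
node strength and degree, Onnela weighted clustering, characteristic path
length (edge length = 1/weight), small-worldness against degree-preserving
rewired nulls, degree-indexed rich-club curves, hemisphere-averaged seed
connectivity, and high-strength subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

from .types import RoiTimeSeriesSet, hemisphere_of_label

__all__ = [
    "ConnectivityMatrix",
    "BrainGraph",
    "RichClubCurve",
    "SeedConnectivityResult",
    "GraphMetrics",
    "correlation_matrix",
    "threshold_density",
    "graph_metrics",
    "rich_club_curve",
    "seed_connectivity",
    "high_strength_subnetwork",
]

R_CLIP = 1.0 - 1e-7  # |r| cap before atanh, keeps z finite for perfect correlation


class EmptyGraphError(ValueError):
    """Requested density retains zero edges."""


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI matrix of Fisher-z transformed Pearson correlations.

    The diagonal is NaN (self-correlation is undefined by convention).
    ``valid`` flags ROIs with nonzero variance; rows/columns of invalid ROIs
    are NaN, never silently zeroed.
    """

    z_values: np.ndarray
    roi_labels: list[str]
    hemisphere: list[str] = field(default_factory=list)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        n = self.z_values.shape[0]
        if self.z_values.shape != (n, n):
            raise ValueError("z_values must be square")
        if len(self.roi_labels) != n:
            raise ValueError("one label per ROI required")
        if not self.hemisphere:
            self.hemisphere = [hemisphere_of_label(l) for l in self.roi_labels]
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)

    @property
    def n_rois(self) -> int:
        return self.z_values.shape[0]

    @property
    def n_pairs(self) -> int:
        """Number of unique off-diagonal node pairs, n(n-1)/2."""
        n = self.n_rois
        return n * (n - 1) // 2

    def index_of(self, label: str) -> int:
        try:
            return self.roi_labels.index(label)
        except ValueError as exc:
            raise KeyError(f"ROI label {label!r} not present") from exc


@dataclass
class BrainGraph:
    """Thresholded, weight-normalized undirected weighted graph.

    ``weights`` is symmetric with zero diagonal; retained edges lie in
    (0, 1] and the maximum retained weight is exactly 1.  ``meta`` records
    the thresholding provenance (density, edge count, normalizing z, tie
    rule).
    """

    weights: np.ndarray
    roi_labels: list[str]
    density: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def degree(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1).astype(int)

    def strength(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.roi_labels)
        ii, jj = np.nonzero(np.triu(self.weights, 1))
        for i, j in zip(ii, jj):
            g.add_edge(self.roi_labels[i], self.roi_labels[j],
                       weight=float(self.weights[i, j]))
        return g


@dataclass
class RichClubCurve:
    """phi(k) over integer degree thresholds, with per-k validity flags."""

    k_values: np.ndarray
    phi: np.ndarray
    defined: np.ndarray  # False when < 2 nodes have degree > k

    def as_dict(self) -> dict[int, float]:
        return {int(k): float(p) for k, p, d in
                zip(self.k_values, self.phi, self.defined) if d}


@dataclass
class SeedConnectivityResult:
    """z between one seed and one target region, per hemisphere and averaged."""

    seed_label: str
    target_label: str
    z_left: float
    z_right: float

    @property
    def z_mean(self) -> float:
        return 0.5 * (self.z_left + self.z_right)


@dataclass
class GraphMetrics:
    """Per-node strength/degree and global weighted-graph summaries."""

    strength: np.ndarray
    degree: np.ndarray
    clustering: float          # mean Onnela weighted clustering over nodes
    path_length: float         # mean shortest path over reachable pairs
    frac_unreachable: float    # fraction of node pairs with no path
    small_worldness: Optional[float] = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def correlation_matrix(series: RoiTimeSeriesSet, n_drop: int = 9) -> ConnectivityMatrix:
    """Pairwise Pearson correlation with Fisher z-transform.

    The first ``n_drop`` volumes are excluded before correlating (transient
    non-steady-state frames).  |r| is capped at 1 - 1e-7 before atanh so
    perfectly (anti)correlated synthetic inputs map to finite z.  Constant
    ROIs are flagged invalid and carry NaN rows.
    """
    X = series.signals[:, n_drop:]
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples after dropping initial volumes")
    sd = X.std(axis=1)
    valid = sd > 0
    z = np.full((series.n_rois, series.n_rois), np.nan)
    if valid.any():
        r = np.corrcoef(X[valid])
        r = np.clip(np.atleast_2d(r), -R_CLIP, R_CLIP)
        zv = np.arctanh(r)
        idx = np.flatnonzero(valid)
        z[np.ix_(idx, idx)] = zv
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(
        z_values=z,
        roi_labels=list(series.roi_labels),
        hemisphere=list(series.hemisphere),
        valid=valid,
    )


def threshold_density(cm: ConnectivityMatrix, density: float = 0.15) -> BrainGraph:
    """Proportional threshold: keep the top ``floor(density * n_pairs)``
    pairs by signed z, then divide retained weights by the largest retained z
    so edge weights span (0, 1].

    Ties are broken deterministically by ascending (row, column) index; the
    rule and the normalizing z are recorded in ``meta``.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    n = cm.n_rois
    n_keep = int(np.floor(density * cm.n_pairs))
    if n_keep == 0:
        raise EmptyGraphError(f"density {density} retains no edges for n={n}")
    iu, ju = np.triu_indices(n, 1)
    z = cm.z_values[iu, ju]
    finite = np.isfinite(z)
    if finite.sum() < n_keep:
        raise ValueError("not enough finite pairs to reach requested density")
    # stable sort on (-z, i, j): most-positive first, index order on ties
    order = np.lexsort((ju, iu, -z))
    order = order[finite[order]][:n_keep]
    z_max = z[order].max()
    if z_max <= 0:
        raise ValueError("largest retained z is not positive; cannot normalize")
    W = np.zeros((n, n))
    W[iu[order], ju[order]] = z[order] / z_max
    W += W.T
    return BrainGraph(
        weights=W,
        roi_labels=list(cm.roi_labels),
        density=density,
        meta={
            "n_edges": int(n_keep),
            "z_max": float(z_max),
            "rounding": "floor",
            "tie_break": "ascending (row, column) index",
        },
    )


def _weighted_clustering(W: np.ndarray) -> np.ndarray:
    """Onnela per-node weighted clustering: geometric mean of triangle
    weights over the binary-degree denominator.  Assumes weights <= 1."""
    cbrt = np.cbrt(W)
    num = np.diagonal(cbrt @ cbrt @ cbrt)
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, num / denom, 0.0)
    return c


def _path_length(W: np.ndarray) -> tuple[float, float]:
    """Characteristic path length on edge lengths 1/weight.

    Returns (mean over reachable ordered pairs, fraction unreachable)."""
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, 0.0)
    D = dijkstra(L, directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    frac_unreachable = 1.0 - finite.sum() / off.sum()
    mean_len = float(D[finite].mean()) if finite.any() else np.inf
    return mean_len, frac_unreachable


def _rewired_null(g: BrainGraph, rng: np.random.Generator,
                  swaps_per_edge: int = 10) -> np.ndarray:
    """Maslov-Sneppen degree-preserving rewire of the binary skeleton with
    the original weights shuffled onto the rewired topology."""
    G = nx.from_numpy_array((g.weights > 0).astype(int))
    m = G.number_of_edges()
    if m >= 2:
        nx.double_edge_swap(G, nswap=swaps_per_edge * m, max_tries=100 * swaps_per_edge * m,
                            seed=int(rng.integers(2**31)))
    n = g.n_nodes
    W = np.zeros((n, n))
    weights = g.weights[np.triu_indices(n, 1)]
    weights = weights[weights > 0]
    rng.shuffle(weights)
    for (i, j), w in zip(G.edges(), weights):
        W[i, j] = W[j, i] = w
    return W


def graph_metrics(g: BrainGraph, n_nulls: int = 0, rng_seed: int = 0,
                  swaps_per_edge: int = 10) -> GraphMetrics:
    """All global weighted-graph metrics.

    Small-worldness sigma = (C/<C_null>)/(L/<L_null>) over ``n_nulls``
    degree-preserving rewired null graphs (skipped when ``n_nulls == 0``).
    Unreachable pairs are excluded from path-length means and their fraction
    reported.
    """
    if g.n_nodes < 3:
        raise ValueError("graph metrics need at least 3 nodes")
    W = g.weights
    strength = g.strength()
    degree = g.degree()
    C = float(_weighted_clustering(W).mean())
    L, frac_unreachable = _path_length(W)
    sigma = None
    if n_nulls >= 1:
        rng = np.random.default_rng(rng_seed)
        c_nulls, l_nulls = [], []
        for _ in range(n_nulls):
            Wn = _rewired_null(g, rng, swaps_per_edge)
            c_nulls.append(_weighted_clustering(Wn).mean())
            l_nulls.append(_path_length(Wn)[0])
        c0, l0 = float(np.mean(c_nulls)), float(np.mean(l_nulls))
        if c0 > 0 and l0 > 0 and L > 0:
            sigma = (C / c0) / (L / l0)
    return GraphMetrics(
        strength=strength,
        degree=degree,
        clustering=C,
        path_length=L,
        frac_unreachable=frac_unreachable,
        small_worldness=sigma,
    )


def rich_club_curve(g: BrainGraph, k_max: int | None = None,
                    weighted: bool = False) -> RichClubCurve:
    """Degree-indexed rich-club curve on the binary skeleton.

    For each k, restrict to nodes of degree > k; phi(k) is the density of
    the induced subgraph, 2 E_sub / (N_sub (N_sub - 1)).  Entries with fewer
    than two surviving nodes are flagged undefined.  ``weighted=True``
    replaces the edge count by the summed subgraph weight over the sum of
    the E_sub largest weights in the whole graph (off by default).
    """
    degree = g.degree()
    if k_max is None:
        k_max = int(degree.max()) if degree.size else 0
    if degree.size and k_max > degree.max():
        raise ValueError("k_max exceeds the maximum degree")
    A = g.weights > 0
    ks = np.arange(0, k_max + 1)
    phi = np.full(ks.shape, np.nan)
    defined = np.zeros(ks.shape, dtype=bool)
    all_w = np.sort(g.weights[np.triu_indices(g.n_nodes, 1)])[::-1]
    for idx, k in enumerate(ks):
        nodes = np.flatnonzero(degree > k)
        n_sub = nodes.size
        if n_sub < 2:
            continue
        sub = A[np.ix_(nodes, nodes)]
        e_sub = int(np.triu(sub, 1).sum())
        defined[idx] = True
        if weighted:
            w_sub = float(np.triu(g.weights[np.ix_(nodes, nodes)], 1).sum())
            denom = float(all_w[:e_sub].sum())
            phi[idx] = w_sub / denom if denom > 0 else np.nan
        else:
            phi[idx] = 2.0 * e_sub / (n_sub * (n_sub - 1))
    return RichClubCurve(k_values=ks, phi=phi, defined=defined)


def seed_connectivity(cm: ConnectivityMatrix, seed: str,
                      targets: Sequence[str]) -> list[SeedConnectivityResult]:
    """z between a seed region and target regions, per hemisphere and
    averaged.

    ``seed`` and ``targets`` are base region names; the matrix must contain
    ``<name>_L`` and ``<name>_R`` instances of each.  Left-seed pairs with
    left-target, right with right, and the two are averaged (hemispheres do
    not differ systematically, so their mean is the session value).
    """
    out = []
    for target in targets:
        vals = {}
        for hemi in ("L", "R"):
            try:
                i = cm.index_of(f"{seed}_{hemi}")
                j = cm.index_of(f"{target}_{hemi}")
            except KeyError as exc:
                raise KeyError(
                    f"missing hemisphere instance for {seed}/{target} ({hemi})"
                ) from exc
            vals[hemi] = float(cm.z_values[i, j])
        out.append(SeedConnectivityResult(seed_label=seed, target_label=target,
                                          z_left=vals["L"], z_right=vals["R"]))
    return out


def high_strength_subnetwork(
    graphs: Sequence[BrainGraph],
    s_min: float = 15.0,
    k_min: float | None = None,
    mode: str = "mean",
) -> tuple[list[str], np.ndarray]:
    """Nodes whose strength exceeds ``s_min`` (and degree ``k_min`` if given),
    with the induced mean connectivity.

    ``mode='mean'`` thresholds the across-subject mean strength/degree;
    ``mode='any'`` keeps nodes exceeding the thresholds in at least one
    subject.  Returns (node labels, induced mean weight matrix); an empty
    selection returns an empty list, not an error.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    labels = graphs[0].roi_labels
    S = np.vstack([g.strength() for g in graphs])
    K = np.vstack([g.degree() for g in graphs])
    if mode == "mean":
        sel = S.mean(axis=0) > s_min
        if k_min is not None:
            sel &= K.mean(axis=0) > k_min
    elif mode == "any":
        sel = (S > s_min).any(axis=0)
        if k_min is not None:
            sel |= (K > k_min).any(axis=0)
    else:
        raise ValueError("mode must be 'mean' or 'any'")
    idx = np.flatnonzero(sel)
    mean_w = np.mean([g.weights for g in graphs], axis=0)
    induced = mean_w[np.ix_(idx, idx)]
    return [labels[i] for i in idx], induced
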