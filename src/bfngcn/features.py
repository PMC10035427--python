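"""Node-feature matrices for GCN input.

Four per-subject feature blocks, individually or concatenated:

* **OS** — original signals: row i is ROI i's time series (d = m).
* **OH** — one-hot encoding: the n x n identity, marking each ROI's
  position in the atlas (d = n).
* **NS** — eight node statistics: three local clustering coefficients
  (Watts–Strogatz binary, Onnela weighted, Zhang–Horvath weighted), four
  centralities (degree, betweenness, closeness, eigenvector) and local
  efficiency (d = 8).
* **CV** — correlation vector: row i of the Pearson matrix, diagonal set
  to 1 (d = n).

Blocks concatenate in the canonical order OS, OH, NS, CV regardless of
the request order, matching the feature-combination grids of the study
protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bfn import AdjacencyMatrix, TimeSeriesMatrix, binarize_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "NodeFeatureMatrix",
    "FEATURE_ORDER",
    "NS_COLUMNS",
    "features_os",
    "features_oh",
    "features_ns",
    "features_cv",
    "combine_features",
    "build_feature_matrix",
]

FEATURE_ORDER = ("OS", "OH", "NS", "CV")

NS_COLUMNS = (
    "cc_ws",
    "cc_onnela",
    "cc_zhang",
    "deg_c",
    "btw_c",
    "clo_c",
    "eig_c",
    "local_eff",
)


@dataclass
class NodeFeatureMatrix:
    values: np.ndarray
    feature_set: tuple[str, ...]
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_set = tuple(self.feature_set)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if not self.column_names:
            self.column_names = [f"f{j}" for j in range(self.d)]
        if len(self.column_names) != self.d:
            raise ValueError("column_names length does not match width")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def features_os(ts: TimeSeriesMatrix, *, zscore: bool = False) -> NodeFeatureMatrix:
    """Original signals: one time point per column (d = m)."""
    values = ts.values.copy()
    if zscore:
        values = values - values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = values / sd
    cols = [f"os_t{t}" for t in range(ts.n_timepoints)]
    return NodeFeatureMatrix(values=values, feature_set=("OS",), column_names=cols)


def features_oh(n: int) -> NodeFeatureMatrix:
    """One-hot position indicators: the n x n identity."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cols = [f"oh_{i}" for i in range(n)]
    return NodeFeatureMatrix(values=np.eye(n), feature_set=("OH",), column_names=cols)


def features_cv(adj_pc: AdjacencyMatrix) -> NodeFeatureMatrix:
    """Correlation vectors: row i of the Pearson matrix, diagonal 1 (d = n)."""
    if adj_pc.estimator != "pc":
        raise ValueError(
            f"correlation vectors are defined on the Pearson estimator, "
            f"got {adj_pc.estimator!r}"
        )
    values = adj_pc.raw.copy()
    np.fill_diagonal(values, 1.0)
    cols = [f"cv_{r}" for r in adj_pc.roi_ids]
    return NodeFeatureMatrix(values=values, feature_set=("CV",), column_names=cols)


# ---------------------------------------------------------------------------
# node statistics


def _zhang_clustering(w: np.ndarray) -> np.ndarray:
    # Zhang-Horvath weighted clustering with weights rescaled to [0, 1]:
    # C_i = sum_{j!=k} w_ij w_jk w_ki / ((sum_j w_ij)^2 - sum_j w_ij^2)
    wmax = w.max()
    if wmax > 0:
        w = w / wmax
    num = np.diag(w @ w @ w)
    s1 = w.sum(axis=1)
    s2 = (w**2).sum(axis=1)
    den = s1**2 - s2
    out = np.zeros(len(w))
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def _eigenvector_centrality(w: np.ndarray) -> np.ndarray:
    # leading eigenvector of the symmetric weight matrix, entries made
    # nonnegative, L2-normalized; zero matrix -> zeros
    if not w.any():
        return np.zeros(len(w))
    vals, vecs = np.linalg.eigh(w)
    v = vecs[:, -1]
    v = np.abs(v)
    return v / np.linalg.norm(v)


def _local_efficiency(g: nx.Graph) -> np.ndarray:
    # per-node: global efficiency of the subgraph induced on its neighbors;
    # unreachable pairs contribute 0
    n = g.number_of_nodes()
    out = np.zeros(n)
    for v in g.nodes:
        nbrs = list(g[v])
        if len(nbrs) < 2:
            continue
        out[v] = nx.global_efficiency(g.subgraph(nbrs))
    return out


def features_ns(
    adj: AdjacencyMatrix, *, binarize_keep_fraction: float = 0.3
) -> NodeFeatureMatrix:
    """Eight node statistics per ROI, in the fixed column order
    ``cc_ws, cc_onnela, cc_zhang, deg_c, btw_c, clo_c, eig_c, local_eff``.

    Binary-graph statistics (Watts–Strogatz clustering, degree,
    betweenness, harmonic closeness, local efficiency) are computed on a
    proportionally thresholded graph keeping the strongest
    ``binarize_keep_fraction`` of |edges|; weighted statistics (Onnela and
    Zhang–Horvath clustering, eigenvector centrality) use |weights|.
    Centralities are normalized by (n-1)-based factors so features are
    comparable across graph sizes.
    """
    n = adj.n
    if n < 2:
        raise ValueError("node statistics need at least 2 nodes")
    w = np.abs(adj.raw)
    is_binary = bool(np.isin(adj.raw, (0.0, 1.0)).all())
    if is_binary and binarize_keep_fraction >= 1.0:
        binary = adj.raw.copy()
    else:
        binary = binarize_adjacency(adj, binarize_keep_fraction).raw
    gb = nx.from_numpy_array(binary)
    gw = nx.from_numpy_array(w)
    if not nx.is_connected(gb):
        logger.info(
            "thresholded graph is disconnected; closeness uses the harmonic "
            "convention and unreachable pairs contribute 0 to efficiency"
        )

    stats = np.zeros((n, 8))
    stats[:, 0] = [nx.clustering(gb)[v] for v in range(n)]
    onnela = nx.clustering(gw, weight="weight")
    stats[:, 1] = [onnela[v] for v in range(n)]
    stats[:, 2] = _zhang_clustering(w)
    stats[:, 3] = binary.sum(axis=1) / (n - 1)
    btw = nx.betweenness_centrality(gb, normalized=True)
    stats[:, 4] = [btw[v] for v in range(n)]
    harm = nx.harmonic_centrality(gb)
    stats[:, 5] = [harm[v] / (n - 1) for v in range(n)]
    stats[:, 6] = _eigenvector_centrality(w)
    stats[:, 7] = _local_efficiency(gb)
    if not np.isfinite(stats).all():
        raise ValueError("non-finite node statistic encountered")
    return NodeFeatureMatrix(
        values=stats, feature_set=("NS",), column_names=list(NS_COLUMNS)
    )


# ---------------------------------------------------------------------------
# combination


def combine_features(blocks: list[NodeFeatureMatrix]) -> NodeFeatureMatrix:
    """Concatenate feature blocks horizontally in canonical OS,OH,NS,CV order."""
    if not blocks:
        raise ValueError("no feature blocks given")
    members: list[str] = []
    for b in blocks:
        members.extend(b.feature_set)
    if len(members) != len(set(members)):
        raise ValueError(f"duplicate feature blocks in {members}")
    ns = {b.n for b in blocks}
    if len(ns) != 1:
        raise ValueError(f"blocks disagree on node count: {sorted(ns)}")
    # order blocks by the canonical position of their first member; blocks
    # that are themselves combinations stay internally ordered
    ordered = sorted(blocks, key=lambda b: FEATURE_ORDER.index(b.feature_set[0]))
    values = np.hstack([b.values for b in ordered])
    cols = [c for b in ordered for c in b.column_names]
    fset = tuple(m for b in ordered for m in b.feature_set)
    if list(fset) != sorted(fset, key=FEATURE_ORDER.index):
        raise ValueError(f"cannot canonically order feature sets {fset}")
    return NodeFeatureMatrix(values=values, feature_set=fset, column_names=cols)


def standardize_columns(x: NodeFeatureMatrix) -> NodeFeatureMatrix:
    """Z-score each feature column across nodes (constant columns left at 0)."""
    v = x.values - x.values.mean(axis=0, keepdims=True)
    sd = v.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return NodeFeatureMatrix(
        values=v / sd, feature_set=x.feature_set, column_names=list(x.column_names)
    )


def build_feature_matrix(
    sets: list[str],
    *,
    ts: TimeSeriesMatrix | None = None,
    adj: AdjacencyMatrix | None = None,
    adj_pc: AdjacencyMatrix | None = None,
    standardize: bool = True,
    os_zscore: bool = False,
    ns_keep_fraction: float = 0.3,
) -> NodeFeatureMatrix:
    """Assemble the requested feature sets for one subject.

    ``sets`` is a list drawn from {"os", "oh", "ns", "cv"} (case
    insensitive).  OS needs the time series, NS the (estimated) adjacency,
    CV the Pearson adjacency.
    """
    blocks: list[NodeFeatureMatrix] = []
    for s in sets:
        s = s.upper()
        if s == "OS":
            if ts is None:
                raise ValueError("OS features need a time-series matrix")
            blocks.append(features_os(ts, zscore=os_zscore))
        elif s == "OH":
            ref = adj or adj_pc or ts
            if ref is None:
                raise ValueError("OH features need a node count source")
            n = ref.n if isinstance(ref, AdjacencyMatrix) else ref.n_rois
            blocks.append(features_oh(n))
        elif s == "NS":
            if adj is None:
                raise ValueError("NS features need an adjacency matrix")
            blocks.append(features_ns(adj, binarize_keep_fraction=ns_keep_fraction))
        elif s == "CV":
            if adj_pc is None:
                raise ValueError("CV features need a Pearson adjacency matrix")
            blocks.append(features_cv(adj_pc))
        else:
            raise ValueError(f"unknown feature set {s!r}")
    out = combine_features(blocks)
    if standardize:
        out = standardize_columns(out)
    return out
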