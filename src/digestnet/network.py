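"""Time-resolved co-occurrence network inference.

Two edge definitions are supported:

``bicor_fdr``
    Biweight midcorrelation between each pair of ASV relative-abundance
    traces, a Student-t p-value per pair, Benjamini-Hochberg correction,
    and an edge wherever q < alpha (positive correlations only by
    default).  This is the robust-correlation network whose edges carry
    the multiple-test-corrected bicor values.

``clr_glasso``
    Sparse inverse-covariance estimation on centered-log-ratio transformed
    counts (graphical lasso over a log-spaced penalty path from
    ``lambda_max`` down to ``lambda_max * lambda_min_ratio``), with the
    penalty selected by StARS (edge instability over seeded subsamples).

The biweight midcorrelation downweights each observation by a Tukey
biweight in its distance from the median (in units of 9 MADs), making the
edge statistic robust to the bloom/crash outliers typical of digester
time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import graphical_lasso
from statsmodels.stats.multitest import multipletests

from .community import relative_abundance
from .datatypes import AbundanceTable, ValidationError

__all__ = [
    "NetworkConfig",
    "CorrelationResult",
    "bicor",
    "bicor_matrix",
    "correlation_test",
    "bh_adjust",
    "build_network",
    "edge_statistics",
    "clr_transform",
    "sparse_precision_network",
    "avg_clustering_coefficient",
]


@dataclass
class NetworkConfig:
    """Knobs of the network-inference stage."""

    prevalence_threshold: float = 0.25  # node kept if present in >= this fraction
    edge_method: str = "bicor_fdr"  # or "clr_glasso"
    fdr_alpha: float = 0.05
    positive_edges_only: bool = True
    glasso_lambda_min_ratio: float = 0.1
    glasso_path_length: int = 20
    stars_instability_threshold: float = 0.05
    stars_subsamples: int = 20
    stars_subsample_size: int | None = None  # default min(n, floor(10*sqrt(n)))
    clr_pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence_threshold <= 1:
            raise ValidationError("prevalence_threshold must be in (0, 1]")
        if not 0 < self.glasso_lambda_min_ratio < 1:
            raise ValidationError("glasso_lambda_min_ratio must be in (0, 1)")
        if self.edge_method not in ("bicor_fdr", "clr_glasso"):
            raise ValidationError(f"unknown edge method {self.edge_method!r}")


@dataclass
class CorrelationResult:
    r: float
    n: int
    t: float
    df: int
    p: float
    q: float | None = None
    exact: bool = False  # |r| = 1, p pinned to 0


def _bicor_prepare(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Median-centered, Tukey-weighted, unit-norm version of ``x``.

    Returns the transformed vector and a flag: True when the MAD was zero
    and the Pearson z-score fallback was used.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        sd = x.std()
        if sd == 0:
            raise ValidationError("constant vector has no defined correlation")
        z = x - x.mean()
        return z / np.linalg.norm(z), True
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    xt = (x - med) * w
    norm = np.linalg.norm(xt)
    if norm == 0:
        raise ValidationError("all observations rejected by the biweight")
    return xt / norm, False


def bicor(x, y) -> float:
    """Biweight midcorrelation of two equal-length vectors.

    Each vector is median-centered and weighted by
    ``w_i = (1 - u_i^2)^2 * 1[|u_i| < 1]`` with
    ``u_i = (x_i - med x) / (9 MAD_x)``; the correlation is the cosine of
    the weighted, centered vectors.  A zero-MAD vector falls back to the
    Pearson z-score (the standard degenerate rule) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("bicor needs two equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("bicor needs n >= 3")
    xt, x_fb = _bicor_prepare(x)
    yt, y_fb = _bicor_prepare(y)
    if x_fb or y_fb:
        warnings.warn("zero MAD: Pearson fallback used", stacklevel=2)
    return float(np.clip(xt @ yt, -1.0, 1.0))


def bicor_matrix(data: np.ndarray | pd.DataFrame) -> np.ndarray:
    """All-pairs biweight midcorrelation of the columns of ``data``."""
    x = np.asarray(data, dtype=float)
    cols = []
    for j in range(x.shape[1]):
        cols.append(_bicor_prepare(x[:, j])[0])
    m = np.column_stack(cols)
    r = np.clip(m.T @ m, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def correlation_test(r: float, n: int) -> CorrelationResult:
    """Two-sided Student-t test of a correlation coefficient (df = n - 2)."""
    if n < 3:
        raise ValidationError("correlation test needs n >= 3")
    df = n - 2
    if abs(r) >= 1.0:
        return CorrelationResult(float(np.sign(r)), n, np.inf * np.sign(r), df, 0.0,
                                 exact=True)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(float(r), n, float(t), df, float(p))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def edge_statistics(rel: pd.DataFrame) -> pd.DataFrame:
    """Per-pair bicor, t, p, and BH q over all unordered ASV pairs.

    ``rel``: ASV-by-sample relative abundances (rows are ASVs).
    """
    ids = list(rel.index)
    n = rel.shape[1]
    r = bicor_matrix(rel.to_numpy().T)
    iu = np.triu_indices(len(ids), 1)
    rvals = r[iu]
    df = n - 2
    with np.errstate(divide="ignore"):
        tvals = rvals * np.sqrt(df) / np.sqrt(np.maximum(1.0 - rvals**2, 0.0))
    pvals = np.where(np.abs(rvals) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(tvals), df))
    qvals = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "source": [ids[i] for i in iu[0]],
            "target": [ids[j] for j in iu[1]],
            "r": rvals,
            "t": tvals,
            "p": pvals,
            "q": qvals,
        }
    )


def _prevalence_nodes(table: AbundanceTable, threshold: float) -> list:
    present = (table.counts > 0).mean(axis=1)
    return present[present >= threshold].index.tolist()


def build_network(table: AbundanceTable, cfg: NetworkConfig | None = None) -> nx.Graph:
    """Infer the ASV co-occurrence network.

    Nodes are ASVs observed in at least ``cfg.prevalence_threshold`` of
    samples, annotated with their mean relative abundance.  Edges follow
    ``cfg.edge_method`` (see module docstring).
    """
    cfg = cfg or NetworkConfig()
    if table.n_samples < 4:
        raise ValidationError("network inference needs at least 4 samples")
    nodes = _prevalence_nodes(table, cfg.prevalence_threshold)
    if len(nodes) < 2:
        raise ValidationError("fewer than 2 ASVs pass the prevalence threshold")
    rel = relative_abundance(table.counts).loc[nodes]

    net = nx.Graph()
    mean_rel = rel.mean(axis=1)
    for node in nodes:
        net.add_node(
            node,
            mean_rel_abundance=float(mean_rel[node]),
            guild=None, indicator=None, mag_id=None, expression=None,
        )

    if cfg.edge_method == "bicor_fdr":
        edges = edge_statistics(rel)
        keep = edges["q"] < cfg.fdr_alpha
        if cfg.positive_edges_only:
            keep &= edges["r"] > 0
        for row in edges[keep].itertuples(index=False):
            net.add_edge(row.source, row.target, weight=float(row.r),
                         qvalue=float(row.q))
    else:
        clr = clr_transform(table.counts.loc[nodes], cfg.clr_pseudocount)
        precision_net = sparse_precision_network(clr, cfg)
        for u, v, d in precision_net.edges(data=True):
            if cfg.positive_edges_only and d["weight"] <= 0:
                continue
            net.add_edge(u, v, **d)
    return net


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform, per sample (column).

    ``clr(x)_i = log((x_i + pc) / g)`` with ``g`` the geometric mean of the
    pseudocounted composition; each column sums to zero.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    x = counts.to_numpy(dtype=float) + pseudocount
    if (x <= 0).any():
        raise ValidationError("counts must be >= 0")
    logx = np.log(x)
    return pd.DataFrame(
        logx - logx.mean(axis=0, keepdims=True),
        index=counts.index, columns=counts.columns,
    )


def _glasso_adjacency(cov: np.ndarray, lam: float) -> np.ndarray | None:
    """Boolean adjacency of the graphical-lasso estimate, None on failure."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, precision = graphical_lasso(cov, alpha=lam, max_iter=200)
    except Exception:
        return None
    adj = np.abs(precision) > 1e-8
    np.fill_diagonal(adj, False)
    return adj


def sparse_precision_network(clr: pd.DataFrame, cfg: NetworkConfig | None = None) -> nx.Graph:
    """Graphical-lasso network with StARS penalty selection.

    ``clr``: ASV-by-sample CLR matrix.  The penalty path is log-spaced from
    ``lambda_max`` (largest absolute off-diagonal covariance, at which the
    graph is empty) down to ``lambda_max * lambda_min_ratio``.  StARS
    estimates per-edge selection frequencies over seeded subsamples of size
    ``min(n, floor(10 sqrt(n)))`` and selects the smallest penalty (densest
    graph) whose monotonized average edge instability stays within the
    threshold.
    Edge weights are sign-carrying partial correlations
    ``-theta_ij / sqrt(theta_ii theta_jj)``.
    """
    cfg = cfg or NetworkConfig()
    ids = list(clr.index)
    x = clr.to_numpy(dtype=float).T  # samples x ASVs
    n, p = x.shape
    if n < 4:
        raise ValidationError("need at least 4 samples")
    cov = np.cov(x, rowvar=False)
    lam_max = np.abs(cov - np.diag(np.diag(cov))).max()
    if lam_max == 0:
        raise ValidationError("degenerate covariance: no off-diagonal signal")
    path = np.geomspace(lam_max, lam_max * cfg.glasso_lambda_min_ratio,
                        cfg.glasso_path_length)

    b = cfg.stars_subsample_size or min(n, int(np.floor(10 * np.sqrt(n))))
    rng = np.random.default_rng(cfg.seed)
    freq = np.zeros((len(path), p, p))
    valid = np.zeros(len(path), dtype=int)
    for _ in range(cfg.stars_subsamples):
        idx = rng.choice(n, size=b, replace=False)
        sub_cov = np.cov(x[idx], rowvar=False)
        for k, lam in enumerate(path):
            adj = _glasso_adjacency(sub_cov, lam)
            if adj is None:
                continue
            freq[k] += adj
            valid[k] += 1

    instability = np.full(len(path), np.inf)
    for k in range(len(path)):
        if valid[k] == 0:
            warnings.warn(f"glasso failed at every subsample for lambda={path[k]:.3g}")
            continue
        xi = freq[k] / valid[k]
        d = 2 * xi * (1 - xi)
        iu = np.triu_indices(p, 1)
        instability[k] = d[iu].mean()
    # monotonize: instability can only grow as lambda shrinks
    mono = np.maximum.accumulate(instability)
    within = np.where(mono <= cfg.stars_instability_threshold)[0]
    k_star = within[-1] if len(within) else 0
    lam_star = path[k_star]

    adj = _glasso_adjacency(cov, lam_star)
    if adj is None:
        raise ValidationError("graphical lasso failed at the selected penalty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, precision = graphical_lasso(cov, alpha=lam_star, max_iter=200)
    net = nx.Graph()
    net.add_nodes_from(ids)
    net.graph["lambda_star"] = float(lam_star)
    net.graph["lambda_path"] = [float(l) for l in path]
    diag = np.sqrt(np.diag(precision))
    for i in range(p):
        for j in range(i + 1, p):
            if adj[i, j]:
                pcor = -precision[i, j] / (diag[i] * diag[j])
                net.add_edge(ids[i], ids[j], weight=float(pcor), qvalue=np.nan)
    return net


def avg_clustering_coefficient(net: nx.Graph, exclude_low_degree: bool = False) -> float:
    """Mean local clustering coefficient ``2 T_i / (k_i (k_i - 1))``.

    Nodes of degree < 2 contribute 0 by default; ``exclude_low_degree``
    averages over degree >= 2 nodes only (the other common convention).
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    local = nx.clustering(net)
    if exclude_low_degree:
        vals = [c for node, c in local.items() if net.degree(node) >= 2]
        if not vals:
            return 0.0
        return float(np.mean(vals))
    return float(np.mean(list(local.values())))
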