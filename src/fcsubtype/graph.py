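"""Cost-efficiency thresholding, binary graph metrics, and node-wise GLM.

Each connectome is sparsified by proportional thresholding: the upper
triangle is ranked by |r| and the strongest fraction PSW of edges is
kept and binarised.  PSW is chosen per subject by exhaustively maximising
the global cost-efficiency

    GCE(PSW) = E(PSW) - PSW,

over PSW in {0.00, 0.01, ..., 1.00}, where E is the global efficiency
of the binarised graph: E = mean_i E_i with
E_i = sum_{j != i} d_ij^{-1} / (n - 1) and d_ij the unweighted
shortest-path length (unreachable pairs contribute 0).

Four node metrics are computed on the thresholded binary graph from
first principles (no graph library): clustering coefficient, k-coreness,
local efficiency (global efficiency of the neighbour-induced subgraph)
and strength (binary degree by default).  Metrics are z-scored within
each subject across regions to remove per-subject scale, then compared
between groups node-wise with an OLS GLM (group indicator + age + sex),
with Benjamini-Hochberg FDR over the regions of each metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .connectome import ConnectivityMatrix

logger = logging.getLogger("fcsubtype")

__all__ = [
    "ThresholdedGraph",
    "GCECurve",
    "threshold_at_psw",
    "shortest_path_lengths",
    "global_efficiency",
    "gce_optimal_psw",
    "node_metrics",
    "normalize_within_subject",
    "glm_node_test",
    "fdr_adjust",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("clustering_coefficient", "kcoreness", "local_efficiency", "strength")


@dataclass
class ThresholdedGraph:
    subject_id: str
    psw: float
    adjacency: np.ndarray  # binary, symmetric, hollow
    retained_weights: np.ndarray | None = None
    region_labels: list[str] = field(default_factory=list)


@dataclass
class GCECurve:
    psw_grid: np.ndarray
    e_values: np.ndarray
    gce_values: np.ndarray
    optimal_psw: float


def threshold_at_psw(cm: ConnectivityMatrix, psw: float,
                     use_magnitude: bool = True) -> ThresholdedGraph:
    """Keep the strongest fraction ``psw`` of edges and binarise.

    Edges are ranked by |r| (or signed r with ``use_magnitude=False``)
    descending; exactly round(psw * n(n-1)/2) edges are retained.  Ties
    at the cutoff are broken by row-major (i, j) position, which makes
    the retained edge sets nested across psw values.
    """
    if not 0.0 <= psw <= 1.0:
        raise ValueError(f"psw must be in [0, 1], got {psw}")
    n = cm.n
    iu = np.triu_indices(n, k=1)
    w = cm.r[iu]
    key = np.abs(w) if use_magnitude else w
    m = w.size
    keep = int(np.floor(psw * m + 0.5))
    order = np.argsort(-key, kind="stable")  # stable: ties keep row-major order
    sel = order[:keep]
    adj = np.zeros((n, n), dtype=np.int8)
    rw = np.zeros((n, n))
    ii, jj = iu[0][sel], iu[1][sel]
    adj[ii, jj] = adj[jj, ii] = 1
    rw[ii, jj] = rw[jj, ii] = w[sel]
    return ThresholdedGraph(cm.subject_id, float(psw), adj, rw, list(cm.region_labels))


def shortest_path_lengths(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths by simultaneous BFS.

    Returns an n x n float matrix with inf for unreachable pairs and 0
    on the diagonal.
    """
    a = np.asarray(adj) > 0
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    d = 0
    while frontier.any():
        d += 1
        nxt = (frontier.astype(float) @ a) > 0
        nxt &= ~reached
        dist[nxt] = d
        reached |= nxt
        frontier = nxt
    return dist


def global_efficiency(g: ThresholdedGraph | np.ndarray) -> tuple[float, np.ndarray]:
    """Global efficiency E and the per-node efficiencies E_i."""
    adj = g.adjacency if isinstance(g, ThresholdedGraph) else np.asarray(g)
    n = adj.shape[0]
    if n < 2:
        return 0.0, np.zeros(n)
    dist = shortest_path_lengths(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    e_i = inv.sum(axis=1) / (n - 1)
    return float(e_i.mean()), e_i


def gce_optimal_psw(cm: ConnectivityMatrix, use_magnitude: bool = True) -> GCECurve:
    """Exhaustive search of GCE = E - PSW over the 101-point PSW grid.

    Ties at the maximum resolve to the smallest psw (cheapest network).
    """
    grid = np.round(np.arange(101) / 100.0, 2)
    e_vals = np.empty(101)
    for idx, psw in enumerate(grid):
        e_vals[idx], _ = global_efficiency(threshold_at_psw(cm, psw, use_magnitude))
    gce = e_vals - grid
    best = int(np.argmax(gce))  # first max = smallest psw
    curve = GCECurve(grid, e_vals, gce, float(grid[best]))
    logger.info("GCE search %s: optimal psw=%.2f (E=%.3f)",
                cm.subject_id, curve.optimal_psw, e_vals[best])
    return curve


def _kcore_numbers(adj: np.ndarray) -> np.ndarray:
    """Core number per node: largest k such that the node survives
    iterative deletion of all nodes with degree < k."""
    a = (np.asarray(adj) > 0).astype(int)
    n = a.shape[0]
    alive = np.ones(n, dtype=bool)
    core = np.zeros(n, dtype=int)
    k = 0
    while alive.any():
        # peel every remaining node whose degree (within survivors) is <= k
        while alive.any():
            idx = np.flatnonzero(alive)
            deg = a[np.ix_(alive, alive)].sum(axis=1)
            low = idx[deg <= k]
            if low.size == 0:
                break
            core[low] = k
            alive[low] = False
        k += 1
    return core


def node_metrics(g: ThresholdedGraph, weighted_strength: bool = False) -> pd.DataFrame:
    """Per-region metrics on the binary thresholded graph.

    clustering_coefficient(i) = 2 T_i / (d_i (d_i - 1)) with T_i the
    triangles through i (0 when d_i < 2); kcoreness(i) is the node's core
    number; local_efficiency(i) is the global efficiency of the subgraph
    induced by i's neighbours (0 with < 2 neighbours); strength(i) is the
    binary degree, or the sum of retained |weights| with
    ``weighted_strength``.
    """
    a = (np.asarray(g.adjacency) > 0).astype(float)
    n = a.shape[0]
    deg = a.sum(axis=1)
    tri = ((a @ a) * a).sum(axis=1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(deg >= 2, 2.0 * tri / (deg * (deg - 1)), 0.0)
    core = _kcore_numbers(a)
    leff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size >= 2:
            leff[i], _ = global_efficiency(a[np.ix_(nbrs, nbrs)])
    if weighted_strength:
        if g.retained_weights is None:
            raise ValueError("weighted strength requested but no retained weights stored")
        strength = np.abs(g.retained_weights).sum(axis=1)
    else:
        strength = deg
    labels = g.region_labels or [f"R{i:03d}" for i in range(n)]
    return pd.DataFrame({
        "subject_id": g.subject_id,
        "region_label": labels,
        "clustering_coefficient": cc,
        "kcoreness": core.astype(float),
        "local_efficiency": leff,
        "strength": strength.astype(float),
    })


def normalize_within_subject(table: pd.DataFrame,
                             metrics: tuple[str, ...] = METRIC_COLUMNS) -> pd.DataFrame:
    """Z-score each metric across regions, separately per subject.

    Removes per-subject scale and amplitude so that node values are
    comparable across individuals.  A metric that is constant across a
    subject's regions normalises to all zeros (logged as degenerate).
    """
    out = table.copy()
    for sid, idx in table.groupby("subject_id").groups.items():
        for m in metrics:
            x = table.loc[idx, m].to_numpy(dtype=float)
            sd = x.std()
            if sd == 0:
                logger.warning("subject %s: metric %s constant across regions; "
                               "normalised to zeros", sid, m)
                out.loc[idx, f"{m}_norm"] = 0.0
            else:
                out.loc[idx, f"{m}_norm"] = (x - x.mean()) / sd
    return out


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) m / j over the ascending ordering, clipped
    at 1, returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def glm_node_test(table: pd.DataFrame, meta: pd.DataFrame,
                  contrast: tuple[str, str],
                  metrics: tuple[str, ...] = METRIC_COLUMNS,
                  use_normalized: bool = True,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Node-wise OLS of metric ~ group + age + sex, FDR per metric.

    ``contrast`` names the two groups compared; the indicator is 1 for
    the first group.  Sex is coded M=1, F=0.  One model per (region,
    metric) — the univariate approach — with BH-FDR applied across
    regions within each metric.
    """
    g1, g2 = contrast
    sub = meta[meta["group"].isin(contrast)].copy()
    if (sub["group"] == g1).sum() == 0 or (sub["group"] == g2).sum() == 0:
        raise ValueError(f"both contrast groups must be nonempty: {contrast}")
    sub["_ind"] = (sub["group"] == g1).astype(float)
    sub["_sex"] = (sub["sex"] == "M").astype(float)
    design = sm.add_constant(sub[["_ind", "age", "_sex"]].to_numpy(dtype=float),
                             has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient (e.g. a single-sex or "
                         "single-age contrast); cannot fit the GLM")
    merged = table.merge(sub[["subject_id", "_ind", "age", "_sex"]], on="subject_id")
    rows = []
    for metric in metrics:
        col = f"{metric}_norm" if use_normalized else metric
        if col not in merged.columns:
            raise KeyError(f"metric column {col!r} missing; run normalize_within_subject first")
        for region, rsub in merged.groupby("region_label", sort=False):
            y = rsub[col].to_numpy(dtype=float)
            X = sm.add_constant(rsub[["_ind", "age", "_sex"]].to_numpy(dtype=float),
                                has_constant="add")
            fit = sm.OLS(y, X).fit()
            rows.append({"region_label": region, "metric": metric,
                         "beta_subtype": float(fit.params[1]),
                         "t": float(fit.tvalues[1]),
                         "p": float(fit.pvalues[1])})
    res = pd.DataFrame(rows)
    res["q"] = np.nan
    for metric in metrics:
        mask = res["metric"] == metric
        p = res.loc[mask, "p"].clip(lower=np.finfo(float).tiny).to_numpy()
        res.loc[mask, "q"] = fdr_adjust(p)
    res["significant"] = res["q"] < alpha
    return res
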