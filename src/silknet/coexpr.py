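"""Weighted co-expression networks: |Pearson| similarity, soft-threshold
adjacency, topological overlap, and average-linkage module detection."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

UNASSIGNED = "unassigned"


def pearson_similarity(expr: pd.DataFrame) -> pd.DataFrame:
    """s_ij = |cor(x_i, x_j)| across the columns of ``expr`` (genes in rows)."""
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 columns to correlate")
    var = expr.var(axis=1, ddof=0)
    if (var == 0).any():
        bad = expr.index[var == 0][0]
        raise ValueError(f"zero-variance gene {bad!r}: remove non-varying genes first")
    sim = np.abs(np.corrcoef(expr.to_numpy(float)))
    np.fill_diagonal(sim, 1.0)
    sim = np.clip(sim, 0.0, 1.0)
    return pd.DataFrame(sim, index=expr.index, columns=expr.index)


def soft_adjacency(sim: pd.DataFrame, beta: float) -> pd.DataFrame:
    """a_ij = s_ij ** beta, element-wise."""
    if beta < 1:
        raise ValueError("soft-threshold power must be >= 1")
    return sim**beta


def _connectivity(adj: np.ndarray) -> np.ndarray:
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10(frequency) on log10(mean connectivity).

    Connectivities are discretized into equal-width bins; empty bins are
    skipped.  R^2 is reported as 0 when the slope is positive.
    """
    k = np.asarray(k, dtype=float)
    if np.all(k == 0):
        raise ValueError("all connectivities are zero")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        xs.append(np.log10(mk))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * np.asarray(xs) + intercept
    ss_res = np.sum((np.asarray(ys) - fitted) ** 2)
    ss_tot = np.sum((np.asarray(ys) - np.mean(ys)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if slope > 0:
        r2 = 0.0
    return float(r2), float(slope)


def pick_soft_threshold(
    sim: pd.DataFrame,
    candidates=range(1, 21),
    r2_target: float = 0.85,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Scan candidate powers for approximate scale-free topology.

    Returns (chosen beta, report).  Chosen beta is the smallest candidate with
    R^2 >= target, else the candidate maximizing R^2.
    """
    if sim.shape[0] < 30:
        raise ValueError("need >= 30 genes for a meaningful scale-free fit")
    rows = []
    for beta in candidates:
        adj = soft_adjacency(sim, beta).to_numpy()
        k = _connectivity(adj)
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {"beta": int(beta), "r_squared": r2, "slope": slope, "mean_k": float(k.mean())}
        )
    report = pd.DataFrame(rows)
    ok = report[report["r_squared"] >= r2_target]
    if len(ok):
        chosen = int(ok["beta"].iloc[0])
    else:
        chosen = int(report.loc[report["r_squared"].idxmax(), "beta"])
    return chosen, report


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    L_ij = sum_u a_iu a_uj over u != i, j; diagonal set to 1.
    """
    a = adj.to_numpy(float).copy()
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l_mat = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l_mat + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def _relabel(genes: pd.Index, raw: np.ndarray, min_module_size: int) -> pd.Series:
    """Deterministic labels: modules ordered by size desc, ties by smallest
    member gene id; undersized clusters become 'unassigned'."""
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    keep = {c: sorted(m) for c, m in clusters.items() if len(m) >= min_module_size}
    ordered = sorted(keep.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    labels = pd.Series(UNASSIGNED, index=genes, dtype=object)
    for rank, (_, members) in enumerate(ordered, start=1):
        labels.loc[members] = f"M{rank}"
    return labels


def detect_modules(
    tom: pd.DataFrame, cut_height: float = 0.995, min_module_size: int = 30
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static tree cut."""
    if tom.shape[0] != tom.shape[1]:
        raise ValueError("TOM must be square")
    if not 0 < cut_height < 1:
        raise ValueError("cut_height must lie in (0, 1)")
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    diss = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    return _relabel(tom.index, raw, min_module_size)


def consensus_modules(
    tom_d: pd.DataFrame,
    tom_w: pd.DataFrame,
    cut_height: float = 0.995,
    min_module_size: int = 30,
    scale_quantile: float = 0.95,
) -> pd.Series:
    """Modules shared by both conditions.

    Each TOM is scaled so its ``scale_quantile`` off-diagonal value matches the
    first TOM's; the consensus TOM is the element-wise minimum.
    """
    if not tom_d.index.equals(tom_w.index):
        raise ValueError("gene index mismatch between the two TOMs")
    d = tom_d.to_numpy(float)
    w = tom_w.to_numpy(float)
    off = ~np.eye(d.shape[0], dtype=bool)
    q_d = np.quantile(d[off], scale_quantile)
    q_w = np.quantile(w[off], scale_quantile)
    if q_w > 0 and q_d > 0:
        w = np.minimum(w * (q_d / q_w), 1.0)
    cons = np.minimum(d, w)
    np.fill_diagonal(cons, 1.0)
    cons_df = pd.DataFrame(cons, index=tom_d.index, columns=tom_d.columns)
    return detect_modules(cons_df, cut_height=cut_height, min_module_size=min_module_size)
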