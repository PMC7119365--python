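"""Differential co-expression between conditions and seed-gene networks.

An edge is differential when the ratio of its larger to smaller network weight
(TOM by default) exceeds a fold-change threshold.  Condition-specific networks
connect seed genes to differentially expressed partners from the seed-bearing
modules, and can be pruned to partners carrying a selection signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpr import UNASSIGNED

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_WEIGHT_FLOOR = 0.05


@dataclass
class ConditionNetwork:
    """Edge list plus per-node degrees for one condition."""

    condition: str
    seeds: list[str]
    edges: pd.DataFrame  # columns: seed, partner, weight, fold_change
    nodes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.nodes:
            partners = sorted(set(self.edges["partner"])) if len(self.edges) else []
            self.nodes = sorted(set(self.seeds) | set(partners))

    @property
    def degrees(self) -> pd.Series:
        deg = pd.Series(0, index=pd.Index(self.nodes, name="gene"), dtype=int)
        for _, row in self.edges.iterrows():
            deg[row["seed"]] += 1
            deg[row["partner"]] += 1
        return deg

    def seed_degrees(self) -> pd.Series:
        deg = self.degrees
        return deg.reindex(self.seeds).fillna(0).astype(int)


def edge_fold_change(
    w_d: float, w_w: float, epsilon_floor: float = 1e-12
) -> tuple[float, str | None]:
    """Fold change max/min of two edge weights and the favored condition.

    Returns (fc, favored) with favored in {'domestic', 'wild', None}; fc is
    inf when the smaller weight is exactly 0 and the larger is positive, and
    1 when both are 0.
    """
    for w in (w_d, w_w):
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"edge weight {w} outside [0, 1]")
    hi, lo = max(w_d, w_w), min(w_d, w_w)
    if hi == 0.0:
        return 1.0, None
    favored = "domestic" if w_d > w_w else ("wild" if w_w > w_d else None)
    if lo == 0.0:
        return math.inf, favored
    # the epsilon clamp is for the division only; FC is still >= 1
    fc = max(hi / max(lo, epsilon_floor), 1.0)
    return fc, favored


def differential_edges(
    tom_d: pd.DataFrame,
    tom_w: pd.DataFrame,
    node_universe=None,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    min_weight: float = 0.0,
) -> pd.DataFrame:
    """All pairs whose weight fold change strictly exceeds the threshold.

    ``min_weight`` optionally drops pairs whose larger weight is below an
    absolute floor (a bare fold change admits edges between near-zero
    weights).  Rows are ordered lexicographically by (gene1, gene2) with
    gene1 < gene2.
    """
    if not tom_d.index.equals(tom_w.index):
        raise ValueError("gene index mismatch between the two TOMs")
    genes = list(tom_d.index) if node_universe is None else sorted(node_universe)
    missing = [g for g in genes if g not in tom_d.index]
    if missing:
        raise ValueError(f"gene {missing[0]!r} absent from the TOMs")
    d = tom_d.loc[genes, genes].to_numpy(float)
    w = tom_w.loc[genes, genes].to_numpy(float)
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    wd, ww = d[iu, ju], w[iu, ju]
    hi = np.maximum(wd, ww)
    lo = np.minimum(wd, ww)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(hi == 0.0, 1.0, np.where(lo == 0.0, np.inf, hi / lo))
    keep = (fc > fc_threshold) & (hi >= min_weight)
    rows = pd.DataFrame(
        {
            "gene1": np.asarray(genes)[iu[keep]],
            "gene2": np.asarray(genes)[ju[keep]],
            "weight_d": wd[keep],
            "weight_w": ww[keep],
            "fold_change": fc[keep],
            "favored": np.where(wd[keep] > ww[keep], "domestic", "wild"),
        }
    )
    return rows.sort_values(["gene1", "gene2"], ignore_index=True)


def build_seed_networks(
    seeds: list[str],
    module_assignment: pd.Series,
    deg_genes: set[str],
    diff_edges: pd.DataFrame,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
) -> dict[str, ConditionNetwork]:
    """Condition-specific networks of seed genes and their DEG partners.

    Candidate partners are DEGs sharing a module with at least one seed; an
    edge (seed, partner) enters the condition-c network iff it is a
    differential edge favoring c with weight in c >= ``weight_floor``.
    """
    present = [s for s in seeds if s in module_assignment.index]
    if not present:
        raise ValueError("no seed gene present after filtering")
    seed_modules = {
        m for m in module_assignment.reindex(present) if m != UNASSIGNED and pd.notna(m)
    }
    candidates = {
        g
        for g in module_assignment.index[module_assignment.isin(seed_modules)]
        if g in deg_genes and g not in present
    }

    nets = {}
    for cond, wcol in (("domestic", "weight_d"), ("wild", "weight_w")):
        rows = []
        for rec in diff_edges.itertuples(index=False):
            if rec.favored != cond:
                continue
            pair = {rec.gene1, rec.gene2}
            seed_side = pair & set(present)
            partner_side = pair & candidates
            if len(seed_side) != 1 or len(partner_side) != 1:
                continue
            weight = getattr(rec, wcol)
            if weight < weight_floor:
                continue
            rows.append(
                {
                    "seed": seed_side.pop(),
                    "partner": partner_side.pop(),
                    "weight": weight,
                    "fold_change": rec.fold_change,
                }
            )
        edges = pd.DataFrame(rows, columns=["seed", "partner", "weight", "fold_change"])
        edges = edges.sort_values(["seed", "partner"], ignore_index=True)
        nets[cond] = ConditionNetwork(condition=cond, seeds=sorted(present), edges=edges)
    return nets


def seed_degree_table(networks: dict[str, ConditionNetwork]) -> pd.DataFrame:
    """Per-seed partner degree in each condition network."""
    return pd.DataFrame({cond: net.seed_degrees() for cond, net in networks.items()})


def prune_by_selection(
    network: ConditionNetwork, selected_genes: set[str]
) -> ConditionNetwork:
    """Drop partner nodes lacking a selection signature; seeds are kept."""
    edges = network.edges[network.edges["partner"].isin(selected_genes)].reset_index(
        drop=True
    )
    return ConditionNetwork(condition=network.condition, seeds=list(network.seeds), edges=edges)
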