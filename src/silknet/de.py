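"""Stage-matched differential expression via a negative-binomial exact test.

Counts for the two groups are deterministically rescaled to a common library
size; the test conditions on the rescaled total and sums the probabilities of
all splits at most as likely as the observed one.  Benjamini-Hochberg
adjustment is applied within each stage contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

REPLICATED_ADJ_P = 0.05
NONREPLICATED_ADJ_P = 0.01
LOG2FC_CUT = 1.0


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def estimate_common_dispersion(
    counts: pd.DataFrame, groups: pd.Series, eff_lib: pd.Series
) -> float:
    """Method-of-moments common NB dispersion on library-size-scaled counts.

    phi = median over genes of max(0, (s^2 - mbar) / mbar^2), with s^2 the
    pooled within-group variance and mbar the mean of the scaled counts.
    Requires at least one group with >= 2 replicates.
    """
    groups = groups.reindex(counts.columns)
    sizes = groups.value_counts()
    rep_groups = sizes.index[sizes >= 2]
    if len(rep_groups) == 0:
        raise ValueError(
            "no replicated group: cannot estimate dispersion; use a fixed dispersion"
        )
    common = float(np.exp(np.mean(np.log(eff_lib.reindex(counts.columns)))))
    scaled = counts.div(eff_lib.reindex(counts.columns), axis=1) * common

    ss = np.zeros(counts.shape[0])
    dof = 0
    vals = []
    for g in rep_groups:
        cols = groups.index[groups == g]
        sub = scaled[cols].to_numpy(float)
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += len(cols) - 1
        vals.append(sub)
    s2 = ss / dof
    mbar = np.concatenate(vals, axis=1).mean(axis=1)
    ok = mbar > 0
    phi_g = np.maximum(0.0, (s2[ok] - mbar[ok]) / mbar[ok] ** 2)
    if phi_g.size == 0:
        return 0.0
    return float(np.median(phi_g))


def nb_exact_test(
    counts_a, counts_b, libsizes_a, libsizes_b, phi: float
) -> float:
    """Two-sided exact p-value for a difference in NB means between groups.

    Counts are rescaled to the geometric-mean common library size and rounded;
    conditional on the rescaled total, group-A's sum is compared against the
    NB (or, for phi = 0, binomial) split distribution.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative counts")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    la = np.asarray(libsizes_a, dtype=float)
    lb = np.asarray(libsizes_b, dtype=float)
    common = np.exp(np.mean(np.log(np.concatenate([la, lb]))))
    sa = int(np.round(a * common / la).sum())
    sb = int(np.round(b * common / lb).sum())
    t = sa + sb
    if t == 0:
        return 1.0
    na, nb = a.size, b.size
    x = np.arange(t + 1)
    if phi == 0.0:
        logg = stats.binom.logpmf(x, t, na / (na + nb))
    else:
        mu = t / (na + nb)
        ra, rb = na / phi, nb / phi
        pa = ra / (ra + na * mu)
        pb = rb / (rb + nb * mu)
        logg = stats.nbinom.logpmf(x, ra, pa) + stats.nbinom.logpmf(t - x, rb, pb)
        logg -= np.logaddexp.reduce(logg)
    g = np.exp(logg)
    p = float(g[g <= g[sa] * (1.0 + 1e-10)].sum())
    return min(p, 1.0)


def _log2fc(counts_a, counts_b, eff_a, eff_b, pseudo: float = 0.5) -> float:
    # normalized group means with a per-group pseudo-count; domestic = group A
    mean_a = float(np.mean(np.asarray(counts_a) / np.asarray(eff_a))) * 1e6
    mean_b = float(np.mean(np.asarray(counts_b) / np.asarray(eff_b))) * 1e6
    return float(np.log2((mean_a + pseudo) / (mean_b + pseudo)))


def de_contrast(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    stage: str,
    norm: pd.DataFrame,
    condition_a: str = "domestic",
    condition_b: str = "wild",
    dispersion: float | None = None,
    fixed_dispersion: float = 0.1,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Test every gene for condition A vs B at one stage.

    Returns a frame with gene, stage, log2fc, p_value, adj_p, replicated,
    is_deg, direction.  ``dispersion=None`` triggers estimation when both
    groups are replicated, else the fixed default is used.
    """
    if "condition" not in design.columns:
        raise ValueError("sample sheet lacks a 'condition' column")
    sel = design[design["stage"] == stage]
    cols_a = [s for s in sel.index[sel["condition"] == condition_a] if s in counts.columns]
    cols_b = [s for s in sel.index[sel["condition"] == condition_b] if s in counts.columns]
    if not cols_a or not cols_b:
        raise ValueError(f"stage {stage!r}: missing samples for one condition")
    replicated = min(len(cols_a), len(cols_b)) >= 2

    eff = (norm["lib_size"] * norm["factor"]).astype(float)
    if dispersion is None:
        if replicated:
            groups = pd.Series(
                [condition_a] * len(cols_a) + [condition_b] * len(cols_b),
                index=cols_a + cols_b,
            )
            dispersion = estimate_common_dispersion(
                counts[cols_a + cols_b], groups, eff
            )
        else:
            dispersion = fixed_dispersion

    mat_a = counts[cols_a].to_numpy(float)
    mat_b = counts[cols_b].to_numpy(float)
    la = eff.reindex(cols_a).to_numpy()
    lb = eff.reindex(cols_b).to_numpy()

    pvals = np.empty(counts.shape[0])
    lfc = np.empty(counts.shape[0])
    for i in range(counts.shape[0]):
        pvals[i] = nb_exact_test(mat_a[i], mat_b[i], la, lb, dispersion)
        lfc[i] = _log2fc(mat_a[i], mat_b[i], la, lb, pseudo)

    out = pd.DataFrame(
        {
            "gene": counts.index,
            "stage": stage,
            "log2fc": lfc,
            "p_value": pvals,
            "adj_p": bh_adjust(pvals),
            "replicated": replicated,
        }
    ).set_index("gene", drop=False)
    return call_degs(out)


def call_degs(results: pd.DataFrame) -> pd.DataFrame:
    """Flag DEGs: |log2FC| > 1 and adj_p < 0.05 (replicated) / < 0.01 (not)."""
    if "replicated" not in results.columns or results["replicated"].isna().any():
        raise ValueError("every result needs a replicated/non-replicated tag")
    out = results.copy()
    cut = np.where(out["replicated"], REPLICATED_ADJ_P, NONREPLICATED_ADJ_P)
    out["is_deg"] = (np.abs(out["log2fc"]) > LOG2FC_CUT) & (out["adj_p"] < cut)
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def run_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    norm: pd.DataFrame,
    stages: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Run the per-stage contrast across all stages; BH within each stage."""
    if stages is None:
        stages = list(dict.fromkeys(design["stage"]))
    frames = [de_contrast(counts, design, st, norm, **kwargs) for st in stages]
    return pd.concat(frames, ignore_index=True)


def deg_summary(results: pd.DataFrame) -> dict[str, int]:
    """Per-stage DEG counts."""
    return {
        st: int(sub["is_deg"].sum()) for st, sub in results.groupby("stage", sort=False)
    }
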