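"""Count normalization (TMM), FPKM, replicate collapsing, and expression filters."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def library_sizes(counts: pd.DataFrame) -> pd.Series:
    """Per-sample library size = column sum of counts."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    return lib


def _choose_reference(counts: pd.DataFrame, lib: pd.Series) -> str:
    # canonical auto choice: sample whose upper-quartile of scaled counts is
    # closest to the mean upper-quartile
    uq = counts.div(lib, axis=1).quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def compute_tmm_factors(
    counts: pd.DataFrame,
    reference_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.DataFrame:
    """Weighted trimmed-mean-of-M-values scaling factors.

    For each sample against the reference: per-gene log2 ratios M and average
    log-abundances A are computed on library-size-scaled counts, genes with a
    zero count in either sample are dropped, the top/bottom ``trim_m`` of M and
    ``trim_a`` of A are trimmed, and the remaining M are averaged with
    inverse-asymptotic-variance weights.  Factors are rescaled to geometric
    mean 1.

    Returns a frame with columns ``factor`` and ``lib_size`` indexed by sample.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = library_sizes(counts)
    ref = reference_sample if reference_sample is not None else _choose_reference(counts, lib)
    if ref not in counts.columns:
        raise ValueError(f"reference sample {ref!r} not in count matrix")

    y_r = counts[ref].to_numpy(float)
    n_r = lib[ref]
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        y_s = counts[s].to_numpy(float)
        n_s = lib[s]
        keep = (y_s > 0) & (y_r > 0)
        ys, yr = y_s[keep], y_r[keep]
        m = np.log2((ys / n_s) / (yr / n_r))
        a = 0.5 * np.log2((ys / n_s) * (yr / n_r))
        v = (n_s - ys) / (n_s * ys) + (n_r - yr) / (n_r * yr)
        n = m.size
        if n == 0:
            raise ValueError(f"no genes usable for TMM between {s!r} and {ref!r}")
        # doubly trimmed: keep genes inside both rank windows
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m)
        ra = rankdata(a)
        trimmed = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not trimmed.any():
            factors[s] = 1.0
            continue
        w = 1.0 / v[trimmed]
        f = np.sum(w * m[trimmed]) / np.sum(w)
        factors[s] = float(2.0**f)

    fac = pd.Series(factors).reindex(counts.columns)
    fac /= np.exp(np.mean(np.log(fac)))
    return pd.DataFrame({"factor": fac, "lib_size": lib})


def compute_fpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, norm: pd.DataFrame
) -> pd.DataFrame:
    """FPKM(g, s) = count * 1e9 / (length * lib_size * factor)."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        bad = counts.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {bad!r}")
    if (lengths <= 0).any():
        bad = counts.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    eff = norm["lib_size"] * norm["factor"]
    return counts.div(eff.reindex(counts.columns), axis=1).div(lengths, axis=0) * 1e9


def collapse_replicates(fpkm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Average FPKM across replicates of each (condition, stage).

    Columns of the result are named ``<condition>_<stage>``; single samples
    pass through unchanged.
    """
    missing = [s for s in fpkm.columns if s not in design.index]
    if missing:
        raise ValueError(f"sample {missing[0]!r} has no design record")
    groups: dict[str, list[str]] = {}
    for s in fpkm.columns:
        key = f"{design.loc[s, 'condition']}_{design.loc[s, 'stage']}"
        groups.setdefault(key, []).append(s)
    out = pd.DataFrame(
        {key: fpkm[samples].mean(axis=1) for key, samples in groups.items()},
        index=fpkm.index,
    )
    return out


def filter_low_expression(
    fpkm: pd.DataFrame, fpkm_floor: float = 1.0, max_low_samples: int = 10
) -> tuple[pd.DataFrame, list[str]]:
    """Drop genes with FPKM below the floor in more than ``max_low_samples``
    columns (strict '>'). Returns (kept matrix, removed gene list)."""
    if fpkm_floor < 0 or max_low_samples < 0:
        raise ValueError("thresholds must be >= 0")
    n_low = (fpkm < fpkm_floor).sum(axis=1)
    removed = fpkm.index[n_low > max_low_samples]
    return fpkm.drop(index=removed), list(removed)


def remove_nonvarying(
    expr: pd.DataFrame, max_missing_frac: float = 0.5
) -> tuple[pd.DataFrame, list[str]]:
    """Drop zero-variance genes and genes missing in more than half the columns."""
    var = expr.var(axis=1, ddof=0)
    missing_frac = expr.isna().mean(axis=1)
    bad = expr.index[(var.fillna(0.0) == 0.0) | (missing_frac > max_missing_frac)]
    return expr.drop(index=bad), list(bad)


def classify_expression_levels(
    fpkm: pd.DataFrame, low_cut: float = 1.0, super_cut: float = 1000.0
) -> pd.DataFrame:
    """Tally genes per sample into bands [0, low), [low, super], (super, inf)."""
    low = (fpkm < low_cut).sum(axis=0)
    high = (fpkm > super_cut).sum(axis=0)
    mid = fpkm.shape[0] - low - high
    return pd.DataFrame({"low": low, "mid": mid, "super_high": high})
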