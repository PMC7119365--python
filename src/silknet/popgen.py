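"""Sliding-window nucleotide diversity and Fst from a two-population VCF,
compound-quantile selection-region calling, and gene overlap."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GenotypePanel:
    """Per-population biallelic SNP tallies.

    Arrays are parallel over sites: ``n_alleles`` counts non-missing alleles,
    ``alt_count`` alternate alleles, ``het_count`` heterozygous genotypes.
    """

    population: str
    samples: list[str]
    chrom: np.ndarray  # site chromosome (str)
    pos: np.ndarray  # 1-based position
    n_alleles: np.ndarray
    alt_count: np.ndarray
    het_count: np.ndarray
    chrom_lengths: dict[str, int]

    @property
    def n_sites(self) -> int:
        return self.pos.size


def read_vcf_panels(
    vcf_path: str, population_map: dict[str, str]
) -> tuple[GenotypePanel, GenotypePanel, dict]:
    """Split a VCF into two per-population panels.

    Multi-allelic and non-SNP records are dropped and counted.  Every sample
    in the map must exist in the VCF; VCF samples not in the map are ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = list(vcf.samples)
    missing = [s for s in population_map if s not in vcf_samples]
    if missing:
        raise ValueError(f"sample {missing[0]!r} in population map absent from VCF")
    pops = sorted(set(population_map.values()))
    if len(pops) != 2:
        raise ValueError(f"expected exactly 2 populations, got {pops}")
    pop_cols = {
        p: np.array([i for i, s in enumerate(vcf_samples) if population_map.get(s) == p])
        for p in pops
    }
    chrom_lengths: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig="):
            body = line.split("<", 1)[1].rstrip(">")
            fields = dict(kv.split("=", 1) for kv in body.split(",") if "=" in kv)
            if "ID" in fields and "length" in fields:
                chrom_lengths[fields["ID"]] = int(fields["length"])

    chroms, positions = [], []
    data = {p: {"n": [], "ac": [], "het": []} for p in pops}
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_dropped += 1
            continue
        gt = rec.gt_types  # 0=hom-ref, 1=het, 2=hom-alt, 3=missing (gts012)
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        for p in pops:
            sub = gt[pop_cols[p]]
            called = sub[sub != 3]
            data[p]["n"].append(2 * called.size)
            data[p]["ac"].append(int((called == 1).sum() + 2 * (called == 2).sum()))
            data[p]["het"].append(int((called == 1).sum()))
    chrom_arr = np.array(chroms, dtype=object)
    pos_arr = np.array(positions, dtype=np.int64)
    for c in set(chroms):
        chrom_lengths.setdefault(c, int(pos_arr[chrom_arr == c].max()))

    panels = []
    for p in pops:
        panels.append(
            GenotypePanel(
                population=p,
                samples=[s for s in vcf_samples if population_map.get(s) == p],
                chrom=chrom_arr,
                pos=pos_arr,
                n_alleles=np.array(data[p]["n"], dtype=np.int64),
                alt_count=np.array(data[p]["ac"], dtype=np.int64),
                het_count=np.array(data[p]["het"], dtype=np.int64),
                chrom_lengths=chrom_lengths,
            )
        )
    report = {"n_sites": int(pos_arr.size), "n_dropped_non_biallelic_snp": n_dropped}
    return panels[0], panels[1], report


def site_pi(panel: GenotypePanel) -> np.ndarray:
    """Per-site unbiased heterozygosity 2p(1-p) * n/(n-1); NaN where n < 2."""
    n = panel.n_alleles.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = panel.alt_count / n
        pi = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    pi[n < 2] = np.nan
    return pi


def _windows(chrom_len: int, window_size: int, step: int):
    start = 0
    while start < chrom_len:
        yield start, min(start + window_size, chrom_len)
        start += step


def window_pi(
    panel: GenotypePanel, window_size: int, step: int
) -> pd.DataFrame:
    """Per-window pi = sum of site pi over contained SNPs / window_size."""
    if not window_size >= step >= 1:
        raise ValueError("require window_size >= step >= 1")
    pi = site_pi(panel)
    rows = []
    for chrom in panel.chrom_lengths:
        on = panel.chrom == chrom
        pos0 = panel.pos[on] - 1  # to 0-based
        vals = pi[on]
        ok = ~np.isnan(vals)
        for start, end in _windows(panel.chrom_lengths[chrom], window_size, step):
            inw = ok & (pos0 >= start) & (pos0 < start + window_size)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": int(inw.sum()),
                    "pi": float(vals[inw].sum()) / window_size,
                }
            )
    return pd.DataFrame(rows)


def wc_fst_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham per-site variance components (a, b + c) for two
    populations; inputs are individual counts, alt frequencies, and
    heterozygote proportions."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, a + b + c


def hudson_fst_components(
    n1: np.ndarray, p1: np.ndarray, n2: np.ndarray, p2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hudson estimator per-site numerator/denominator (allele counts n)."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1.0) - p2 * (1 - p2) / (n2 - 1.0)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def window_fst(
    panel_1: GenotypePanel,
    panel_2: GenotypePanel,
    window_size: int,
    step: int,
    estimator: str = "weir_cockerham",
) -> pd.DataFrame:
    """Per-window Fst as a ratio of per-site component sums.

    Windows without any usable SNP get NaN.  Values are reported as computed
    (negative estimates are not clamped).
    """
    if not window_size >= step >= 1:
        raise ValueError("require window_size >= step >= 1")
    if panel_1.n_sites != panel_2.n_sites or not np.array_equal(panel_1.pos, panel_2.pos):
        # intersect on (chrom, pos)
        key1 = list(zip(panel_1.chrom, panel_1.pos))
        key2 = list(zip(panel_2.chrom, panel_2.pos))
        common = set(key1) & set(key2)
        idx1 = np.array([i for i, k in enumerate(key1) if k in common])
        idx2 = np.array([i for i, k in enumerate(key2) if k in common])
    else:
        idx1 = idx2 = np.arange(panel_1.n_sites)

    usable = (panel_1.n_alleles[idx1] >= 2) & (panel_2.n_alleles[idx2] >= 2)
    idx1, idx2 = idx1[usable], idx2[usable]
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = panel_1.alt_count[idx1] / panel_1.n_alleles[idx1]
        p2 = panel_2.alt_count[idx2] / panel_2.n_alleles[idx2]
    if estimator == "weir_cockerham":
        n1 = panel_1.n_alleles[idx1] / 2.0
        n2 = panel_2.n_alleles[idx2] / 2.0
        h1 = panel_1.het_count[idx1] / n1
        h2 = panel_2.het_count[idx2] / n2
        num, den = wc_fst_components(n1, p1, h1, n2, p2, h2)
    elif estimator == "hudson":
        num, den = hudson_fst_components(
            panel_1.n_alleles[idx1].astype(float), p1,
            panel_2.n_alleles[idx2].astype(float), p2,
        )
    else:
        raise ValueError(f"unknown Fst estimator {estimator!r}")

    chrom = panel_1.chrom[idx1]
    pos0 = panel_1.pos[idx1] - 1
    rows = []
    for c in panel_1.chrom_lengths:
        on = chrom == c
        for start, end in _windows(panel_1.chrom_lengths[c], window_size, step):
            inw = on & (pos0 >= start) & (pos0 < start + window_size)
            d = float(den[inw].sum())
            fst = float(num[inw].sum()) / d if inw.sum() > 0 and d != 0 else np.nan
            rows.append(
                {"chrom": c, "start": start, "end": end, "n_snps": int(inw.sum()), "fst": fst}
            )
    return pd.DataFrame(rows)


def window_stats(
    panel_d: GenotypePanel,
    panel_w: GenotypePanel,
    window_size: int = 50_000,
    step: int = 25_000,
    estimator: str = "weir_cockerham",
) -> pd.DataFrame:
    """Combined per-window table: n_snps, pi_d, pi_w, ratio, diff, fst."""
    pi_d = window_pi(panel_d, window_size, step)
    pi_w = window_pi(panel_w, window_size, step)
    fst = window_fst(panel_d, panel_w, window_size, step, estimator)
    out = pi_d.rename(columns={"pi": "pi_d"})
    out["pi_w"] = pi_w["pi"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pi_ratio"] = np.where(out["pi_w"] > 0, out["pi_d"] / out["pi_w"], np.nan)
    out["pi_diff"] = out["pi_d"] - out["pi_w"]
    out["fst"] = fst["fst"]
    out["n_snps"] = np.maximum(out["n_snps"], fst["n_snps"])
    return out


def call_selection_regions(
    stats: pd.DataFrame,
    pi_stat: str = "ratio",
    lower_q: float = 0.05,
    upper_q: float = 0.95,
) -> tuple[pd.DataFrame, dict]:
    """Outlier windows: chosen pi statistic below its lower empirical quantile
    AND Fst above its upper quantile (both strict); overlapping or adjacent
    outlier windows are merged into regions."""
    col = {"ratio": "pi_ratio", "diff": "pi_diff"}.get(pi_stat)
    if col is None:
        raise ValueError("pi_stat must be 'ratio' or 'diff'")
    defined = stats.dropna(subset=[col, "fst"])
    if len(defined) == 0:
        raise ValueError("all windows undefined")
    if len(defined) < 20:
        raise ValueError(f"only {len(defined)} defined windows; quantiles meaningless")
    lo = float(np.quantile(defined[col], lower_q))
    hi = float(np.quantile(defined["fst"], upper_q))
    outliers = defined[(defined[col] < lo) & (defined["fst"] > hi)]
    regions = merge_intervals(outliers)
    thresholds = {"pi_threshold": lo, "fst_threshold": hi, "n_outlier_windows": len(outliers)}
    return regions, thresholds


def merge_intervals(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or abutting (chrom, start, end) intervals."""
    rows = []
    for chrom, sub in windows.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for rec in sub.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = rec.start, rec.end
            elif rec.start <= cur_e:
                cur_e = max(cur_e, rec.end)
            else:
                rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e)})
                cur_s, cur_e = rec.start, rec.end
        if cur_s is not None:
            rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def overlap_genes(regions: pd.DataFrame, gene_models: pd.DataFrame) -> set[str]:
    """Genes whose 0-based half-open interval intersects any region by >= 1 bp."""
    selected = set()
    for g in gene_models.itertuples(index=False):
        for r in regions.itertuples(index=False):
            if g.chrom == r.chrom and g.start < r.end and r.start < g.end:
                selected.add(g.gene)
                break
    return selected
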