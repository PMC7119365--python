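"""Readers and writers for the plain-text interchange formats.

All tables are tab-separated. Genomic intervals are 0-based half-open;
VCF positions are 1-based (converted on read).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_SHEET_COLUMNS = ("sample", "condition", "stage", "replicate")


class FormatError(ValueError):
    """A malformed input file (message names the file and offending record)."""


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples integer count matrix.

    First column = gene id, header row = sample ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise FormatError(f"{path}: non-numeric count at gene {bad!r}, sample {col!r}")
        if (vals < 0).any():
            bad = df.index[vals < 0][0]
            raise FormatError(f"{path}: negative count at gene {bad!r}, sample {col!r}")
        if not np.allclose(vals, np.round(vals)):
            bad = df.index[~np.isclose(vals, np.round(vals))][0]
            raise FormatError(f"{path}: non-integer count at gene {bad!r}, sample {col!r}")
    return df.astype(np.int64)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample design sheet (sample, condition, stage, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in REQUIRED_SHEET_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: sample sheet lacks required column {col!r}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    return df.set_index("sample", drop=False)


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read gene models (gene, chrom, start, end); 0-based half-open.

    Adds a ``length`` column (end - start).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"{path}: gene model table lacks column {col!r}")
    df = df.copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] <= df["start"]).any():
        bad = df.loc[df["end"] <= df["start"], "gene"].iloc[0]
        raise FormatError(f"{path}: non-positive length for gene {bad!r}")
    df["length"] = df["end"] - df["start"]
    return df.set_index("gene", drop=False)


def write_gene_models(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene", "chrom", "start", "end"]
    df[cols].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (gene, term) annotation into gene -> set of terms."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene"):
            raise FormatError(f"{path}: annotation must start with a 'gene\\tterm' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected 'gene\\tterm'")
            ann.setdefault(parts[0], set()).add(parts[1])
    return ann


def write_annotation(ann: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(ann):
            for term in sorted(ann[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, population) map."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "sample" not in df.columns or "population" not in df.columns:
        raise FormatError(f"{path}: population map needs 'sample' and 'population' columns")
    return dict(zip(df["sample"], df["population"]))


def write_population_map(popmap: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def write_vcf(
    path: str | Path,
    sites: pd.DataFrame,
    genotypes: np.ndarray,
    sample_names: list[str],
    chrom_lengths: dict[str, int],
) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype fields.

    ``genotypes`` is an (n_sites, n_samples) int array of alt-allele dosages
    (0, 1, 2) with -1 for missing.
    """
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        for i, row in enumerate(sites.itertuples(index=False)):
            gts = "\t".join(gt_strings[int(g)] for g in genotypes[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
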