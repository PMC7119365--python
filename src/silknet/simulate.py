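"""Seeded synthetic inputs with planted ground truth.

Expression: a per-module latent stage trajectory drives correlated genes;
gene mean = base_mean * 2**(amplitude * u + DE shift) and counts are negative
binomial (deterministic rounding at dispersion 0).  Differential co-expression
is planted by giving a gene pair an extra shared latent factor in one
condition only.  Genotypes: independent biallelic sites with Beta-distributed
frequencies; a sweep compresses population-1 frequencies toward fixation and
optionally boosts between-population divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .popgen import GenotypePanel

STAGES = ("0p", "1p", "2p", "3p", "4p", "5p", "w")
CONDITIONS = ("domestic", "wild")
REPLICATED_STAGES = ("0p", "1p", "2p", "3p", "5p")


def default_design() -> list[tuple[str, str, int]]:
    """Two conditions x 7 stages; duplicated except at 4p and w."""
    design = []
    for cond in CONDITIONS:
        for stage in STAGES:
            design.append((cond, stage, 2 if stage in REPLICATED_STAGES else 1))
    return design


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticTruth:
    """Planted ground truth for acceptance checks."""

    module_labels: dict[str, str] = field(default_factory=dict)
    planted_diff_edges: list[dict] = field(default_factory=list)
    planted_de: list[dict] = field(default_factory=list)
    sweep_intervals: list[dict] = field(default_factory=list)
    selected_genes: list[str] = field(default_factory=list)
    planted_terms: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "module_labels": self.module_labels,
            "planted_diff_edges": self.planted_diff_edges,
            "planted_de": self.planted_de,
            "sweep_intervals": self.sweep_intervals,
            "selected_genes": sorted(self.selected_genes),
            "planted_terms": {t: sorted(g) for t, g in self.planted_terms.items()},
        }


@dataclass
class ExpressionSimConfig:
    n_genes: int = 400
    module_sizes: tuple[int, ...] = (50, 50, 50)
    within_module_cor: float = 0.9
    seed_gene_placement: dict[str, int] = field(default_factory=dict)
    module_conditions: tuple[str | None, ...] | None = None  # None entry = both
    diff_edge_spec: list[tuple[str, str, str, float]] = field(default_factory=list)
    de_gene_spec: list[tuple[str, tuple[str, ...], float]] = field(default_factory=list)
    dispersion: float = 0.05
    amplitude: float = 2.0
    base_mean_range: tuple[float, float] = (50.0, 500.0)
    library_size_range: tuple[int, int] = (1_000_000, 1_200_000)
    design: list[tuple[str, str, int]] = field(default_factory=default_design)
    rng_seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError("module sizes sum exceeds n_genes")
        if not 0.0 <= self.within_module_cor <= 1.0:
            raise ConfigError("within_module_cor must lie in [0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.module_conditions is not None and len(self.module_conditions) != len(
            self.module_sizes
        ):
            raise ConfigError("module_conditions must match module_sizes")
        if len(self.module_sizes) >= len(STAGES):
            raise ConfigError(
                "at most 6 modules: stage trajectories are orthogonalized over 7 stages"
            )
        for name, m in self.seed_gene_placement.items():
            if not 0 <= m < len(self.module_sizes):
                raise ConfigError(f"seed gene {name!r} placed in unknown module {m}")
        for g1, g2, cond, coupling in self.diff_edge_spec:
            if cond not in CONDITIONS:
                raise ConfigError(f"unknown condition {cond!r} in diff_edge_spec")
            if not 0.0 < coupling <= 1.0:
                raise ConfigError("diff-edge coupling must lie in (0, 1]")


@dataclass
class ExpressionDataset:
    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    gene_lengths: pd.Series
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_counts(self.counts, outdir / "counts.tsv")
        io.write_sample_sheet(self.sample_sheet, outdir / "samples.tsv")
        io.write_json(self.truth.to_dict(), outdir / "truth_expression.json")


def _gene_ids(config: ExpressionSimConfig) -> tuple[list[str], dict[str, int | None]]:
    width = max(4, len(str(config.n_genes)))
    ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    module_of: dict[str, int | None] = {}
    pos = 0
    for m, size in enumerate(config.module_sizes):
        for g in ids[pos : pos + size]:
            module_of[g] = m
        pos += size
    for g in ids[pos:]:
        module_of[g] = None
    # seed genes replace the leading generic members of their module
    replaced: dict[int, int] = {}
    for name in sorted(config.seed_gene_placement):
        m = config.seed_gene_placement[name]
        offset = sum(config.module_sizes[:m]) + replaced.get(m, 0)
        if replaced.get(m, 0) >= config.module_sizes[m]:
            raise ConfigError(f"module {m} too small for its seed genes")
        old = ids[offset]
        ids[offset] = name
        module_of[name] = module_of.pop(old)
        replaced[m] = replaced.get(m, 0) + 1
    return ids, module_of


def generate_expression_dataset(config: ExpressionSimConfig) -> ExpressionDataset:
    """Simulate a count matrix with planted modules, DE genes, and
    condition-specific co-expression edges."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    genes, module_of = _gene_ids(config)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = config.n_genes
    n_modules = len(config.module_sizes)
    n_stages = len(STAGES)
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    cond_idx = {c: i for i, c in enumerate(CONDITIONS)}

    # per-gene incident diff edges; total variance budget must not exceed 1
    edges_of: dict[str, list[tuple[int, str, float]]] = {}
    for e, (g1, g2, cond, coupling) in enumerate(config.diff_edge_spec):
        for g in (g1, g2):
            if g not in gene_idx:
                raise ConfigError(f"diff-edge gene {g!r} does not exist")
            edges_of.setdefault(g, []).append((e, cond, coupling))
    for g, incident in edges_of.items():
        base = config.within_module_cor if module_of[g] is not None else 0.0
        for cond in CONDITIONS:
            total = base + sum(c for _, fav, c in incident if fav == cond)
            if total > 1.0 + 1e-12:
                raise ConfigError(
                    f"gene {g!r}: module correlation + couplings exceed 1 in {cond}"
                )
    for gene, stages, _ in config.de_gene_spec:
        if gene not in gene_idx:
            raise ConfigError(f"DE gene {gene!r} does not exist")
        for st in stages:
            if st not in stage_idx:
                raise ConfigError(f"unknown stage {st!r} in de_gene_spec")

    # fixed draw order => determinism
    log_lo, log_hi = np.log(config.base_mean_range[0]), np.log(config.base_mean_range[1])
    base_mean = np.exp(rng.uniform(log_lo, log_hi, n_genes))
    # module trajectories are centered and orthonormalized across stages so
    # the planted correlation structure is realized even with only 7 stages
    raw = rng.standard_normal((n_stages, max(n_modules, 1)))
    raw = raw - raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    z_module = (q * np.sqrt(n_stages)).T[:n_modules]
    w_pair = rng.standard_normal((len(config.diff_edge_spec), n_stages))
    if w_pair.size:
        w_pair = w_pair - w_pair.mean(axis=1, keepdims=True)
        w_pair = w_pair / w_pair.std(axis=1, keepdims=True)
    # gene stage trajectories are conserved across conditions: planted edges
    # and DE shifts are the only condition-specific structure
    eps = rng.standard_normal((n_genes, n_stages))

    de_shift = np.zeros((n_genes, n_stages))
    for gene, stages, lfc in config.de_gene_spec:
        for st in stages:
            de_shift[gene_idx[gene], stage_idx[st]] = lfc

    # latent signal u[g, c, t] with unit variance budget
    u = np.zeros((n_genes, len(CONDITIONS), n_stages))
    for g in genes:
        gi = gene_idx[g]
        m = module_of[g]
        for c, cond in enumerate(CONDITIONS):
            var_mod = 0.0
            if m is not None:
                active = (
                    config.module_conditions is None
                    or config.module_conditions[m] is None
                    or config.module_conditions[m] == cond
                )
                if active:
                    var_mod = config.within_module_cor
            var_pair = 0.0
            pair_term = np.zeros(n_stages)
            for e, fav, coupling in edges_of.get(g, []):
                if fav == cond:
                    var_pair += coupling
                    pair_term = pair_term + np.sqrt(coupling) * w_pair[e]
            var_noise = max(0.0, 1.0 - var_mod - var_pair)
            sig = np.sqrt(var_mod) * z_module[m] if var_mod > 0 else 0.0
            u[gi, c] = sig + pair_term + np.sqrt(var_noise) * eps[gi]

    samples = []
    for cond, stage, n_rep in config.design:
        prefix = "D" if cond == "domestic" else "W"
        for r in range(1, n_rep + 1):
            samples.append(
                {"sample": f"{prefix}_{stage}_{r}", "condition": cond,
                 "stage": stage, "replicate": r}
            )
    sheet = pd.DataFrame(samples)

    lib = rng.integers(
        config.library_size_range[0], config.library_size_range[1] + 1, len(samples)
    ).astype(float)
    mean_lib = lib.mean()

    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for j, rec in enumerate(samples):
        c = cond_idx[rec["condition"]]
        t = stage_idx[rec["stage"]]
        shift = de_shift[:, t] if rec["condition"] == "domestic" else 0.0
        mu = base_mean * 2.0 ** (config.amplitude * u[:, c, t] + shift)
        mu = mu * (lib[j] / mean_lib)
        if config.dispersion == 0.0:
            counts[:, j] = np.rint(mu).astype(np.int64)
        else:
            n_nb = 1.0 / config.dispersion
            p_nb = n_nb / (n_nb + mu)
            counts[:, j] = rng.negative_binomial(n_nb, p_nb)

    counts_df = pd.DataFrame(counts, index=genes, columns=sheet["sample"].tolist())
    gene_lengths = pd.Series(
        rng.integers(500, 5001, n_genes), index=genes, name="length"
    )

    truth = SyntheticTruth(
        module_labels={
            g: (f"M{m + 1}" if m is not None else "unassigned")
            for g, m in module_of.items()
        },
        planted_diff_edges=[
            {"gene1": min(g1, g2), "gene2": max(g1, g2), "favored": cond}
            for g1, g2, cond, _ in config.diff_edge_spec
        ],
        planted_de=[
            {"gene": gene, "stage": st, "sign": 1 if lfc > 0 else -1}
            for gene, stages, lfc in config.de_gene_spec
            for st in stages
        ],
    )
    return ExpressionDataset(counts_df, sheet, gene_lengths, truth)


@dataclass
class GenotypeSimConfig:
    n_pop1: int = 10
    n_pop2: int = 8
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    snp_density: float = 0.005
    sweep_intervals: list[tuple[int, int, float, float]] = field(default_factory=list)
    beta_params: tuple[float, float] = (0.8, 0.8)
    freq_clip: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        ivs = sorted(self.sweep_intervals)
        prev_end = -1
        for start, end, factor, boost in ivs:
            if not 0 <= start < end <= self.chrom_length:
                raise ConfigError(f"sweep interval ({start}, {end}) out of range")
            if start < prev_end:
                raise ConfigError("overlapping sweep intervals")
            if factor < 1.0:
                raise ConfigError("diversity_reduction_factor must be >= 1")
            if not 0.0 <= boost <= 1.0:
                raise ConfigError("differentiation_boost must lie in [0, 1]")
            prev_end = end


@dataclass
class GenotypeDataset:
    sites: pd.DataFrame  # chrom, pos (1-based), ref, alt
    genotypes: np.ndarray  # (n_sites, n_samples) dosage, -1 missing
    sample_names: list[str]
    popmap: dict[str, str]
    chrom_lengths: dict[str, int]
    truth: SyntheticTruth

    def panels(self) -> tuple[GenotypePanel, GenotypePanel]:
        pops = sorted(set(self.popmap.values()))
        out = []
        chrom = self.sites["chrom"].to_numpy(dtype=object)
        pos = self.sites["pos"].to_numpy(dtype=np.int64)
        for p in pops:
            cols = [i for i, s in enumerate(self.sample_names) if self.popmap[s] == p]
            sub = self.genotypes[:, cols]
            called = sub >= 0
            out.append(
                GenotypePanel(
                    population=p,
                    samples=[self.sample_names[i] for i in cols],
                    chrom=chrom,
                    pos=pos,
                    n_alleles=2 * called.sum(axis=1),
                    alt_count=np.where(called, sub, 0).sum(axis=1),
                    het_count=(sub == 1).sum(axis=1),
                    chrom_lengths=self.chrom_lengths,
                )
            )
        return out[0], out[1]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_vcf(
            outdir / "variants.vcf", self.sites, self.genotypes,
            self.sample_names, self.chrom_lengths,
        )
        io.write_population_map(self.popmap, outdir / "populations.tsv")
        io.write_json(self.truth.to_dict(), outdir / "truth_genotypes.json")


def generate_genotype_panels(config: GenotypeSimConfig) -> GenotypeDataset:
    """Simulate two diploid population panels with planted sweeps.

    Population 1 is the 'domestic' (sweep-bearing) panel.  Sites are
    independent; inside a sweep, pop-1 frequencies are pulled toward fixation
    by the diversity-reduction factor and pushed further by the boost.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n_snps = int(round(config.chrom_length * config.snp_density))
    if n_snps < 1:
        raise ConfigError("snp_density too low: no sites")
    pos = np.sort(rng.choice(config.chrom_length, size=n_snps, replace=False)) + 1
    p_anc = np.clip(
        rng.beta(*config.beta_params, n_snps), config.freq_clip[0], config.freq_clip[1]
    )
    p1 = p_anc.copy()
    p2 = p_anc.copy()
    target = np.where(p_anc >= 0.5, 1.0, 0.0)
    for start, end, factor, boost in config.sweep_intervals:
        mask = (pos - 1 >= start) & (pos - 1 < end)
        p1[mask] = target[mask] + (p1[mask] - target[mask]) / factor
        p1[mask] = (1.0 - boost) * p1[mask] + boost * target[mask]

    g1 = rng.binomial(2, p1[:, None], (n_snps, config.n_pop1))
    g2 = rng.binomial(2, p2[:, None], (n_snps, config.n_pop2))
    geno = np.concatenate([g1, g2], axis=1).astype(np.int8)
    if config.missing_rate > 0:
        drop = rng.random(geno.shape) < config.missing_rate
        geno[drop] = -1

    names = [f"D{i + 1:02d}" for i in range(config.n_pop1)] + [
        f"W{i + 1:02d}" for i in range(config.n_pop2)
    ]
    popmap = {s: ("domestic" if s.startswith("D") else "wild") for s in names}
    sites = pd.DataFrame(
        {"chrom": config.chrom, "pos": pos, "ref": "A", "alt": "T"}
    )
    truth = SyntheticTruth(
        sweep_intervals=[
            {"chrom": config.chrom, "start": int(s), "end": int(e),
             "factor": f, "boost": b}
            for s, e, f, b in config.sweep_intervals
        ]
    )
    return GenotypeDataset(
        sites=sites,
        genotypes=geno,
        sample_names=names,
        popmap=popmap,
        chrom_lengths={config.chrom: config.chrom_length},
        truth=truth,
    )


def generate_annotation(
    genes: list[str],
    n_terms: int,
    planted_term_spec: dict[str, list[str]] | None = None,
    seed: int = 0,
    mean_terms_per_gene: float = 2.0,
    gene_lengths: pd.Series | None = None,
    chrom: str = "chr1",
    chrom_length: int | None = None,
) -> tuple[dict[str, set[str]], pd.DataFrame, SyntheticTruth]:
    """Random gene->term annotation plus non-overlapping gene coordinates.

    Planted terms annotate exactly their designated gene sets (background
    assignment never reuses a planted term), so they are maximally
    over-represented in those sets.
    """
    if n_terms < 1:
        raise ConfigError("need at least one term")
    planted = planted_term_spec or {}
    for term, members in planted.items():
        for g in members:
            if g not in genes:
                raise ConfigError(f"planted gene {g!r} for term {term!r} does not exist")
    rng = np.random.default_rng(seed)
    n = len(genes)
    width = max(2, len(str(n_terms)))
    background_terms = [
        t for t in (f"T{i + 1:0{width}d}" for i in range(n_terms)) if t not in planted
    ]

    if gene_lengths is None:
        lengths = rng.integers(500, 5001, n)
    else:
        lengths = gene_lengths.reindex(genes).to_numpy(np.int64)
    if chrom_length is None:
        chrom_length = int(lengths.sum() * 2 + n * 100)
    slot = chrom_length // n
    starts = np.arange(n) * slot
    ends = starts + np.minimum(lengths, slot - 1 if slot > 1 else 1)
    ends = np.maximum(ends, starts + 1)
    models = pd.DataFrame(
        {"gene": genes, "chrom": chrom, "start": starts, "end": ends}
    )
    models["length"] = models["end"] - models["start"]
    models = models.set_index("gene", drop=False)

    ann: dict[str, set[str]] = {g: set() for g in genes}
    for g in genes:
        k = min(int(rng.poisson(mean_terms_per_gene)), len(background_terms))
        if k > 0:
            picked = rng.choice(len(background_terms), size=k, replace=False)
            ann[g].update(background_terms[i] for i in picked)
    for term, members in planted.items():
        for g in members:
            ann[g].add(term)

    truth = SyntheticTruth(planted_terms={t: list(m) for t, m in planted.items()})
    return ann, models, truth


# ---------------------------------------------------------------------------
# packaged study fixture: one coherent synthetic study exercising every stage


def default_study_config(seed: int = 1) -> dict:
    """A full synthetic study: seed genes in two planted modules,
    condition-specific edges to DE partners, a planted sweep overlapping some
    partners, and stage-persistent annotation terms."""
    fib = ["Fib-H", "Fib-L", "P25"]
    ser = ["Sericin1", "Sericin2", "Sericin3"]
    n_genes = 300
    module_sizes = (40, 40, 40)
    width = max(4, len(str(n_genes)))
    gid = lambda i: f"G{i + 1:0{width}d}"  # noqa: E731

    # module 0 occupies indices 0..39 (first 3 replaced by fibroin seeds),
    # module 1 indices 40..79 (first 3 replaced by sericin seeds); the planted
    # sweep [0, 150 kb) covers the leading module-0 genes incl. dom_partners
    dom_partners = [gid(i) for i in (3, 4, 5)]  # module 0, domestic-favored
    ser_dom_partner = gid(46)                   # module 1, domestic-favored
    wild_partners = [gid(47), gid(48)]          # module 1, wild-favored
    diff_edges = [
        ("Fib-H", dom_partners[0], "domestic", 0.15),
        ("Fib-L", dom_partners[1], "domestic", 0.15),
        ("P25", dom_partners[2], "domestic", 0.15),
        ("Sericin3", ser_dom_partner, "domestic", 0.15),
        ("Sericin1", wild_partners[0], "wild", 0.15),
        ("Sericin2", wild_partners[1], "wild", 0.15),
    ]

    all_stages = tuple(STAGES)
    up_genes = [gid(i) for i in range(120, 135)]
    down_genes = [gid(i) for i in range(135, 145)]
    de_spec = [(g, all_stages, 2.0) for g in up_genes]
    de_spec += [(g, all_stages, -2.0) for g in down_genes]
    # partner genes must themselves be DEGs to enter the seed networks
    de_spec += [(g, all_stages, 2.0) for g in dom_partners + [ser_dom_partner]]
    de_spec += [(g, all_stages, -2.0) for g in wild_partners]

    return {
        "expression": ExpressionSimConfig(
            n_genes=n_genes,
            module_sizes=module_sizes,
            within_module_cor=0.85,
            seed_gene_placement={**{g: 0 for g in fib}, **{g: 1 for g in ser}},
            diff_edge_spec=diff_edges,
            de_gene_spec=de_spec,
            dispersion=0.05,
            base_mean_range=(200.0, 2000.0),
            rng_seed=seed,
        ),
        "genotypes": GenotypeSimConfig(
            chrom_length=2_000_000,
            snp_density=0.005,
            sweep_intervals=[(0, 150_000, 10.0, 0.5)],
            rng_seed=seed + 1,
        ),
        "annotation": {
            "n_terms": 30,
            "seed": seed + 2,
            "planted_term_spec": {
                "T_UPSET": up_genes,
                "T_DOWNSET": down_genes,
            },
        },
        "seed_genes": fib + ser,
    }


def generate_study(outdir, seed: int = 1, config: dict | None = None) -> dict:
    """Write a complete synthetic study (all pipeline inputs + truth) to
    ``outdir`` and return the file manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or default_study_config(seed)

    expr_ds = generate_expression_dataset(cfg["expression"])
    expr_ds.write(outdir)

    geno_ds = generate_genotype_panels(cfg["genotypes"])
    geno_ds.write(outdir)

    ann_cfg = cfg["annotation"]
    genes = list(expr_ds.counts.index)
    annotation, models, ann_truth = generate_annotation(
        genes,
        n_terms=ann_cfg["n_terms"],
        planted_term_spec=ann_cfg.get("planted_term_spec"),
        seed=ann_cfg.get("seed", seed),
        gene_lengths=expr_ds.gene_lengths,
        chrom=cfg["genotypes"].chrom,
        chrom_length=cfg["genotypes"].chrom_length,
    )
    io.write_annotation(annotation, outdir / "annotation.tsv")
    io.write_gene_models(models, outdir / "gene_models.tsv")
    with open(outdir / "seed_genes.txt", "w") as fh:
        fh.write("\n".join(cfg["seed_genes"]) + "\n")

    # genes overlapping the planted sweep(s) are the planted selection set
    sweep_df = pd.DataFrame(geno_ds.truth.sweep_intervals)
    selected: list[str] = []
    if len(sweep_df):
        from .popgen import overlap_genes

        selected = sorted(overlap_genes(sweep_df, models))
    truth = SyntheticTruth(
        module_labels=expr_ds.truth.module_labels,
        planted_diff_edges=expr_ds.truth.planted_diff_edges,
        planted_de=expr_ds.truth.planted_de,
        sweep_intervals=geno_ds.truth.sweep_intervals,
        selected_genes=selected,
        planted_terms=ann_truth.planted_terms,
    )
    io.write_json(truth.to_dict(), outdir / "truth.json")

    manifest = {
        "counts": str(outdir / "counts.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "gene_models": str(outdir / "gene_models.tsv"),
        "annotation": str(outdir / "annotation.tsv"),
        "seed_genes": str(outdir / "seed_genes.txt"),
        "vcf": str(outdir / "variants.vcf"),
        "popmap": str(outdir / "populations.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    return manifest
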