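"""Synthetic MSRE-seq cohort generator.

Emulates the statistical structure of a two-cohort (spastic CP vs
control) myogenic-cell methylation study: 6 samples per group, two
paired cell conditions (proliferating myoblasts, MB, and
differentiating myotubes, MT), per-site methylation probabilities with
planted group effects, chromosomal concentration of effects, megabase
hyper/hypo blocks, and promoter-window shifts. Coverage follows the
MSRE-seq assay logic: HpaII cuts unmethylated CCGG, so the expected
intact-fragment depth at a site scales with its methylation
probability.

Every draw flows from a single integer seed through
``numpy.random.Generator`` streams; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import SiteCatalog, format_site_id

GROUPS = ("control", "CP")
CONDITIONS = ("MB", "MT")

GENE_CLASSES = ("protein_coding", "lincRNA", "miRNA", "snRNA", "pseudogene")


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study design: 6 subjects per cohort,
    CCGG density ~0.75 per kbp (the genome-wide HpaII-target density),
    and a negative-binomial coverage model whose depth and dispersion
    imply a per-site replicate SD of ~0.2 log2 score units — the noise
    level at which |logFC| ~ 0.7-1 group effects are FDR-detectable in
    a 6 vs 6 cohort over a million-site universe, as the emulated
    study's significant-site tables require.
    """

    n_per_group: int = 6
    chrom_spec: Sequence[tuple[str, int]] = (
        ("chr1", 6_000_000),
        ("chr2", 6_000_000),
        ("chr3", 6_000_000),
        ("chr4", 6_000_000),
        ("chr5", 6_000_000),
    )
    site_density: float = 0.75  # expected CCGG sites per kbp
    baseline_beta: tuple[float, float] = (2.0, 2.0)
    frac_dm: float = 0.02
    delta: float = 1.5  # log-odds shift at DM sites in the CP group
    dm_sign_prob: float = 0.5  # probability a DM site is hypermethylated
    enriched_chroms: frozenset[str] = frozenset()
    enriched_multiple: float = 4.0
    block_spec: Sequence[tuple[str, int, int, float]] = ()  # (chrom, start, end, logit effect)
    promoter_spec: Sequence[tuple[str, int, float]] = ()  # (chrom, tss_pos, logit effect)
    promoter_halfwidth: int = 1000
    depth_mean: float = 300.0  # expected intact-fragment depth at theta = 1
    nb_dispersion: float = 0.005
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    n_genes: int = 120
    n_enhancers: int = 40
    muscle_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.frac_dm < 1:
            raise ValueError(f"frac_dm must be in (0, 1), got {self.frac_dm}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lengths = dict(self.chrom_spec)
        for chrom, start, end, _ in self.block_spec:
            if chrom not in lengths or not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"block [{start}, {end}) outside {chrom}")
        for chrom, tss, _ in self.promoter_spec:
            if chrom not in lengths or not (1 <= tss <= lengths[chrom]):
                raise ValueError(f"planted TSS {tss} outside {chrom}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def synthetic_catalog(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> SiteCatalog:
    """Sample CCGG site positions directly at the configured density.

    Positions are uniform per chromosome (count ~ Binomial at
    ``site_density`` per kbp), sorted and deduplicated — the spatial
    null against which planted regional structure stands out.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    frames = []
    for chrom, length in config.chrom_spec:
        n = rng.binomial(length, min(1.0, config.site_density / 1000.0))
        pos = np.unique(rng.integers(1, length - 3, size=n, endpoint=True))
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "site_id": [format_site_id(chrom, int(p)) for p in pos],
        }))
    sites = pd.concat(frames, ignore_index=True)
    return SiteCatalog(sites=sites, chrom_lengths=dict(config.chrom_spec))


@dataclass
class TruthTable:
    """Ground truth for recovery tests: per-site methylation
    probabilities per group plus the planted regional effects."""

    sites: pd.DataFrame  # site_id, chrom, pos, theta_control, theta_cp, dm_flag, planted_logfc
    blocks: pd.DataFrame  # chrom, start, end, effect
    promoters: pd.DataFrame  # chrom, tss_pos, effect

    def __post_init__(self) -> None:
        th = self.sites[["theta_control", "theta_cp"]].to_numpy()
        if not ((th > 0) & (th < 1)).all():
            raise ValueError("theta must lie strictly in (0, 1)")
        flags = self.sites["dm_flag"].to_numpy()
        differ = self.sites["theta_cp"].to_numpy() != self.sites["theta_control"].to_numpy()
        if not (flags == differ).all():
            raise ValueError("dm_flag inconsistent with theta columns")


def simulate_truth(config: SimulationConfig, catalog: SiteCatalog,
                   rng: np.random.Generator | None = None) -> TruthTable:
    """Draw per-site baseline methylation and plant all configured effects.

    Baseline theta_i ~ Beta(a, b). An exact-count subset of
    floor(frac_dm * n) sites receives a +/- ``delta`` shift on the
    log-odds in the CP group, with DM sites over-allocated to
    ``enriched_chroms`` by weighted sampling without replacement at
    weight ``enriched_multiple``. Block and promoter effects are added
    on the logit scale to every member site.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sites = catalog.sites.reset_index(drop=True)
    n = len(sites)
    if n == 0:
        raise ValueError("catalog is empty")
    a, b = config.baseline_beta
    theta = rng.beta(a, b, size=n)
    # keep strictly interior so logit shifts stay finite
    theta = np.clip(theta, 1e-6, 1 - 1e-6)

    n_dm = int(np.floor(config.frac_dm * n))
    if n_dm < 1:
        raise ValueError("no DM sites plantable: frac_dm * n_sites < 1")
    weights = np.ones(n)
    on_enriched = sites["chrom"].isin(config.enriched_chroms).to_numpy()
    weights[on_enriched] = config.enriched_multiple
    dm_idx = rng.choice(n, size=n_dm, replace=False, p=weights / weights.sum())
    signs = np.where(rng.random(n_dm) < config.dm_sign_prob, 1.0, -1.0)

    shift = np.zeros(n)
    shift[dm_idx] += signs * config.delta

    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    for bchrom, start, end, effect in config.block_spec:
        member = (chrom == bchrom) & (pos - 1 >= start) & (pos - 1 < end)
        shift[member] += effect
    w = config.promoter_halfwidth
    for pchrom, tss, effect in config.promoter_spec:
        member = (chrom == pchrom) & (pos >= tss - w) & (pos <= tss + w)
        shift[member] += effect

    # apply the logit shift only where one is planted, so unaffected
    # sites keep theta_cp == theta_control bit-for-bit
    theta_cp = theta.copy()
    hit = shift != 0
    theta_cp[hit] = np.clip(_expit(_logit(theta[hit]) + shift[hit]),
                            1e-6, 1 - 1e-6)
    truth = sites[["site_id", "chrom", "pos"]].copy()
    truth["theta_control"] = theta
    truth["theta_cp"] = theta_cp
    truth["dm_flag"] = theta_cp != theta
    # the exact-count site-level subset, distinct from block/promoter members
    planted = np.zeros(n, dtype=bool)
    planted[dm_idx] = config.delta != 0
    truth["planted_dm"] = planted
    with np.errstate(divide="ignore"):
        truth["planted_logfc"] = np.log2(theta_cp / theta)
    blocks = pd.DataFrame(config.block_spec, columns=["chrom", "start", "end", "effect"])
    promoters = pd.DataFrame(config.promoter_spec, columns=["chrom", "tss_pos", "effect"])
    return TruthTable(sites=truth, blocks=blocks, promoters=promoters)


def make_design(n_per_group: int = 6, condition: str = "MB",
                subject_prefixes: tuple[str, str] = ("CN", "CP")) -> pd.DataFrame:
    """Cohort design table for one cell condition: sample_id, group, condition."""
    rows = []
    for prefix, group in zip(subject_prefixes, GROUPS):
        for i in range(1, n_per_group + 1):
            rows.append((f"{prefix}{i}_{condition}", group, condition))
    return pd.DataFrame(rows, columns=["sample_id", "group", "condition"])


def simulate_depth_matrix(truth: TruthTable, config: SimulationConfig,
                          design: pd.DataFrame,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Negative-binomial intact-fragment depths, sites x samples.

    depth_ij ~ NB(mean = s_j * depth_mean * theta_i(group(j)),
    dispersion phi), with per-sample size factors s_j log-uniform in
    ``size_factor_range``. Fully methylated sites resist digestion and
    reach ``depth_mean`` coverage on average; unmethylated sites are cut
    and yield none.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    unknown = set(design["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s) in design: {sorted(unknown)}")
    lo, hi = config.size_factor_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(design)))
    theta = {
        "control": truth.sites["theta_control"].to_numpy(),
        "CP": truth.sites["theta_cp"].to_numpy(),
    }
    phi = config.nb_dispersion
    nb_n = 1.0 / phi
    cols = {}
    for j, row in enumerate(design.itertuples(index=False)):
        mean = s[j] * config.depth_mean * theta[row.group]
        p = nb_n / (nb_n + mean)
        cols[row.sample_id] = rng.negative_binomial(nb_n, p)
    depths = pd.DataFrame(cols, index=truth.sites["site_id"].to_numpy())
    depths.index.name = "site_id"
    depths.attrs["size_factors"] = dict(zip(design["sample_id"], s))
    return depths


def emit_annotations(config: SimulationConfig, catalog: SiteCatalog,
                     rng: np.random.Generator | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Synthetic gene/TSS table, enhancer intervals, and muscle gene list.

    Gene models are pairwise non-overlapping (one gene per equal-width
    slot along each chromosome). Where a slot contains two catalogue
    sites close enough to fall in one promoter window, the TSS is
    placed midway between them, so a subset of promoters is guaranteed
    to survive the >=2-CpG inclusion rule. About a third of genes carry
    a second transcript (TSS shifted 500 bp) to exercise
    one-transcript-per-gene deduplication.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lengths = dict(config.chrom_spec)
    total = sum(lengths.values())
    site_pos = {c: g["pos"].to_numpy() for c, g in catalog.sites.groupby("chrom")}

    gene_rows = []
    gid = 0
    for chrom, length in config.chrom_spec:
        n_chrom = max(1, round(config.n_genes * length / total))
        slot = length // n_chrom
        for k in range(n_chrom):
            gid += 1
            lo = k * slot + 2 * config.promoter_halfwidth
            hi = (k + 1) * slot - 2 * config.promoter_halfwidth
            if hi <= lo:
                continue
            pos = site_pos.get(chrom, np.array([], dtype=int))
            inside = pos[(pos >= lo) & (pos <= hi)]
            gaps = np.diff(inside)
            close = np.flatnonzero(gaps <= config.promoter_halfwidth)
            if close.size:
                i = int(rng.choice(close))
                tss = int((inside[i] + inside[i + 1]) // 2)
            else:
                tss = int(rng.integers(lo, hi, endpoint=True))
            strand = "+" if rng.random() < 0.5 else "-"
            klass = GENE_CLASSES[rng.integers(0, len(GENE_CLASSES))]
            gene = f"G{gid:04d}"
            gene_rows.append((gene, f"{gene}.1", chrom, strand, tss, klass))
            if rng.random() < 0.3:
                alt = min(tss + 500, length - 1)
                gene_rows.append((gene, f"{gene}.2", chrom, strand, alt, klass))
    tss_table = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "transcript_id", "chrom", "strand", "tss_pos", "class"],
    )

    enh_rows = []
    for i in range(config.n_enhancers):
        chrom, length = config.chrom_spec[rng.integers(0, len(config.chrom_spec))]
        start = int(rng.integers(0, max(1, length - 600)))
        enh_rows.append((chrom, start, start + 600, f"ENH{i + 1:04d}"))
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end", "name"])

    genes = tss_table["gene_id"].unique()
    n_muscle = max(1, int(config.muscle_fraction * len(genes)))
    muscle = sorted(rng.choice(genes, size=n_muscle, replace=False).tolist())
    return tss_table, enhancers, muscle


def choose_planted_promoters(tss_table: pd.DataFrame, catalog: SiteCatalog,
                             n: int, effect: float,
                             rng: np.random.Generator,
                             halfwidth: int = 1000,
                             min_sites: int = 2) -> list[tuple[str, int, float]]:
    """Pick n eligible promoter windows (>= min_sites member sites) to plant."""
    pos_by_chrom = {c: g["pos"].to_numpy() for c, g in catalog.sites.groupby("chrom")}
    eligible = []
    for row in tss_table.drop_duplicates("gene_id").itertuples(index=False):
        pos = pos_by_chrom.get(row.chrom)
        if pos is None:
            continue
        k = np.searchsorted(pos, [row.tss_pos - halfwidth, row.tss_pos + halfwidth + 1])
        if k[1] - k[0] >= min_sites:
            eligible.append((row.chrom, int(row.tss_pos)))
    if len(eligible) < n:
        raise ValueError(f"only {len(eligible)} promoter windows have >= {min_sites} sites")
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [(eligible[i][0], eligible[i][1], effect) for i in idx]


def choose_planted_blocks(config: SimulationConfig, n: int, effect: float,
                          rng: np.random.Generator,
                          width: int = 1_000_000) -> list[tuple[str, int, int, float]]:
    """Pick n distinct megabase bins and assign alternating-sign effects."""
    bins = []
    for chrom, length in config.chrom_spec:
        for b in range(length // width):
            bins.append((chrom, b * width, (b + 1) * width))
    if len(bins) < n:
        raise ValueError(f"only {len(bins)} whole bins available")
    idx = rng.choice(len(bins), size=n, replace=False)
    return [
        (bins[i][0], bins[i][1], bins[i][2], effect if k % 2 == 0 else -effect)
        for k, i in enumerate(idx)
    ]


@dataclass
class SimulatedCohort:
    """Everything one study run needs, bundled: catalogue, annotations,
    ground truth, design tables, and per-condition depth matrices."""

    config: SimulationConfig
    catalog: SiteCatalog
    truth: TruthTable
    tss_table: pd.DataFrame
    enhancers: pd.DataFrame
    muscle_genes: list[str]
    design: dict[str, pd.DataFrame] = field(default_factory=dict)
    depths: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.catalog.to_tsv(outdir / "site_catalog.tsv")
        self.truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        self.tss_table.to_csv(outdir / "tss_table.tsv", sep="\t", index=False)
        self.enhancers.to_csv(outdir / "enhancers.bed", sep="\t",
                              index=False, header=False)
        (outdir / "muscle_genes.txt").write_text("\n".join(self.muscle_genes) + "\n")
        for cond in self.depths:
            self.design[cond].to_csv(outdir / f"design_{cond}.tsv", sep="\t", index=False)
            self.depths[cond].to_csv(outdir / f"depth_{cond}.tsv", sep="\t")


def simulate_cohort(config: SimulationConfig,
                    n_planted_blocks: int = 0, block_effect: float = 1.0,
                    n_planted_promoters: int = 0, promoter_effect: float = 1.5,
                    conditions: Sequence[str] = CONDITIONS) -> SimulatedCohort:
    """End-to-end simulation of one study: shared ground truth, then an
    independent depth matrix per cell condition.

    Planted blocks/promoters may be requested by count here (placed
    reproducibly from the config seed) instead of being listed
    explicitly in the config.
    """
    rng = np.random.default_rng(config.seed)
    catalog = synthetic_catalog(config, rng)
    tss_table, enhancers, muscle = emit_annotations(config, catalog, rng)
    if n_planted_blocks and not config.block_spec:
        config = replace(config, block_spec=tuple(
            choose_planted_blocks(config, n_planted_blocks, block_effect, rng)))
    if n_planted_promoters and not config.promoter_spec:
        config = replace(config, promoter_spec=tuple(choose_planted_promoters(
            tss_table, catalog, n_planted_promoters, promoter_effect, rng,
            halfwidth=config.promoter_halfwidth)))
    truth = simulate_truth(config, catalog, rng)
    cohort = SimulatedCohort(config=config, catalog=catalog, truth=truth,
                             tss_table=tss_table, enhancers=enhancers,
                             muscle_genes=muscle)
    for cond in conditions:
        design = make_design(config.n_per_group, cond)
        cohort.design[cond] = design
        cohort.depths[cond] = simulate_depth_matrix(truth, config, design, rng)
    return cohort
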