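"""End-to-end orchestration: catalogue/simulation -> scores ->
per-condition differential sites -> overlap -> chromosome enrichment ->
megabase bins -> promoter loads -> run report.

Configuration is a flat key-value mapping (YAML or dict). Two modes:

``simulate``
    Generate a synthetic cohort from the bundled generator (default);
    all simulator keys mirror :class:`msreseq.simulate.SimulationConfig`.
``load``
    Read depth matrices, design tables and annotations from the paths
    given in the config.

Every stage logs a one-line count summary to stderr and contributes to
the machine-readable :class:`RunReport` (JSON). A fixed seed yields a
byte-identical report.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import data as refdata
from .cohort import cohort_summary
from .differential import (annotate_sites, annotation_summary,
                           common_significant, run_differential)
from .promoters import build_windows, promoter_loads, test_promoters
from .regions import (bin_correlation, bin_logfc, chromosome_enrichment,
                      enriched_intersection, flag_bins)
from .scoring import common_sites, normalize_depth
from .simulate import CONDITIONS, SimulationConfig, simulate_cohort


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def load_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key-value mapping")
    return cfg


def default_demo_config(seed: int = 0) -> dict[str, Any]:
    """The seeded demonstration run: 30 Mbp synthetic genome, planted
    site effects on an enriched chromosome, two megabase blocks and two
    shifted promoters."""
    return {
        "mode": "simulate",
        "seed": seed,
        "enriched_chroms": ["chr3"],
        "n_planted_blocks": 2,
        "block_effect": 0.3,
        "n_planted_promoters": 2,
        "promoter_effect": 1.5,
        "min_depth": 1,
        "alpha": 0.05,
        "p_method": "exact",
    }


@dataclass
class RunReport:
    """Per-stage counts plus the config echo — the run's audit record."""

    seed: int
    config: dict[str, Any]
    n_sites_catalog: int = 0
    n_sites_common: int = 0
    n_significant: dict[str, int] = field(default_factory=dict)
    n_overlap: int = 0
    n_overlap_hyper: int = 0
    n_overlap_hypo: int = 0
    n_overlap_discordant: int = 0
    enriched_chroms: dict[str, list[str]] = field(default_factory=dict)
    enriched_both: list[str] = field(default_factory=list)
    n_bins: dict[str, int] = field(default_factory=dict)
    n_bins_flagged: dict[str, int] = field(default_factory=dict)
    bin_correlation_r: float | None = None
    n_promoter_windows: int = 0
    n_significant_promoters: dict[str, int] = field(default_factory=dict)
    annotation: dict[str, dict[str, int]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_significant:
            if self.n_overlap > min(self.n_significant.values()):
                raise ValueError("overlap exceeds a per-condition significant count")
        parts = (self.n_overlap_hyper + self.n_overlap_hypo
                 + self.n_overlap_discordant)
        if parts != self.n_overlap:
            raise ValueError("overlap direction classes do not sum to total")
        if self.n_sites_common > self.n_sites_catalog:
            raise ValueError("common sites exceed catalogue size")

    def to_json(self) -> str:
        payload = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def _simulation_config(cfg: Mapping[str, Any]) -> SimulationConfig:
    kwargs: dict[str, Any] = {}
    for f in dc_fields(SimulationConfig):
        if f.name in cfg:
            v = cfg[f.name]
            if f.name == "enriched_chroms":
                v = frozenset(v)
            elif f.name in {"chrom_spec", "block_spec", "promoter_spec"}:
                v = tuple(tuple(x) for x in v)
            elif f.name == "baseline_beta" or f.name == "size_factor_range":
                v = tuple(v)
            kwargs[f.name] = v
    return SimulationConfig(**kwargs)


def _load_inputs(cfg: Mapping[str, Any]):
    depths, designs = {}, {}
    for cond in CONDITIONS:
        for key in (f"depth_{cond.lower()}", f"design_{cond.lower()}"):
            if key not in cfg:
                raise ValueError(f"load mode requires config key {key!r}")
            if not Path(cfg[key]).exists():
                raise FileNotFoundError(f"input path not found: {cfg[key]}")
        depths[cond] = pd.read_csv(cfg[f"depth_{cond.lower()}"], sep="\t",
                                   index_col=0)
        designs[cond] = pd.read_csv(cfg[f"design_{cond.lower()}"], sep="\t")
    tss = pd.read_csv(cfg["tss_table"], sep="\t") if "tss_table" in cfg else None
    enh = (pd.read_csv(cfg["enhancers"], sep="\t", header=None,
                       names=["chrom", "start", "end", "name"])
           if "enhancers" in cfg else None)
    muscle = (Path(cfg["muscle_genes"]).read_text().split()
              if "muscle_genes" in cfg else [])
    return depths, designs, tss, enh, muscle


def run_pipeline(config: str | Path | Mapping[str, Any],
                 outdir: str | Path | None = None) -> RunReport:
    """Execute every stage and return (and optionally write) the report."""
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    mode = cfg.get("mode", "simulate")
    alpha = float(cfg.get("alpha", 0.05))
    p_method = cfg.get("p_method", "exact")
    min_depth = int(cfg.get("min_depth", 1))
    report = RunReport(seed=seed, config=dict(cfg))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if mode == "simulate":
        sim_cfg = _simulation_config({**cfg, "seed": seed})
        cohort = simulate_cohort(
            sim_cfg,
            n_planted_blocks=int(cfg.get("n_planted_blocks", 0)),
            block_effect=float(cfg.get("block_effect", 1.0)),
            n_planted_promoters=int(cfg.get("n_planted_promoters", 0)),
            promoter_effect=float(cfg.get("promoter_effect", 1.5)),
        )
        depths, designs = cohort.depths, cohort.design
        tss, enh, muscle = cohort.tss_table, cohort.enhancers, cohort.muscle_genes
        catalog = cohort.catalog
        report.n_sites_catalog = len(catalog)
        if out is not None:
            cohort.write(out / "simulated_inputs")
        _log("simulate", f"{len(catalog)} catalogue sites, "
                         f"{int(cohort.truth.sites['dm_flag'].sum())} DM planted")
    elif mode == "load":
        depths, designs, tss, enh, muscle = _load_inputs(cfg)
        catalog = None
        report.n_sites_catalog = len(next(iter(depths.values())))
        _log("load", f"{report.n_sites_catalog} sites loaded")
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    # intersect sites covered in every sample of every condition
    joint = pd.concat([depths[c] for c in depths], axis=1)
    joint = common_sites(joint, min_depth=min_depth)
    report.n_sites_common = len(joint)
    _log("score", f"{len(joint)} sites in common at min_depth={min_depth}")

    scores, results, bins = {}, {}, {}
    for cond in depths:
        d = depths[cond].loc[joint.index]
        scores[cond] = normalize_depth(d, designs[cond])
        results[cond] = run_differential(scores[cond], alpha=alpha,
                                         p_method=p_method)
        report.n_significant[cond] = int(results[cond].table["significant"].sum())
        _log("diff", f"{cond}: {report.n_significant[cond]} significant sites "
                     f"(FDR < {alpha})")
        b = bin_logfc(results[cond])
        bins[cond] = flag_bins(b) if len(b) >= 2 else b.assign(flag="neutral")
        report.n_bins[cond] = len(bins[cond])
        report.n_bins_flagged[cond] = int((bins[cond]["flag"] != "neutral").sum())
        if out is not None:
            results[cond].to_tsv(out / f"sites_{cond}.tsv")
            bins[cond].to_csv(out / f"bins_{cond}.tsv", sep="\t", index=False)
        if tss is not None and enh is not None:
            genes = tss.drop_duplicates("gene_id").copy()
            genes["start"] = (genes["tss_pos"] - 1).clip(lower=0)
            genes["end"] = genes["tss_pos"] + 2000
            genes = genes.rename(columns={"gene_id": "name"})
            ann = annotate_sites(results[cond].significant, genes[
                ["chrom", "start", "end", "name"]], enh, muscle)
            report.annotation[cond] = annotation_summary(ann)

    conds = list(depths)
    if len(conds) == 2:
        a, b = conds
        overlap = common_significant(results[a], results[b],
                                     logfc_a=f"logfc_{a}", logfc_b=f"logfc_{b}")
        report.n_overlap = len(overlap)
        report.n_overlap_hyper = int((overlap["direction"] == "hyper").sum())
        report.n_overlap_hypo = int((overlap["direction"] == "hypo").sum())
        report.n_overlap_discordant = int((overlap["direction"] == "discordant").sum())
        _log("overlap", f"{report.n_overlap} sites significant in both "
                        f"({report.n_overlap_hyper} hyper / "
                        f"{report.n_overlap_hypo} hypo)")
        if out is not None:
            overlap.to_csv(out / "overlap_sites.tsv", sep="\t", index=False)
        try:
            r, n_shared = bin_correlation(bins[a], bins[b])
            report.bin_correlation_r = round(r, 6)
            _log("bins", f"bin logFC correlation {a} vs {b}: r={r:.3f} "
                         f"over {n_shared} bins")
        except ValueError:
            pass

    enr_tables = {}
    for cond in conds:
        enr = chromosome_enrichment(results[cond], alpha=alpha)
        enr_tables[cond] = enr
        report.enriched_chroms[cond] = sorted(enr.loc[enr["enriched"], "chrom"])
        if out is not None:
            enr.to_csv(out / f"enrichment_{cond}.tsv", sep="\t", index=False)
    report.enriched_both = enriched_intersection(*enr_tables.values())
    _log("enrich", f"enriched in all conditions: {report.enriched_both}")

    if tss is not None:
        # windows are built over the tested (common) site set, which is
        # shared across conditions by construction
        windows = build_windows(tss, results[conds[0]].table)
        report.n_promoter_windows = len(windows.table)
        for cond in conds:
            loads = promoter_loads(scores[cond], windows)
            ptab = test_promoters(loads, designs[cond], windows,
                                  alpha=alpha, p_method=p_method)
            report.n_significant_promoters[cond] = int(ptab["significant"].sum())
            if out is not None:
                ptab.to_csv(out / f"promoters_{cond}.tsv", sep="\t", index=False)
        _log("promoters", f"{report.n_promoter_windows} windows tested; "
                          f"significant: {report.n_significant_promoters}")

    report.validate()
    if out is not None:
        (out / "report.json").write_text(report.to_json() + "\n")
        _log("report", f"written to {out / 'report.json'}")
    return report


def reference_cohort_summary() -> pd.DataFrame:
    """Demographic summary of the bundled 12-subject cohort table."""
    return cohort_summary(refdata.cohort_design())
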