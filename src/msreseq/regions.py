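"""Regional structure of differential methylation.

Two views above the single-site level: a per-chromosome one-sided
Fisher exact test for enrichment of significant sites, and mean logFC
over fixed 1-Mbp bins with hyper/hypo flagging of bins falling outside
the 95% interval of the genome-wide bin-value distribution.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

BIN_WIDTH = 1_000_000
Z_95 = 1.959963984540054  # two-sided 95% normal quantile


def chromosome_enrichment(results, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided (greater) Fisher exact enrichment per chromosome.

    For each chromosome the 2x2 table is [significant on / off
    chromosome; non-significant on / off chromosome], with the tested
    sites as the universe. Enrichment, not depletion, is the question:
    depleted chromosomes report p ~ 1.
    """
    t = results.table if hasattr(results, "table") else results
    rows = []
    for chrom, sub in t.groupby("chrom", sort=False):
        n_total = len(sub)
        if n_total == 0:
            warnings.warn(f"{chrom}: no tested sites, excluded")
            continue
        n_sig = int(sub["significant"].sum())
        sig_off = int(t["significant"].sum()) - n_sig
        nonsig_on = n_total - n_sig
        nonsig_off = len(t) - n_total - sig_off
        _, p = stats.fisher_exact([[n_sig, sig_off], [nonsig_on, nonsig_off]],
                                  alternative="greater")
        rows.append((chrom, n_sig, n_total, float(p), p < alpha))
    return pd.DataFrame(rows, columns=["chrom", "n_sig", "n_total",
                                       "p_enrich", "enriched"])


def enriched_intersection(*enrichment_tables: pd.DataFrame) -> list[str]:
    """Chromosomes enriched under every condition."""
    sets = [set(t.loc[t["enriched"], "chrom"]) for t in enrichment_tables]
    return sorted(set.intersection(*sets)) if sets else []


def bin_logfc(results, bin_width: int = BIN_WIDTH) -> pd.DataFrame:
    """Mean logFC of tested sites over fixed-width genomic bins.

    A site at 1-based position p maps to bin floor((p - 1) / width);
    bins are anchored at coordinate 0 of each chromosome and empty bins
    are omitted. Trailing partial bins are kept.
    """
    t = results.table if hasattr(results, "table") else results
    b = t[["chrom", "pos", "logfc"]].copy()
    b["bin_index"] = (b["pos"] - 1) // bin_width
    g = (b.groupby(["chrom", "bin_index"], sort=False)
          .agg(n_sites=("logfc", "size"), mean_logfc=("logfc", "mean"))
          .reset_index())
    g["start"] = g["bin_index"] * bin_width
    g["end"] = (g["bin_index"] + 1) * bin_width
    return g[["chrom", "bin_index", "start", "end", "n_sites", "mean_logfc"]]


def flag_bins(bins: pd.DataFrame, method: str = "sd") -> pd.DataFrame:
    """Flag bins outside the 95% interval of the bin-value distribution.

    ``method="sd"`` (default): hyper if mean_logfc > mu + 1.96 sigma,
    hypo if < mu - 1.96 sigma, where mu and sigma are the genome-wide
    mean and SD of bin values. ``method="percentile"``: the empirical
    [2.5%, 97.5%] interval instead.
    """
    if len(bins) < 2:
        raise ValueError("need >= 2 bins to flag outliers")
    v = bins["mean_logfc"].to_numpy(dtype=float)
    out = bins.copy()
    if method == "sd":
        mu, sigma = v.mean(), v.std(ddof=1)
        if sigma == 0:
            warnings.warn("zero spread among bins; all flagged neutral")
            out["flag"] = "neutral"
            return out
        lo, hi = mu - Z_95 * sigma, mu + Z_95 * sigma
    elif method == "percentile":
        lo, hi = np.percentile(v, [2.5, 97.5])
    else:
        raise ValueError(f"unknown method: {method!r}")
    out["flag"] = np.where(v > hi, "hyper", np.where(v < lo, "hypo", "neutral"))
    return out


def bin_correlation(bins_a: pd.DataFrame, bins_b: pd.DataFrame) -> tuple[float, int]:
    """Pearson r of mean logFC over bins present in both tables."""
    a = bins_a.set_index(["chrom", "bin_index"])["mean_logfc"]
    b = bins_b.set_index(["chrom", "bin_index"])["mean_logfc"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared bins; need >= 3")
    r, _ = stats.pearsonr(a.loc[shared], b.loc[shared])
    return float(r), int(len(shared))
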