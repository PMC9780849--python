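"""Methylation scores from intact-fragment depths.

The upstream assay reports, per CpG site and sample, the sequencing
depth of HpaII-resistant (hence methylated) fragments. The commercial
scoring step of the original platform is undisclosed; the stand-in
implemented here is log2(CPM + 0.5) of that coverage — a score on the
same response scale as log-scaled expression data, which is what the
downstream linear-model tests assume. Externally computed score
matrices can be supplied instead (`ScoreMatrix.from_tsv`), so the
stand-in is swappable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import parse_site_id

PSEUDOCOUNT = 0.5


@dataclass
class ScoreMatrix:
    """Sites x samples methylation scores (log2 scale) plus the design.

    Rows are indexed by canonical site id and kept in (chrom, pos)
    order; columns match the design table's ``sample_id`` order.
    """

    scores: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.scores.columns) != list(self.design["sample_id"]):
            raise ValueError("score columns do not match design sample_ids")
        if self.scores.isna().any().any():
            raise ValueError("score matrix contains missing values")
        bad_groups = set(self.design["group"]) - {"CP", "control"}
        if bad_groups:
            raise ValueError(f"unknown groups: {sorted(bad_groups)}")
        if "condition" in self.design.columns:
            bad_cond = set(self.design["condition"]) - {"MB", "MT"}
            if bad_cond:
                raise ValueError(f"unknown conditions: {sorted(bad_cond)}")

    @property
    def site_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def positions(self) -> pd.DataFrame:
        parsed = [parse_site_id(s) for s in self.scores.index]
        return pd.DataFrame(parsed, columns=["chrom", "pos"],
                            index=self.scores.index)

    def group_columns(self, group: str) -> list[str]:
        return list(self.design.loc[self.design["group"] == group, "sample_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, scores_path: str | Path, design: pd.DataFrame) -> "ScoreMatrix":
        scores = pd.read_csv(scores_path, sep="\t", index_col=0)
        return cls(scores=scores, design=design)


def _sort_by_position(df: pd.DataFrame) -> pd.DataFrame:
    keys = sorted(df.index, key=parse_site_id)
    return df.loc[keys]


def normalize_depth(depths: pd.DataFrame, design: pd.DataFrame) -> ScoreMatrix:
    """log2(CPM + 0.5) scores from a site x sample depth matrix.

    CPM_ij = depth_ij / sum_i depth_ij * 1e6, so multiplying a sample's
    depths by any constant leaves its score column unchanged
    (library-size differences removed).
    """
    if (depths.to_numpy() < 0).any():
        raise ValueError("depths must be non-negative")
    totals = depths.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero depth column for sample(s): {list(zero.index)}")
    cpm = depths / totals * 1e6
    scores = np.log2(cpm + PSEUDOCOUNT)
    scores = _sort_by_position(scores)
    scores = scores[list(design["sample_id"])]
    return ScoreMatrix(scores=scores, design=design.reset_index(drop=True))


def common_sites(depths: pd.DataFrame, min_depth: int = 1) -> pd.DataFrame:
    """Retain sites covered at >= min_depth in every sample.

    Mirrors the study-design step of intersecting HpaII-site calls
    across all subjects before testing. Returns the filtered depth
    matrix; the retained count is its length.
    """
    keep = (depths >= min_depth).all(axis=1)
    if not keep.any():
        raise ValueError(
            f"no sites retained at min_depth={min_depth}; lower min_depth")
    return depths.loc[keep]
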