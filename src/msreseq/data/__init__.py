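"""Bundled reference tables for the spastic-CP myogenic-cell cohort.

Small published summary tables shipped as plain TSV: the cohort design
(12 subjects), the 79 CpG sites differentially methylated in both MBs
and MTs, per-chromosome significant-site counts with Fisher enrichment
p-values, and the significant promoter windows per condition.
"""

from importlib import resources

import pandas as pd


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)


def cohort_design() -> pd.DataFrame:
    """12-subject cohort design: sample, diagnosis, age, sex, GMFCS, tissue."""
    return _read("cohort_design.tsv", na_values=["NA"])


def overlap_sites() -> pd.DataFrame:
    """The 79 CpG sites significant in both MBs and MTs, with per-condition
    logFC and FDR-corrected p-values."""
    df = _read("overlap_sites.tsv")
    df["gene"] = df["gene"].fillna("")
    return df


def chromosome_enrichment_table() -> pd.DataFrame:
    """Per-chromosome significant-CpG counts and Fisher enrichment
    p-values for MB/MT cell conditions plus the external muscle-tissue
    and blood columns (fixture only; the latter two are not recomputed
    by this package)."""
    return _read("chromosome_enrichment.tsv")


def significant_promoters(condition: str) -> pd.DataFrame:
    """Significant promoter windows for condition 'MB' or 'MT'."""
    cond = condition.lower()
    if cond not in {"mb", "mt"}:
        raise ValueError("condition must be 'MB' or 'MT'")
    return _read(f"promoters_{cond}.tsv")
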