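"""Cohort design tables and demographic summaries."""

from __future__ import annotations

import warnings

import pandas as pd


def assign_groups(design: pd.DataFrame) -> pd.DataFrame:
    """Derive the two-cohort ``group`` column from the diagnosis field:
    a spastic-CP diagnosis maps to ``CP``, everything else (idiopathic
    conditions, injuries) to ``control``."""
    out = design.copy()
    if "group" not in out.columns:
        out["group"] = [
            "CP" if "CP" in str(d) else "control" for d in out["diagnosis"]
        ]
    return out


def cohort_summary(design: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, sex counts, mean age and sample (n-1) SD of age.

    Display columns (``age_mean``, ``age_sd``) are rounded to one
    decimal; groups of size < 2 omit the SD with a warning.
    """
    design = assign_groups(design)
    if design["age"].isna().any():
        raise ValueError("ages must be present for every sample")
    if (design["age"] <= 0).any():
        raise ValueError("ages must be positive")
    rows = []
    for group, sub in design.groupby("group"):
        if len(sub) < 2:
            warnings.warn(f"group {group} has < 2 samples; SD omitted")
            sd = float("nan")
        else:
            sd = round(float(sub["age"].std(ddof=1)), 1)
        sexes = sub["sex"].value_counts().to_dict() if "sex" in sub else {}
        rows.append({
            "group": group,
            "n": len(sub),
            "n_male": int(sexes.get("M", 0)),
            "n_female": int(sexes.get("F", 0)),
            "age_mean": round(float(sub["age"].mean()), 1),
            "age_sd": sd,
        })
    return pd.DataFrame(rows)
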