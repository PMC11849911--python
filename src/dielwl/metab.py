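"""Targeted-metabolomics censoring, run normalization and diel statistics.

Features are censored on peak height against a limit of detection (LOD,
2x background) and limit of quantification (LOQ, 5x background), with
optional absolute overrides; boundary values fall in the upper category.
Technical runs are normalized by the summed abundance of a representative
retention-time x m/z region: each sample's values are divided by its region
sum and rescaled by the grand mean region sum, which makes the
normalization idempotent and pins every sample's post-normalization region
sum to that grand mean exactly.  Time-of-day x treatment effects per
feature are tested on log peak area by a two-way fixed-effects model, with
Holm-adjusted pairwise ZT contrasts within treatment; censored values are
excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LimitSpec",
    "censor",
    "normalize_region",
    "average_injections",
    "diel_treatment_stats",
]

FLAG_ND = "ND"
FLAG_LT_LOQ = "<LOQ"
FLAG_QUANT = "quantified"


@dataclass(frozen=True)
class LimitSpec:
    """Detection/quantification limits, multiplier-based with overrides.

    ``lod = lod_multiplier * background`` and ``loq = loq_multiplier *
    background`` unless absolute overrides are given (peak-height units).
    """

    background: float
    lod_multiplier: float = 2.0
    loq_multiplier: float = 5.0
    lod_absolute: float | None = None
    loq_absolute: float | None = None

    def __post_init__(self):
        if self.background <= 0:
            raise ValueError("background level must be positive")
        if self.loq <= 0 or self.lod <= 0 or self.loq < self.lod:
            raise ValueError("limits must satisfy loq >= lod > 0")

    @property
    def lod(self) -> float:
        return (
            self.lod_absolute
            if self.lod_absolute is not None
            else self.lod_multiplier * self.background
        )

    @property
    def loq(self) -> float:
        return (
            self.loq_absolute
            if self.loq_absolute is not None
            else self.loq_multiplier * self.background
        )


def censor(table: pd.DataFrame, limits: LimitSpec) -> pd.DataFrame:
    """Flag each row by peak height: ND / "<LOQ" / quantified.

    height < LOD -> ND; LOD <= height < LOQ -> detected but not
    quantifiable; height >= LOQ -> quantified (boundaries inclusive at the
    upper category).  Negative heights are an error.
    """
    if "height" not in table.columns:
        raise ValueError("table needs a 'height' column")
    h = table["height"].to_numpy(dtype=float)
    if np.any(h < 0):
        raise ValueError("negative peak heights")
    flags = np.where(h < limits.lod, FLAG_ND, np.where(h < limits.loq, FLAG_LT_LOQ, FLAG_QUANT))
    out = table.copy()
    out["flag"] = flags
    return out


def normalize_region(
    table: pd.DataFrame,
    region: tuple,
    sample_col: str = "run_id",
    value_col: str = "area",
) -> tuple:
    """Region-sum normalize abundances across technical runs.

    ``region`` is ``(rt_min, rt_max, mz_min, mz_max)``.  Each sample's
    values are divided by its summed abundance over features inside the
    region and multiplied by the mean region sum over all samples, so after
    normalization every sample's region sum equals that mean exactly.
    Samples with zero region sum are excluded and reported.  Returns
    ``(normalized_table, factors)`` with per-sample region sums and scale
    factors.
    """
    rt_min, rt_max, mz_min, mz_max = region
    in_region = (
        table["rt"].between(rt_min, rt_max) & table["mz"].between(mz_min, mz_max)
    )
    if not in_region.any():
        raise ValueError("no features inside the representative region")
    sums = table.loc[in_region].groupby(sample_col)[value_col].sum()
    sums = sums.reindex(table[sample_col].unique()).fillna(0.0)
    bad = sums.index[sums <= 0].tolist()
    sums_ok = sums.drop(bad)
    grand_mean = float(sums_ok.mean())
    factors = pd.DataFrame(
        {
            "region_sum": sums_ok,
            "scale_factor": grand_mean / sums_ok,
        }
    )
    factors.index.name = sample_col
    out = table[~table[sample_col].isin(bad)].copy()
    out[value_col] = out[value_col] * out[sample_col].map(factors["scale_factor"]).to_numpy()
    if "height" in out.columns and value_col != "height":
        out["height"] = out["height"] * out[sample_col].map(factors["scale_factor"]).to_numpy()
    factors.attrs["excluded_samples"] = bad
    return out, factors


def average_injections(table: pd.DataFrame, value_cols=("area", "height")) -> pd.DataFrame:
    """Average technical injections within each biological sample."""
    keys = [
        c
        for c in ("feature", "mz", "rt", "accession", "treatment", "zt", "bio_replicate")
        if c in table.columns
    ]
    return table.groupby(keys, as_index=False)[list(value_cols)].mean()


def diel_treatment_stats(
    feature_table: pd.DataFrame,
    alpha: float = 0.05,
    min_reps: int = 2,
) -> dict:
    """Two-way time-of-day x treatment statistics for one feature.

    Fits ``log(area) ~ treatment * ZT`` on quantified rows only and reports
    the ZT main-effect and interaction p-values plus Holm-adjusted pairwise
    ZT contrasts (Welch) within each treatment.  Cells (treatment x ZT)
    that are entirely non-detected mark the feature ``partial`` and the
    contrasts touching them are skipped; features without residual
    variance are flagged ``degenerate``.
    """
    df = feature_table.copy()
    if "flag" in df.columns:
        n_censored = int((df["flag"] != FLAG_QUANT).sum())
        df = df[df["flag"] == FLAG_QUANT]
    else:
        n_censored = 0
    df = df[df["area"] > 0].copy()
    result = {
        "feature": feature_table["feature"].iloc[0] if len(feature_table) else None,
        "n_used": len(df),
        "n_censored": n_censored,
        "p_zt": np.nan,
        "p_interaction": np.nan,
        "p_treatment": np.nan,
        "partial": False,
        "degenerate": False,
        "contrasts": pd.DataFrame(
            columns=["treatment", "zt_a", "zt_b", "p_value", "p_holm"]
        ),
    }
    if df.empty:
        result["partial"] = True
        return result
    df["log_area"] = np.log(df["area"])

    all_cells = [
        (t, z)
        for t in feature_table["treatment"].unique()
        for z in sorted(feature_table["zt"].unique())
    ]
    counts = df.groupby(["treatment", "zt"]).size()
    missing_cells = [c for c in all_cells if counts.get(c, 0) < min_reps]
    result["partial"] = len(missing_cells) > 0

    if df["zt"].nunique() >= 2 and df["treatment"].nunique() >= 2 and len(df) > 4:
        if np.isclose(df["log_area"].var(), 0.0):
            result["degenerate"] = True
        else:
            model = ols("log_area ~ C(treatment) * C(zt)", data=df).fit()
            if model.df_resid > 0 and model.ssr > 1e-12:
                tab = anova_lm(model, typ=2)
                result["p_zt"] = float(tab.loc["C(zt)", "PR(>F)"])
                result["p_treatment"] = float(tab.loc["C(treatment)", "PR(>F)"])
                result["p_interaction"] = float(tab.loc["C(treatment):C(zt)", "PR(>F)"])
            else:
                result["degenerate"] = True

    rows = []
    for t in df["treatment"].unique():
        zts = sorted(df.loc[df["treatment"] == t, "zt"].unique())
        for za, zb in combinations(zts, 2):
            if (t, za) in missing_cells or (t, zb) in missing_cells:
                continue
            a = df.loc[(df["treatment"] == t) & (df["zt"] == za), "log_area"]
            b = df.loc[(df["treatment"] == t) & (df["zt"] == zb), "log_area"]
            if len(a) < min_reps or len(b) < min_reps:
                continue
            if np.isclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
                p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            rows.append({"treatment": t, "zt_a": za, "zt_b": zb, "p_value": p})
    if rows:
        contrasts = pd.DataFrame(rows)
        contrasts["p_holm"] = multipletests(contrasts["p_value"], method="holm")[1]
        result["contrasts"] = contrasts
    return result


def diel_treatment_stats_table(table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Run :func:`diel_treatment_stats` per feature; tidy summary frame."""
    rows = []
    for feat, sub in table.groupby("feature"):
        r = diel_treatment_stats(sub, **kwargs)
        rows.append(
            {
                "feature": feat,
                "n_used": r["n_used"],
                "n_censored": r["n_censored"],
                "p_zt": r["p_zt"],
                "p_treatment": r["p_treatment"],
                "p_interaction": r["p_interaction"],
                "partial": r["partial"],
                "degenerate": r["degenerate"],
            }
        )
    return pd.DataFrame(rows)
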