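"""Diel phase estimation, phase-change classification and subgenome summaries.

Phase is the ZT of peak replicate-mean expression on the 4-point grid
{1, 7, 13, 19}; with 6-hourly sampling the phase-change between treatments
is necessarily a multiple of 6 h, giving exactly five circular classes
{-12, -6, 0, +6, +12}.  The sign convention follows "positive = WL peaks
earlier": the difference ``phase_WW - phase_WL`` is wrapped so that +/-18
becomes -/+6, while +/-12 keeps the sign of the unwrapped difference (the
two half-cycle shifts are circularly identical and are distinguished only
by direction).  A ``flip_sign`` flag is available for the opposite
reporting convention.

The homoeolog map (gene -> BnA/BnC subgenome and ortholog group) drives the
divergence summaries: phase-group proportions per subgenome, mean-expression
bias between subgenomes, accession-sharing histograms at gene versus
ortholog level, and per-ortholog profiles of which homoeolog copies respond.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dielwl.containers import ZT_GRID, ExpressionTimeCourse, validate_homoeolog_map

__all__ = [
    "estimate_phase",
    "phase_change_group",
    "phase_table",
    "subgenome_phase_proportions",
    "subgenome_expression_bias",
    "gene_sharing_distribution",
    "responsive_homoeolog_profile",
]

PHASE_GROUPS = (-12, -6, 0, 6, 12)


def estimate_phase(profile) -> float:
    """ZT of maximum of a replicate-mean 4-point profile.

    Ties break toward the earliest ZT; an all-equal profile has no peak and
    returns NaN (the gene is excluded from phase analysis).
    """
    x = np.asarray(profile, dtype=float)
    if x.shape[-1] != len(ZT_GRID):
        raise ValueError(f"profile must cover exactly the ZT grid {ZT_GRID}")
    if np.all(x == x[..., :1], axis=-1).all():
        return float("nan")
    return float(ZT_GRID[int(np.argmax(x))])


def _phases_vector(mean_profiles: pd.DataFrame) -> pd.Series:
    arr = mean_profiles[list(ZT_GRID)].to_numpy(dtype=float)
    flat = np.all(arr == arr[:, :1], axis=1) | ~np.isfinite(arr).all(axis=1)
    idx = np.argmax(arr, axis=1)  # argmax takes the first maximum: earliest ZT
    phases = np.asarray(ZT_GRID, dtype=float)[idx]
    phases[flat] = np.nan
    return pd.Series(phases, index=mean_profiles.index)


def phase_change_group(phase_ww: float, phase_wl: float, flip_sign: bool = False) -> int:
    """Classify a WW->WL phase change into {-12, -6, 0, +6, +12} hours.

    Positive = WL peaks earlier.  The raw difference ``phase_WW - phase_WL``
    is wrapped: +18 -> -6 and -18 -> +6; +/-12 keeps its sign.
    """
    grid = set(ZT_GRID)
    if phase_ww not in grid or phase_wl not in grid:
        raise ValueError(f"phases must lie on the ZT grid {ZT_GRID}")
    d = int(phase_ww - phase_wl)
    if d == 18:
        d = -6
    elif d == -18:
        d = 6
    return -d if flip_sign else d


def phase_table(
    tc_ww: ExpressionTimeCourse,
    tc_wl: ExpressionTimeCourse,
    genes=None,
    flip_sign: bool = False,
) -> pd.DataFrame:
    """Phase per treatment and phase-change group for each (called) gene.

    Genes with a flat profile in either treatment are dropped (phase
    undefined).  ``genes`` restricts to a call set.
    """
    p_ww = _phases_vector(tc_ww.replicate_mean())
    p_wl = _phases_vector(tc_wl.replicate_mean())
    df = pd.DataFrame({"phase_WW": p_ww, "phase_WL": p_wl})
    if genes is not None:
        df = df.loc[df.index.intersection(pd.Index(genes))]
    df = df.dropna()
    df["group"] = [
        phase_change_group(ww, wl, flip_sign=flip_sign)
        for ww, wl in zip(df["phase_WW"], df["phase_WL"])
    ]
    df.index.name = "gene_id"
    return df


def subgenome_phase_proportions(
    phase_records: pd.DataFrame, hmap: pd.DataFrame, accession: str | None = None
) -> pd.DataFrame:
    """Proportion of WL genes per phase-change group, total and by subgenome.

    Proportions are taken relative to the total number of (mapped) WL genes
    within the stratum, so each stratum's proportions sum to 1.  Unmapped
    genes are reported under subgenome ``"unmapped"`` (excluded from the
    per-subgenome strata but counted in the report).
    """
    hmap = validate_homoeolog_map(hmap.reset_index(drop=True))
    sub = hmap["subgenome"].reindex(phase_records.index)
    rows = []
    strata = {"all": phase_records.index}
    for sg in ("BnA", "BnC"):
        strata[sg] = phase_records.index[sub == sg]
    unmapped = phase_records.index[sub.isna()]
    for name, idx in strata.items():
        groups = phase_records.loc[idx, "group"]
        total = len(groups)
        for g in PHASE_GROUPS:
            rows.append(
                {
                    "accession": accession,
                    "subgenome": name,
                    "group": g,
                    "n_genes": int((groups == g).sum()),
                    "proportion": (groups == g).sum() / total if total else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_unmapped"] = len(unmapped)
    return out


def subgenome_expression_bias(
    courses, hmap: pd.DataFrame, n_boot: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Mean log2 expression by subgenome with a bootstrap CI on BnC - BnA.

    One row per course (accession x treatment): per-subgenome mean and
    log-sum expression, the BnC - BnA mean difference, and a percentile
    bootstrap interval over genes.  A subgenome with zero genes yields NaN
    and is reported rather than silently skipped.
    """
    hmap = validate_homoeolog_map(hmap.reset_index(drop=True))
    rng = np.random.default_rng(seed)
    rows = []
    for c in courses:
        sub = hmap["subgenome"].reindex(c.genes)
        gene_means = c.data.mean(axis=1)
        vals = {}
        for sg in ("BnA", "BnC"):
            x = gene_means[sub == sg]
            vals[sg] = x
        diff = (
            float(vals["BnC"].mean() - vals["BnA"].mean())
            if len(vals["BnA"]) and len(vals["BnC"])
            else np.nan
        )
        lo = hi = np.nan
        if np.isfinite(diff):
            a, b = vals["BnA"].to_numpy(), vals["BnC"].to_numpy()
            boots = [
                rng.choice(b, b.size).mean() - rng.choice(a, a.size).mean()
                for _ in range(n_boot)
            ]
            lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "accession": c.accession,
                "treatment": c.treatment,
                "mean_BnA": vals["BnA"].mean() if len(vals["BnA"]) else np.nan,
                "mean_BnC": vals["BnC"].mean() if len(vals["BnC"]) else np.nan,
                "logsum_BnA": np.log2((2 ** vals["BnA"]).sum()) if len(vals["BnA"]) else np.nan,
                "logsum_BnC": np.log2((2 ** vals["BnC"]).sum()) if len(vals["BnC"]) else np.nan,
                "diff_BnC_minus_BnA": diff,
                "diff_ci_low": lo,
                "diff_ci_high": hi,
                "n_BnA": int(len(vals["BnA"])),
                "n_BnC": int(len(vals["BnC"])),
            }
        )
    return pd.DataFrame(rows)


def gene_sharing_distribution(call_sets: dict, hmap: pd.DataFrame) -> pd.DataFrame:
    """Accession-sharing histograms at gene level and ortholog-group level.

    ``call_sets`` maps accession -> set of WL-called genes.  At the gene
    level each gene counts the accessions calling it; at the ortholog level
    an ortholog group's accession set is the union over its member genes, so
    the ortholog-level count always dominates the per-member counts.
    Returns a tidy histogram (level, n_accessions, count, proportion).
    """
    if len(call_sets) < 2:
        raise ValueError("sharing needs at least 2 accessions")
    hmap = validate_homoeolog_map(hmap.reset_index(drop=True))
    gene_counts = {}
    og_sets = {}
    for acc, genes in call_sets.items():
        for g in genes:
            gene_counts[g] = gene_counts.get(g, 0) + 1
            og = hmap["ortholog_group"].get(g)
            if og is not None:
                og_sets.setdefault(og, set()).add(acc)
    rows = []
    n_acc = len(call_sets)
    for level, counts in (
        ("gene", list(gene_counts.values())),
        ("ortholog", [len(s) for s in og_sets.values()]),
    ):
        counts = np.asarray(counts)
        total = counts.size
        for k in range(1, n_acc + 1):
            n = int((counts == k).sum())
            rows.append(
                {
                    "level": level,
                    "n_accessions": k,
                    "count": n,
                    "proportion": n / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def responsive_homoeolog_profile(
    ortholog_group: str, call_sets: dict, hmap: pd.DataFrame
) -> pd.DataFrame:
    """Which homoeolog copies of one ortholog group respond, per accession.

    Returns accession x (n_responsive, n_BnA, n_BnC, members) covering the
    one/two/three-responsive-copy summaries.
    """
    hmap = validate_homoeolog_map(hmap.reset_index(drop=True))
    members = hmap[hmap["ortholog_group"] == ortholog_group]
    if members.empty:
        raise KeyError(f"unknown ortholog group {ortholog_group!r}")
    rows = []
    for acc, genes in call_sets.items():
        hit = members[members["gene_id"].isin(set(genes))]
        rows.append(
            {
                "accession": acc,
                "n_responsive": len(hit),
                "n_BnA": int((hit["subgenome"] == "BnA").sum()),
                "n_BnC": int((hit["subgenome"] == "BnC").sum()),
                "members": ",".join(sorted(hit["gene_id"])),
            }
        )
    return pd.DataFrame(rows).set_index("accession")
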