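"""Preprocessing and differential diel-pattern detection.

A gene is water-limitation responsive if its 4-point diel expression course
changes between treatments either in *shape* or in *level*:

* the **kME score** measures pattern change: each replicate time course is
  z-scored and correlated with a basis of eigengene profiles; the score is
  the summed absolute difference between the treatments' mean correlations,
  ``kME(g) = sum_m |mean_r cor(g_WL,r, E_m) - mean_r cor(g_WW,r, E_m)|``.
  Averaging per-replicate correlations (rather than correlating the
  replicate-mean profile) keeps the score sensitive to within-treatment
  consistency, which is what gives the treatment-label permutation null its
  power against balanced pattern changes such as antiphase flips.
* the **Med score** measures level change:
  ``Med(g) = |median(g_WL samples) - median(g_WW samples)|``.

Significance comes from an empirical-FDR permutation test that shuffles
treatment labels of whole replicate time courses within an accession, which
preserves within-series autocorrelation.  Upstream helpers implement the
zero-variance / low-expression filters, TMM library-size normalization and
single-missing-replicate imputation the scores assume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from dielwl.containers import ZT_GRID, REPLICATES, ExpressionTimeCourse

__all__ = [
    "filter_genes",
    "tmm_factors",
    "normalize_counts",
    "impute_missing_replicate",
    "impute_course",
    "build_eigengene_basis",
    "pattern_change_scores",
    "permutation_calls",
    "validate_with_pointwise_tests",
    "drop_low_signal_accessions",
]


# --------------------------------------------------------------------------
# filtering / normalization / imputation


def filter_genes(courses):
    """Apply the zero-variance and low-expression filters.

    Genes with no variance across all samples of all supplied courses are
    removed; the remainder is kept only if the replicate-mean log2
    expression exceeds zero at at least one ZT in at least one course.

    Parameters
    ----------
    courses : sequence of ExpressionTimeCourse
        Typically the WW and WL courses of one accession.

    Returns
    -------
    (filtered_courses, report) where ``report`` is a frame listing every
    removed gene and the rule that removed it.
    """
    courses = list(courses)
    if not courses:
        raise ValueError("no courses supplied")
    genes = courses[0].genes
    for c in courses[1:]:
        if not c.genes.equals(genes):
            raise ValueError("courses must share one gene index")

    combined = pd.concat([c.data for c in courses], axis=1)
    variance = combined.var(axis=1, ddof=0)
    zero_var = variance.fillna(0.0) == 0.0

    means = pd.concat([c.replicate_mean() for c in courses], axis=1)
    expressed = (means > 0.0).any(axis=1)

    removed = []
    for g in genes[zero_var]:
        removed.append({"gene_id": g, "reason": "zero_variance"})
    for g in genes[~zero_var & ~expressed]:
        removed.append({"gene_id": g, "reason": "low_expression"})
    keep = genes[~zero_var & expressed]
    if len(keep) == 0:
        warnings.warn("all genes removed by filtering", RuntimeWarning, stacklevel=2)
    report = pd.DataFrame(removed, columns=["gene_id", "reason"])
    out = [
        ExpressionTimeCourse(c.accession, c.treatment, c.data.loc[keep].copy())
        for c in courses
    ]
    return out, report


def tmm_factors(
    counts: pd.DataFrame,
    ref_column=None,
    log_ratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors for a count matrix.

    Implements the standard TMM recipe: per-gene log ratios (M) and average
    log expression (A) against a reference sample, doubly trimmed
    (``log_ratio_trim`` on M, ``abs_expr_trim`` on A), combined by a
    precision-weighted mean; factors are rescaled to have geometric mean 1.
    The reference defaults to the sample whose 75th percentile of scaled
    counts is closest to the mean across samples.
    """
    counts = counts.astype(float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    if ref_column is None:
        q75 = counts.div(lib, axis=1).quantile(0.75)
        ref_column = (q75 - q75.mean()).abs().idxmin()
    ref = counts[ref_column]
    nref = lib[ref_column]

    factors = {}
    for s in counts.columns:
        if s == ref_column:
            factors[s] = 1.0
            continue
        obs, nobs = counts[s], lib[s]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() == 0:
            factors[s] = 1.0
            continue
        p_obs, p_ref = obs[ok] / nobs, ref[ok] / nref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        w = (nobs - obs[ok]) / (nobs * obs[ok]) + (nref - ref[ok]) / (nref * ref[ok])
        lo_m, hi_m = np.quantile(m, [log_ratio_trim, 1 - log_ratio_trim])
        lo_a, hi_a = np.quantile(a, [abs_expr_trim, 1 - abs_expr_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0 or np.allclose(m, 0):
            factors[s] = 1.0
        else:
            factors[s] = float(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))
    f = pd.Series(factors)[counts.columns]
    return f / np.exp(np.mean(np.log(f)))


def normalize_counts(
    counts: pd.DataFrame, gene_lengths: pd.Series | None = None
) -> tuple:
    """Library-size normalize raw counts and return log2 expression.

    Counts are scaled by TMM-adjusted effective library sizes to
    counts-per-million; when ``gene_lengths`` (bp) is given an additional
    per-kilobase correction yields FPKM-like values.  The result is
    ``log2(x + 1)``.  Returns ``(log2_expression, scale_factors)``.
    """
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=0) * factors
    cpm = counts.div(eff_lib, axis=1) * 1e6
    if gene_lengths is not None:
        lengths_kb = gene_lengths.reindex(counts.index) / 1e3
        if lengths_kb.isna().any() or (lengths_kb <= 0).any():
            raise ValueError("gene lengths must be positive and cover all genes")
        cpm = cpm.div(lengths_kb, axis=0)
    return np.log2(cpm + 1.0), factors


def impute_missing_replicate(values) -> float:
    """Impute a single missing replicate as the median of the two observed."""
    values = np.asarray(values, dtype=float)
    if values.size != 2 or np.isnan(values).any():
        raise ValueError("exactly two observed replicate values are required")
    return float(np.median(values))


def impute_course(tc: ExpressionTimeCourse):
    """Fill single-missing replicates; flag genes with >= 2 missing at a ZT.

    Returns ``(imputed_course, unusable_genes)``.  The imputed course
    records which cells were filled in its ``imputed`` mask; genes with two
    or more missing replicates at any ZT cannot be imputed under the
    median-of-two rule and are returned separately (to be excluded for this
    accession).
    """
    data = tc.data.copy()
    missing_per_zt = tc.n_missing_per_zt()
    unusable = data.index[(missing_per_zt >= 2).any(axis=1)]
    imputed_mask = pd.DataFrame(False, index=data.index, columns=data.columns)
    for zt in ZT_GRID:
        block = data[zt]
        rows = block.isna().sum(axis=1) == 1
        if not rows.any():
            continue
        med = block[rows].median(axis=1)
        for rep in block.columns:
            fill = rows & block[rep].isna()
            data.loc[fill, (zt, rep)] = med[fill]
            imputed_mask.loc[fill, (zt, rep)] = True
    out = ExpressionTimeCourse(tc.accession, tc.treatment, data, imputed=imputed_mask)
    return out, list(unusable)


# --------------------------------------------------------------------------
# eigengene basis and scores


def _zscore_profiles(x: np.ndarray) -> np.ndarray:
    """Z-score 4-point profiles along the last axis; flat profiles -> zeros."""
    mu = np.nanmean(x, axis=-1, keepdims=True)
    sd = np.nanstd(x, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[~np.isfinite(z)] = 0.0
    return z


@dataclass
class EigengeneBasis:
    """Basis of representative 4-point diel profiles (rows z-scored)."""

    profiles: pd.DataFrame  # eigengene x ZT
    cluster_sizes: pd.Series

    @property
    def zscored(self) -> np.ndarray:
        return _zscore_profiles(self.profiles.to_numpy())


def build_eigengene_basis(
    courses,
    min_cluster_size: int = 20,
    cut_height: float = 0.3,
) -> EigengeneBasis:
    """Cluster diel profiles from the combined treatments into eigengenes.

    Every gene contributes its replicate-mean 4-point profile from each
    supplied course (so WW and WL shapes are both represented in one shared
    basis).  Profiles are z-scored, clustered by average linkage on the
    signed-correlation dissimilarity ``(1 - r)/2`` and cut at
    ``cut_height``; each retained cluster is summarized by the
    sign-oriented first principal component of its member profiles.

    The default cut height (0.3 on the (1 - r)/2 dissimilarity, i.e.
    within-cluster correlation above ~0.4) keeps clusters of distinct peak
    times apart; a coarser cut can fuse antiphase shape families into a
    nearly collinear basis that is blind to the orthogonal phases.
    """
    profiles = np.vstack([c.replicate_mean().to_numpy() for c in courses])
    z = _zscore_profiles(profiles)
    keep = z.any(axis=1)
    z = z[keep]
    if z.shape[0] == 0:
        raise ValueError("no non-flat profiles to build a basis from")
    if z.shape[0] <= min_cluster_size:
        labels = np.ones(z.shape[0], dtype=int)
    else:
        r = np.clip(np.corrcoef(z), -1.0, 1.0)
        diss = (1.0 - r) / 2.0
        np.fill_diagonal(diss, 0.0)
        labels = fcluster(average(squareform(diss, checks=False)), cut_height, "distance")

    eig_rows, sizes = [], []
    for lab in np.unique(labels):
        members = z[labels == lab]
        if members.shape[0] < min_cluster_size and len(np.unique(labels)) > 1:
            continue
        eig_rows.append(_first_pc(members))
        sizes.append(members.shape[0])
    if not eig_rows:  # all clusters below the size floor: one trivial basis
        eig_rows, sizes = [_first_pc(z)], [z.shape[0]]
    prof = pd.DataFrame(
        np.vstack(eig_rows),
        index=[f"E{i + 1}" for i in range(len(eig_rows))],
        columns=list(ZT_GRID),
    )
    return EigengeneBasis(prof, pd.Series(sizes, index=prof.index))


def _first_pc(members: np.ndarray) -> np.ndarray:
    """Sign-oriented first right-singular vector of a profile matrix.

    No column centering: the members are already z-scored per profile, and
    the shared shape is exactly what the summary must retain.
    """
    if members.shape[0] == 1:
        v = members[0]
    else:
        _, _, vt = np.linalg.svd(members, full_matrices=False)
        v = vt[0]
    mean_profile = members.mean(axis=0)
    if np.dot(v, mean_profile) < 0:
        v = -v
    return v


def _course_stack(tc: ExpressionTimeCourse) -> np.ndarray:
    """Return replicate time courses as (genes, replicates, ZTs)."""
    arr = np.empty((len(tc.genes), len(REPLICATES), len(ZT_GRID)))
    for ri, rep in enumerate(REPLICATES):
        for zi, zt in enumerate(ZT_GRID):
            arr[:, ri, zi] = tc.data[(zt, rep)].to_numpy()
    return arr


def _eigengene_correlations(courses: np.ndarray, basis: EigengeneBasis) -> np.ndarray:
    """Pearson r of each z-scored course with each eigengene, (G, R, M)."""
    z = _zscore_profiles(courses)
    ez = _zscore_profiles(basis.profiles.to_numpy())
    return np.einsum("grt,mt->grm", z, ez) / len(ZT_GRID)


def _scores_for_assignment(corr, samples, sel, profile, basis_z):
    """kME and Med given a boolean course-assignment (True = pseudo-WW)."""
    if profile == "per_replicate":
        m_ww = corr[:, sel].mean(axis=1)
        m_wl = corr[:, ~sel].mean(axis=1)
        kme = np.abs(m_wl - m_ww).sum(axis=1)
    else:  # replicate_mean
        prof_ww = _zscore_profiles(samples[:, sel].mean(axis=1))
        prof_wl = _zscore_profiles(samples[:, ~sel].mean(axis=1))
        r_ww = prof_ww @ basis_z.T / len(ZT_GRID)
        r_wl = prof_wl @ basis_z.T / len(ZT_GRID)
        kme = np.abs(r_wl - r_ww).sum(axis=1)
    g = samples.shape[0]
    med_ww = np.nanmedian(samples[:, sel].reshape(g, -1), axis=1)
    med_wl = np.nanmedian(samples[:, ~sel].reshape(g, -1), axis=1)
    return kme, np.abs(med_wl - med_ww)


def pattern_change_scores(
    tc_ww: ExpressionTimeCourse,
    tc_wl: ExpressionTimeCourse,
    basis: EigengeneBasis,
    profile: str = "per_replicate",
) -> pd.DataFrame:
    """Per-gene kME (pattern change) and Med (level change) scores.

    ``profile='per_replicate'`` (default) averages the per-replicate
    eigengene correlations before differencing; ``'replicate_mean'``
    correlates the z-scored replicate-mean profile instead.  Genes whose
    profiles have zero variance get correlation 0 and are flagged.
    """
    if not tc_ww.genes.equals(tc_wl.genes):
        raise ValueError("WW and WL courses must share one gene index")
    if profile not in {"per_replicate", "replicate_mean"}:
        raise ValueError("profile must be 'per_replicate' or 'replicate_mean'")
    c_ww, c_wl = _course_stack(tc_ww), _course_stack(tc_wl)
    samples = np.concatenate([c_ww, c_wl], axis=1)  # (G, 6, 4)
    corr = np.concatenate(
        [_eigengene_correlations(c_ww, basis), _eigengene_correlations(c_wl, basis)],
        axis=1,
    )
    sel = np.array([True] * len(REPLICATES) + [False] * len(REPLICATES))
    basis_z = _zscore_profiles(basis.profiles.to_numpy())
    kme, med = _scores_for_assignment(corr, samples, sel, profile, basis_z)
    flat = ~_zscore_profiles(np.nanmean(samples, axis=1)).any(axis=1)
    return pd.DataFrame(
        {"kME": kme, "Med": med, "flat_profile": flat}, index=tc_ww.genes
    )


def _pooled_fdr(observed: np.ndarray, null_pool: np.ndarray, n_perm: int) -> np.ndarray:
    """Empirical FDR per observed score from a pooled permutation null.

    ``FDR(s) = (#null >= s / n_perm) / #observed >= s``, made monotone by
    taking the running minimum from the largest score down (a q-value).
    """
    order = np.argsort(observed)[::-1]
    s_sorted = observed[order]
    null_sorted = np.sort(null_pool)
    n_null_ge = null_sorted.size - np.searchsorted(null_sorted, s_sorted, side="left")
    n_obs_ge = np.arange(1, s_sorted.size + 1)
    raw = (n_null_ge / n_perm) / n_obs_ge
    # q-value: best FDR over all thresholds that still include the gene
    fdr = np.minimum.accumulate(raw[::-1])[::-1]
    fdr = np.clip(fdr, 0.0, 1.0)
    out = np.empty_like(fdr)
    out[order] = fdr
    return out


def permutation_calls(
    tc_ww: ExpressionTimeCourse,
    tc_wl: ExpressionTimeCourse,
    basis: EigengeneBasis,
    n_perm: int = 100,
    fdr_target: float = 0.05,
    seed: int = 0,
    profile: str = "per_replicate",
) -> pd.DataFrame:
    """Call WL-responsive genes against a treatment-label permutation null.

    Null scores come from reassigning the six replicate time courses to two
    pseudo-treatments of three (the same reassignment applied to every
    gene).  The identity assignment and its complement are excluded: they
    reproduce the observed labelling and carry no null information.  The
    empirical FDR per score threshold is the permutation-mean null
    exceedance count over the observed exceedance count; a gene is called at
    FDR <= ``fdr_target``.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    scores = pattern_change_scores(tc_ww, tc_wl, basis, profile=profile)

    c_ww, c_wl = _course_stack(tc_ww), _course_stack(tc_wl)
    samples = np.concatenate([c_ww, c_wl], axis=1)
    corr = np.concatenate(
        [_eigengene_correlations(c_ww, basis), _eigengene_correlations(c_wl, basis)],
        axis=1,
    )
    basis_z = _zscore_profiles(basis.profiles.to_numpy())

    n_courses = 2 * len(REPLICATES)
    identity = frozenset(range(len(REPLICATES)))
    pool = [
        c
        for c in combinations(range(n_courses), len(REPLICATES))
        if frozenset(c) != identity
        and frozenset(range(n_courses)) - frozenset(c) != identity
    ]
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(pool), size=n_perm)

    null_kme, null_med = [], []
    for pi in picks:
        sel = np.zeros(n_courses, dtype=bool)
        sel[list(pool[pi])] = True
        k, m = _scores_for_assignment(corr, samples, sel, profile, basis_z)
        null_kme.append(k)
        null_med.append(m)
    null_kme = np.concatenate(null_kme)
    null_med = np.concatenate(null_med)

    fdr_kme = _pooled_fdr(scores["kME"].to_numpy(), null_kme, n_perm)
    fdr_med = _pooled_fdr(scores["Med"].to_numpy(), null_med, n_perm)
    out = scores.copy()
    out["fdr_kME"] = fdr_kme
    out["fdr_Med"] = fdr_med
    out["called_kME"] = (fdr_kme <= fdr_target) & ~out["flat_profile"]
    out["called_Med"] = fdr_med <= fdr_target
    return out


# --------------------------------------------------------------------------
# single-timepoint validation and accession QC


def validate_with_pointwise_tests(
    tc_ww: ExpressionTimeCourse,
    tc_wl: ExpressionTimeCourse,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch tests per gene x ZT with per-ZT Benjamini-Hochberg adjustment.

    Returns a frame with raw and adjusted p-values per ZT and an
    ``any_zt_significant`` flag.  ZTs with fewer than two observed
    replicates on either side are skipped (NaN p, flagged).
    """
    if not tc_ww.genes.equals(tc_wl.genes):
        raise ValueError("WW and WL courses must share one gene index")
    out = pd.DataFrame(index=tc_ww.genes)
    any_sig = np.zeros(len(out), dtype=bool)
    skipped = np.zeros(len(out), dtype=bool)
    for zt in ZT_GRID:
        a = tc_ww.data[zt].to_numpy()
        b = tc_wl.data[zt].to_numpy()
        enough = (np.sum(~np.isnan(a), axis=1) >= 2) & (np.sum(~np.isnan(b), axis=1) >= 2)
        p = np.full(len(out), np.nan)
        if enough.any():
            with np.errstate(invalid="ignore", divide="ignore"):
                res = stats.ttest_ind(
                    a[enough], b[enough], axis=1, equal_var=False, nan_policy="omit"
                )
            p[enough] = res.pvalue
        padj = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            padj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        out[f"p_ZT{zt}"] = p
        out[f"padj_ZT{zt}"] = padj
        any_sig |= np.where(np.isfinite(padj), padj <= alpha, False)
        skipped |= ~enough
    out["any_zt_significant"] = any_sig
    out["skipped_zt"] = skipped
    return out


def jaccard_overlap(set_a, set_b) -> float:
    """Jaccard index of two gene sets (1.0 when both are empty)."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def drop_low_signal_accessions(calls_by_accession: dict, min_kme_genes: int = 50):
    """Drop accessions with fewer than ``min_kme_genes`` kME calls.

    ``calls_by_accession`` maps accession to either a call table (with a
    ``called_kME`` column) or an integer count.  Returns
    ``(retained_accessions, log_frame)``.
    """
    rows = []
    retained = []
    for acc, calls in calls_by_accession.items():
        n = int(calls) if np.isscalar(calls) else int(calls["called_kME"].sum())
        dropped = n < min_kme_genes
        rows.append({"accession": acc, "n_kME_calls": n, "dropped": dropped})
        if not dropped:
            retained.append(acc)
    return retained, pd.DataFrame(rows)
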