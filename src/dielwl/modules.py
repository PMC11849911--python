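"""Global response-score co-expression modules.

The response score of a gene is the WL - WW difference of replicate-mean
log2 expression at each ZT; concatenating these 4-point response profiles
over all accessions gives one feature vector per gene (length
4 x n_accessions).  Genes are z-scored and connected by a signed weighted
adjacency ``a_ij = ((1 + r_ij)/2)^beta``; average-linkage clustering of the
dissimilarity ``1 - a_ij`` with a static cut yields modules, each
summarized by a sign-oriented eigengene (first principal component).
Modules whose eigengenes correlate above a merge threshold are fused;
clusters below the minimum size land in the null module ``M0``.

A module can mix accessions that respond in opposite directions at the
same time of day; :func:`split_opposing_modules` partitions such a module's
accessions by the sign of their projection onto the eigengene so enrichment
can be read per direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from dielwl.containers import ZT_GRID, ExpressionTimeCourse

__all__ = [
    "compute_response_scores",
    "build_network",
    "detect_modules",
    "module_eigengene",
    "split_opposing_modules",
    "ResponseModule",
]


def compute_response_scores(courses: dict) -> pd.DataFrame:
    """Per-gene WL - WW replicate-mean log2 difference at each ZT.

    ``courses`` maps ``(accession, treatment)`` to an
    :class:`ExpressionTimeCourse`.  Accessions missing either treatment are
    excluded and reported via ``result.attrs['excluded_accessions']``.
    Result columns are a (accession, zt) MultiIndex.
    """
    accs = sorted({a for a, _ in courses})
    blocks, used, excluded = [], [], []
    for acc in accs:
        ww, wl = courses.get((acc, "WW")), courses.get((acc, "WL"))
        if ww is None or wl is None:
            excluded.append(acc)
            continue
        if not ww.genes.equals(wl.genes):
            raise ValueError(f"gene sets differ between treatments for {acc}")
        diff = wl.replicate_mean() - ww.replicate_mean()
        diff.columns = pd.MultiIndex.from_product(
            [[acc], list(ZT_GRID)], names=["accession", "zt"]
        )
        blocks.append(diff)
        used.append(acc)
    if not blocks:
        raise ValueError("no accession has both treatments")
    out = pd.concat(blocks, axis=1)
    out.attrs["excluded_accessions"] = excluded
    return out


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[~np.isfinite(z)] = 0.0
    return z


def build_network(scores: pd.DataFrame, beta: float = 6.0):
    """Signed weighted gene-gene dissimilarity from response scores.

    Genes are z-scored across their concatenated (accession x ZT) vectors;
    the signed adjacency is ``((1 + r)/2)^beta`` and the returned
    dissimilarity is its complement (symmetric, zero diagonal).  Genes with
    zero-variance vectors are removed first and listed in
    ``diss.attrs['removed_genes']``.
    """
    x = scores.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    removed = scores.index[~keep].tolist()
    z = _zscore_rows(x[keep])
    r = np.clip(z @ z.T / z.shape[1], -1.0, 1.0)
    adj = ((1.0 + r) / 2.0) ** beta
    diss = 1.0 - adj
    np.fill_diagonal(diss, 0.0)
    out = pd.DataFrame(diss, index=scores.index[keep], columns=scores.index[keep])
    out.attrs["removed_genes"] = removed
    return out


@dataclass
class ResponseModule:
    """One response module: gene set, eigengene and mean accession profiles."""

    module_id: str
    genes: list
    eigengene: pd.DataFrame = field(repr=False)  # accession x ZT
    mean_profiles: pd.DataFrame = field(repr=False)  # accession x ZT mean response
    explained_variance: float = float("nan")
    accessions: list | None = None  # restricted set after opposing-response splits


def module_eigengene(scores: pd.DataFrame) -> tuple:
    """Sign-oriented first PC of a module's z-scored score matrix.

    Returns ``(eigengene_frame, explained_variance, mean_profile_frame)``
    with the eigengene reshaped to accession x ZT and oriented so its
    correlation with the module's mean profile is non-negative.  A
    single-gene module's eigengene is that gene's z-scored profile.
    """
    if scores.shape[0] == 0:
        raise ValueError("empty module")
    z = _zscore_rows(scores.to_numpy(dtype=float))
    mean_vec = z.mean(axis=0)
    if z.shape[0] == 1:
        v, ev = z[0], 1.0
    else:
        # no column centering: rows are z-scored and the shared shape is
        # exactly what the eigengene must capture
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
        ev = float(s[0] ** 2 / np.sum(s**2)) if s.sum() > 0 else 1.0
    if np.dot(v, mean_vec) < 0:
        v = -v
    cols = scores.columns
    accs = list(dict.fromkeys(cols.get_level_values("accession")))
    eig = pd.DataFrame(
        v.reshape(len(accs), len(ZT_GRID)), index=accs, columns=list(ZT_GRID)
    )
    mean_prof = pd.DataFrame(
        mean_vec.reshape(len(accs), len(ZT_GRID)), index=accs, columns=list(ZT_GRID)
    )
    return eig, ev, mean_prof


def detect_modules(
    diss: pd.DataFrame,
    scores: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.6,
    merge_threshold: float = 0.75,
) -> tuple:
    """Average-linkage modules from a dissimilarity with a static tree cut.

    Clusters below ``min_module_size`` collapse into the null module
    ``M0``; modules whose eigengene vectors correlate at or above
    ``merge_threshold`` are merged iteratively.  Labels are assigned by
    decreasing module size (``M1`` largest).  Returns
    ``(modules, assignment)`` where ``assignment`` maps gene -> module id
    (including ``M0``).
    """
    genes = diss.index
    if len(genes) == 0:
        raise ValueError("empty dissimilarity")
    d = diss.to_numpy(dtype=float)
    if len(genes) == 1 or np.allclose(d, 0.0):
        labels = np.ones(len(genes), dtype=int)
    else:
        labels = fcluster(average(squareform(d, checks=False)), cut_height, "distance")

    members = {}
    for lab in np.unique(labels):
        idx = genes[labels == lab]
        key = lab if len(idx) >= min_module_size else 0
        members.setdefault(key, []).extend(idx)

    sub_scores = {
        lab: scores.loc[idx] for lab, idx in members.items() if lab != 0
    }
    # iterative eigengene merging
    merged = True
    while merged and len(sub_scores) > 1:
        merged = False
        labs = list(sub_scores)
        eigs = {}
        for lab in labs:
            eig, _, _ = module_eigengene(sub_scores[lab])
            eigs[lab] = eig.to_numpy().ravel()
        best = None
        for i, la in enumerate(labs):
            for lb in labs[i + 1 :]:
                r = np.corrcoef(eigs[la], eigs[lb])[0, 1]
                if r >= merge_threshold and (best is None or r > best[0]):
                    best = (r, la, lb)
        if best is not None:
            _, la, lb = best
            sub_scores[la] = pd.concat([sub_scores[la], sub_scores.pop(lb)])
            merged = True

    ordered = sorted(sub_scores.values(), key=len, reverse=True)
    modules = []
    assignment = pd.Series("M0", index=scores.index, name="module")
    for k, sc in enumerate(ordered, start=1):
        eig, ev, mean_prof = module_eigengene(sc)
        mid = f"M{k}"
        modules.append(
            ResponseModule(mid, list(sc.index), eig, mean_prof, ev)
        )
        assignment.loc[sc.index] = mid
    return modules, assignment


def split_opposing_modules(
    module: ResponseModule,
    scores: pd.DataFrame,
    opposing_threshold: float = 0.5,
) -> list:
    """Split a module whose accessions respond in opposite directions.

    If any pair of per-accession mean response profiles correlates below
    ``-opposing_threshold``, the accessions are partitioned by the sign of
    the projection of their 4-point mean profile onto the leading principal
    direction of the accession-profile matrix (a shared reference shape);
    one sub-module per sign is emitted with the same gene set but a
    restricted accession annotation.  Otherwise the module is returned
    unchanged.
    """
    profs = module.mean_profiles
    accs = list(profs.index)
    if len(accs) < 2:
        return [module]
    p = profs.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(p)
    opposing = np.any(r[np.triu_indices(len(accs), 1)] < -opposing_threshold)
    if not opposing:
        return [module]
    _, _, vt = np.linalg.svd(p, full_matrices=False)
    u = vt[0]
    if np.dot(p.sum(axis=0), u) < 0:
        u = -u
    proj = pd.Series(p @ u, index=accs)
    eig = module.eigengene
    pos = [a for a in accs if proj[a] >= 0]
    neg = [a for a in accs if proj[a] < 0]
    out = []
    for suffix, group in (("a", pos), ("b", neg)):
        if not group:
            continue
        out.append(
            ResponseModule(
                f"{module.module_id}{suffix}",
                module.genes,
                eig.loc[group],
                profs.loc[group],
                module.explained_variance,
                accessions=group,
            )
        )
    return out
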