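"""Term over-representation analysis with ortholog mapping and rollups.

Enrichment of a study gene set against a background uses the one-sided
hypergeometric upper tail (equivalent to a one-sided Fisher exact test on
the 2x2 table), Benjamini-Hochberg adjusted across terms within one
analysis.  Annotations are plain two-column term->gene tables; an optional
term->descriptor table groups results under broad parent-like labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "map_to_orthologs",
    "hypergeometric_enrichment",
    "rollup_broad_descriptors",
]


def map_to_orthologs(genes, hmap: pd.DataFrame, column: str = "arabidopsis_ortholog"):
    """De-duplicated ortholog ids for a gene set, plus the unmapped genes.

    Homoeologs sharing one ortholog collapse to a single id.  Returns
    ``(ortholog_ids, unmapped_genes)`` as sorted lists.
    """
    if hmap.empty:
        raise ValueError("empty homoeolog map")
    lookup = hmap.set_index("gene_id")[column]
    mapped, unmapped = set(), []
    for g in genes:
        o = lookup.get(g)
        if o is None or (isinstance(o, float) and np.isnan(o)):
            unmapped.append(g)
        else:
            mapped.add(o)
    return sorted(mapped), sorted(unmapped)


def hypergeometric_enrichment(
    study: set,
    background: set,
    annotations: pd.DataFrame,
    descriptors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``study`` within ``background``.

    ``annotations`` is a two-column frame (term, gene).  Terms with no
    annotated background gene are skipped (listed in
    ``result.attrs['skipped_terms']``).  The p-value for a term annotating
    ``K`` of ``N`` background genes, ``k`` of ``n`` study genes, is
    ``P[X >= k]`` for ``X ~ Hypergeom(N, K, n)``; BH adjustment runs across
    the reported terms.
    """
    study, background = set(study), set(background)
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    n_bg, n_st = len(background), len(study)
    rows, skipped = [], []
    for term, sub in annotations.groupby(annotations.columns[0]):
        annotated = set(sub[annotations.columns[1]]) & background
        k_bg = len(annotated)
        if k_bg == 0:
            skipped.append(term)
            continue
        k_st = len(annotated & study)
        p = float(stats.hypergeom.sf(k_st - 1, n_bg, k_bg, n_st))
        rows.append(
            {
                "term": term,
                "study_count": k_st,
                "study_size": n_st,
                "background_count": k_bg,
                "background_size": n_bg,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term", "study_count", "study_size",
            "background_count", "background_size", "p_value",
        ],
    )
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    if descriptors is not None:
        dmap = descriptors.set_index(descriptors.columns[0])[descriptors.columns[1]]
        out["descriptor"] = out["term"].map(dmap).fillna("unassigned")
    out.attrs["skipped_terms"] = skipped
    return out.sort_values("p_value", ignore_index=True)


def rollup_broad_descriptors(
    results: pd.DataFrame,
    descriptors: pd.DataFrame | None = None,
    significant_only: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group enrichment results under broad descriptors.

    ``results`` may carry extra identifier columns (e.g. ``accession``,
    ``module``) which are preserved so the rollup doubles as a
    descriptor x (accession, module) presence table.  Terms without a
    descriptor fall to ``"unassigned"``.  With ``significant_only`` the view
    is restricted to descriptors with at least one term at
    ``p_adjusted <= alpha``.
    """
    df = results.copy()
    if "descriptor" not in df.columns:
        if descriptors is None:
            raise ValueError("need a descriptor column or a descriptor map")
        dmap = descriptors.set_index(descriptors.columns[0])[descriptors.columns[1]]
        df["descriptor"] = df["term"].map(dmap).fillna("unassigned")
    df["descriptor"] = df["descriptor"].fillna("unassigned")
    extra = [c for c in ("accession", "module") if c in df.columns]
    if significant_only:
        ok = df.groupby(["descriptor"] + extra)["p_adjusted"].transform("min") <= alpha
        df = df[ok]
    grouped = (
        df.groupby(["descriptor"] + extra)
        .agg(
            n_terms=("term", "nunique"),
            terms=("term", lambda t: ",".join(sorted(set(t)))),
            best_p=("p_value", "min"),
            best_p_adjusted=("p_adjusted", "min"),
        )
        .reset_index()
    )
    return grouped.sort_values("best_p", ignore_index=True)
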