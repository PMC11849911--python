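"""Readers, writers and run configuration.

All formats are headered plain text: expression matrices as TSV with gene
ids in the first column and one column per sample, sample metadata as TSV
(sample_id, accession, treatment, zt, replicate), growth tables as CSV
(plant_id, accession, treatment, day, area_cm2), homoeolog maps and
annotation tables as TSV, metabolite feature tables as long-format CSV.
Readers validate shapes and name offending samples in their errors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dielwl.containers import ZT_GRID, REPLICATES, ExpressionTimeCourse, expression_columns

__all__ = [
    "read_growth_csv",
    "read_expression",
    "write_expression",
    "read_homoeolog_map",
    "read_metab_csv",
    "read_annotations",
    "PipelineConfig",
]


def read_growth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"plant_id", "accession", "treatment", "day", "area_cm2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth table {path}: missing columns {sorted(missing)}")
    if (df["day"].astype(float) < 0).any():
        raise ValueError(f"growth table {path}: negative days")
    return df


def _sample_name(accession, treatment, zt, rep) -> str:
    return f"{accession}_{treatment}_ZT{zt}_r{rep}"


def write_expression(courses: dict, matrix_path, meta_path) -> None:
    """Write a courses dict to one expression TSV plus a metadata TSV."""
    blocks, meta = [], []
    for (acc, treat), tc in courses.items():
        df = tc.data.copy()
        df.columns = [
            _sample_name(acc, treat, zt, rep) for zt, rep in df.columns
        ]
        blocks.append(df)
        for zt, rep in tc.data.columns:
            meta.append(
                {
                    "sample_id": _sample_name(acc, treat, zt, rep),
                    "accession": acc,
                    "treatment": treat,
                    "zt": zt,
                    "replicate": rep,
                }
            )
    mat = pd.concat(blocks, axis=1)
    mat.index.name = "gene_id"
    mat.to_csv(matrix_path, sep="\t", na_rep="NA")
    pd.DataFrame(meta).to_csv(meta_path, sep="\t", index=False)


def read_expression(matrix_path, meta_path) -> dict:
    """Read an expression matrix + metadata into per-(accession, treatment)
    time courses.

    Validates the sample grid: every matrix column must appear in the
    metadata, ZTs must lie on {1, 7, 13, 19}, replicates on {1, 2, 3}, and
    gene ids must be unique.  Missing values (``NA``) become the
    missing-replicate mask.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if mat.index.duplicated().any():
        dups = mat.index[mat.index.duplicated()].tolist()[:5]
        raise ValueError(f"duplicate gene ids in {matrix_path}, e.g. {dups}")
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"sample_id", "accession", "treatment", "zt", "replicate"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata {meta_path}: missing columns {sorted(missing_cols)}")
    meta = meta.set_index("sample_id")
    unknown = [s for s in mat.columns if s not in meta.index]
    if unknown:
        raise ValueError(
            f"samples present in matrix but absent from metadata: {unknown[:5]}"
        )
    bad_zt = sorted(set(meta["zt"]) - set(ZT_GRID))
    if bad_zt:
        raise ValueError(f"off-grid ZT values {bad_zt}; expected {ZT_GRID}")
    bad_rep = sorted(set(meta["replicate"]) - set(REPLICATES))
    if bad_rep:
        raise ValueError(f"off-grid replicates {bad_rep}; expected {REPLICATES}")

    courses = {}
    cols = expression_columns()
    for (acc, treat), sub in meta.loc[list(mat.columns)].groupby(
        ["accession", "treatment"]
    ):
        df = pd.DataFrame(np.nan, index=mat.index, columns=cols)
        for sample_id, row in sub.iterrows():
            df[(row["zt"], row["replicate"])] = mat[sample_id]
        df.index.name = "gene_id"
        courses[(acc, treat)] = ExpressionTimeCourse(acc, treat, df)
    return courses


def read_homoeolog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "subgenome", "ortholog_group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"homoeolog map {path}: missing columns {sorted(missing)}")
    return df


def read_metab_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"feature", "mz", "rt", "treatment", "zt", "area", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metabolite table {path}: missing columns {sorted(missing)}")
    return df


def read_annotations(path) -> pd.DataFrame:
    """Two-column (term, gene) TSV; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"annotation table {path} needs at least 2 columns")
    return df.iloc[:, :2].set_axis(["term", "gene_id"], axis=1)


# --------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """End-to-end run configuration; round-trips losslessly through YAML."""

    out_dir: str = "dielwl_out"
    seed: int = 0
    # inputs (None -> stage skipped or simulated)
    expression_matrix: str | None = None
    expression_meta: str | None = None
    homoeolog_map: str | None = None
    growth_table: str | None = None
    metab_table: str | None = None
    annotations: str | None = None
    descriptors: str | None = None
    simulate: bool = True
    # module defaults
    n_perm: int = 100
    fdr_target: float = 0.05
    min_kme_genes: int = 50
    beta: float = 6.0
    min_module_size: int = 30
    cut_height: float = 0.6
    merge_threshold: float = 0.75
    support_threshold: float = 0.95
    chains: int = 2
    warmup: int = 1000
    draws: int = 1000
    background_level: float = 5e3
    region: tuple = (3.2, 6.9, 600.0, 1200.0)
    sim_ortholog_groups: int = 60
    sim_accessions: tuple = ("Ab", "Mu", "St", "Yu")
    sim_plants_per_group: int = 8

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["region"] = list(d["region"])
        d["sim_accessions"] = list(d["sim_accessions"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "region" in d:
            d["region"] = tuple(d["region"])
        if "sim_accessions" in d:
            d["sim_accessions"] = tuple(d["sim_accessions"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
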