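"""End-to-end pipeline driver.

Runs (optionally) the synthetic generators, then preprocessing,
differential-pattern calling per accession, phase/subgenome analysis,
response-score modules, enrichment (when annotations are supplied),
metabolomics (when a feature table is present) and the growth fit (when a
growth table is present).  Every stage writes its artifacts under the
output directory; a manifest JSON records version, seeds, parameters and
input checksums.  Stage failures raise :class:`PipelineError` naming the
stage; artifacts from completed stages are retained.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

import dielwl
from dielwl import diel, enrich, metab as metab_mod, modules as modules_mod, phase as phase_mod
from dielwl import growth as growth_mod
from dielwl import synthetic
from dielwl.io import (
    PipelineConfig,
    read_expression,
    read_growth_csv,
    read_homoeolog_map,
    read_metab_csv,
    read_annotations,
    write_expression,
    write_json,
)

log = logging.getLogger("dielwl")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": dielwl.__version__,
        "seed": config.seed,
        "parameters": {
            "n_perm": config.n_perm,
            "fdr_target": config.fdr_target,
            "beta": config.beta,
            "min_module_size": config.min_module_size,
            "cut_height": config.cut_height,
            "chains": config.chains,
            "draws": config.draws,
        },
        "inputs": {},
        "stages": [],
    }

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("inputs")
        if config.simulate and config.expression_matrix is None:
            design = synthetic.ExpressionSimDesign(
                n_ortholog_groups=config.sim_ortholog_groups,
                accessions=tuple(config.sim_accessions),
                seed=config.seed,
            )
            courses, hmap, truth = synthetic.gen_expression_data(design)
            write_expression(
                courses, out / "expression.tsv", out / "expression_meta.tsv"
            )
            hmap.to_csv(out / "homoeolog_map.tsv", sep="\t", index=False)
            write_json(truth, out / "expression_truth.json")
        else:
            courses = read_expression(config.expression_matrix, config.expression_meta)
            hmap = read_homoeolog_map(config.homoeolog_map)
            manifest["inputs"]["expression_matrix"] = _checksum(config.expression_matrix)
    except Exception as e:  # noqa: BLE001 - stage-labelled re-raise
        raise PipelineError("inputs", e) from e

    accessions = sorted({a for a, _ in courses})
    try:
        stage("preprocess")
        processed = {}
        for acc in accessions:
            pair = [courses[(acc, "WW")], courses[(acc, "WL")]]
            filtered, report = diel.filter_genes(pair)
            imputed = []
            unusable = set()
            for tc in filtered:
                tc_i, bad = diel.impute_course(tc)
                imputed.append(tc_i)
                unusable.update(bad)
            if unusable:
                keep = imputed[0].genes.difference(pd.Index(sorted(unusable)))
                imputed = [
                    type(tc)(tc.accession, tc.treatment, tc.data.loc[keep])
                    for tc in imputed
                ]
            processed[acc] = tuple(imputed)
            log.info("%s: %d genes after QC", acc, len(imputed[0].genes))
    except Exception as e:
        raise PipelineError("preprocess", e) from e

    try:
        stage("dipattern")
        calls = {}
        for acc, (ww, wl) in processed.items():
            basis = diel.build_eigengene_basis([ww, wl])
            calls[acc] = diel.permutation_calls(
                ww, wl, basis,
                n_perm=config.n_perm,
                fdr_target=config.fdr_target,
                seed=config.seed,
            )
            calls[acc].to_csv(out / f"calls_{acc}.tsv", sep="\t")
        retained, qc_log = diel.drop_low_signal_accessions(
            calls, min_kme_genes=config.min_kme_genes
        )
        qc_log.to_csv(out / "accession_qc.tsv", sep="\t", index=False)
    except Exception as e:
        raise PipelineError("dipattern", e) from e

    try:
        stage("phase")
        phase_rows = []
        call_sets = {}
        for acc in retained:
            ww, wl = processed[acc]
            c = calls[acc]
            wl_genes = c.index[c["called_kME"] | c["called_Med"]]
            call_sets[acc] = set(wl_genes)
            pt = phase_mod.phase_table(ww, wl, genes=wl_genes)
            props = phase_mod.subgenome_phase_proportions(pt, hmap, accession=acc)
            phase_rows.append(props)
            pt.to_csv(out / f"phase_{acc}.tsv", sep="\t")
        if phase_rows:
            pd.concat(phase_rows).to_csv(
                out / "phase_proportions.tsv", sep="\t", index=False
            )
        if len(call_sets) >= 2:
            phase_mod.gene_sharing_distribution(call_sets, hmap).to_csv(
                out / "gene_sharing.tsv", sep="\t", index=False
            )
        bias = phase_mod.subgenome_expression_bias(
            [tc for acc in retained for tc in processed[acc]], hmap, seed=config.seed
        )
        bias.to_csv(out / "subgenome_bias.tsv", sep="\t", index=False)
    except Exception as e:
        raise PipelineError("phase", e) from e

    try:
        stage("modules")
        flat_courses = {
            (acc, tc.treatment): tc for acc in retained for tc in processed[acc]
        }
        scores = modules_mod.compute_response_scores(flat_courses)
        diss = modules_mod.build_network(scores, beta=config.beta)
        mods, assignment = modules_mod.detect_modules(
            diss,
            scores.loc[diss.index],
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            merge_threshold=config.merge_threshold,
        )
        assignment.to_csv(out / "module_assignment.tsv", sep="\t")
        eig_rows = []
        for m in mods:
            e = m.eigengene.reset_index(names="accession").melt(
                id_vars="accession", var_name="zt", value_name="value"
            )
            e.insert(0, "module", m.module_id)
            eig_rows.append(e)
        if eig_rows:
            pd.concat(eig_rows).to_csv(out / "module_eigengenes.tsv", sep="\t", index=False)
    except Exception as e:
        raise PipelineError("modules", e) from e

    if config.annotations:
        try:
            stage("enrich")
            annot = read_annotations(config.annotations)
            desc = (
                pd.read_csv(config.descriptors, sep="\t")
                if config.descriptors
                else None
            )
            background = set(assignment.index)
            results = []
            for m in mods:
                res = enrich.hypergeometric_enrichment(
                    set(m.genes) & background, background, annot, descriptors=desc
                )
                res.insert(0, "module", m.module_id)
                results.append(res)
            enr = pd.concat(results, ignore_index=True)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            if desc is not None:
                enrich.rollup_broad_descriptors(enr).to_csv(
                    out / "enrichment_rollup.tsv", sep="\t", index=False
                )
        except Exception as e:
            raise PipelineError("enrich", e) from e

    if config.metab_table or config.simulate:
        try:
            stage("metab")
            if config.metab_table:
                table = read_metab_csv(config.metab_table)
                manifest["inputs"]["metab_table"] = _checksum(config.metab_table)
            else:
                table, m_truth = synthetic.gen_metabolite_data(
                    synthetic.MetabSimDesign(seed=config.seed)
                )
                write_json(m_truth, out / "metab_truth.json")
            limits = metab_mod.LimitSpec(config.background_level)
            normalized, factors = metab_mod.normalize_region(table, config.region)
            flagged = metab_mod.censor(normalized, limits)
            flagged.to_csv(out / "metab_normalized.csv", index=False)
            factors.to_csv(out / "metab_factors.csv")
            averaged = metab_mod.censor(
                metab_mod.average_injections(flagged), limits
            )
            stats = metab_mod.diel_treatment_stats_table(averaged)
            stats.to_csv(out / "metab_effects.tsv", sep="\t", index=False)
        except Exception as e:
            raise PipelineError("metab", e) from e

    if config.growth_table or config.simulate:
        try:
            stage("growth")
            if config.growth_table:
                gtable = read_growth_csv(config.growth_table)
                manifest["inputs"]["growth_table"] = _checksum(config.growth_table)
            else:
                gtable, g_truth = synthetic.gen_growth_data(
                    synthetic.GrowthSimDesign(
                        n_plants_per_group=config.sim_plants_per_group,
                        seed=config.seed,
                    )
                )
                write_json(g_truth, out / "growth_truth.json")
                gtable.to_csv(out / "growth_data.csv", index=False)
            summaries, hyps = [], []
            for acc, sub in gtable.groupby("accession"):
                post = growth_mod.fit_growth_model(
                    sub,
                    chains=config.chains,
                    warmup=config.warmup,
                    draws=config.draws,
                    seed=config.seed,
                )
                s = post.summary()
                s.insert(0, "accession", acc)
                summaries.append(s)
                h = growth_mod.hypothesis_table(
                    post, support_threshold=config.support_threshold
                )
                h.insert(0, "accession", acc)
                hyps.append(h)
                ribbon = growth_mod.posterior_predictive(
                    post, sorted(sub["day"].unique()), seed=config.seed
                )
                ribbon.insert(0, "accession", acc)
                ribbon.to_csv(out / f"growth_ribbon_{acc}.tsv", sep="\t", index=False)
            pd.concat(summaries).to_csv(out / "growth_params.tsv", sep="\t", index=False)
            pd.concat(hyps).to_csv(out / "growth_hypotheses.tsv", sep="\t", index=False)
        except Exception as e:
            raise PipelineError("growth", e) from e

    write_json(manifest, out / "manifest.json")
    return out
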