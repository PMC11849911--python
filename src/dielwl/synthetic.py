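"""Synthetic growth, expression, metabolite and response-score datasets.

Every generator takes a frozen design, draws from a seeded
``numpy.random.Generator`` (one independent stream per dataset kind, spawned
from the design seed) and returns both the dataset and a *truth record*
holding every random choice made: responsive genes and their planted shifts,
replicate dropouts, per-run scale factors, effect labels.  Identical designs
yield bit-identical outputs.

The defaults mirror the study conditions the downstream stages assume:
16 plants per treatment group observed daily for 27 days for growth; 14
accessions x {WW, WL} x ZT {1, 7, 13, 19} x 3 replicates for expression
with water-limitation responses restricted to phase shifts in
{+/-6, +/-12} h and/or median shifts; metabolite features at ZT {4, 12, 20}
with technical-injection scale factors and abundances that can fall below
the 2x-background limit of detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dielwl.containers import ZT_GRID, REPLICATES, ExpressionTimeCourse, expression_columns
from dielwl.growth import GompertzParams, VarianceParams, gompertz_mean, variance_profile

#: the 14 accessions retained in the reference experiment
DEFAULT_ACCESSIONS = (
    "Ab", "Al", "Av", "Br", "Ca", "Da", "DH12", "DH20",
    "Gr", "Mu", "Ne", "Se", "St", "Yu",
)

METAB_ZTS = (4, 12, 20)


def _spawn(seed: int, kind: str) -> np.random.Generator:
    """One RNG stream per dataset kind, all derived from the top-level seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(
        {"growth": 1, "expression": 2, "metab": 3, "response": 4}[kind]
    )[-1])


# --------------------------------------------------------------------------
# growth


@dataclass(frozen=True)
class GrowthSimDesign:
    """Design for Gompertz growth series with heteroskedastic Student-t noise."""

    n_plants_per_group: int = 16
    days: tuple = tuple(range(27))
    params: dict = field(
        default_factory=lambda: {
            "WW": GompertzParams(130.0, 15.0, 0.25),
            "WL": GompertzParams(65.0, 14.0, 0.25),
        }
    )
    variance: dict = field(
        default_factory=lambda: {
            "WW": VarianceParams(20.0, 10.0, 3.0),
            "WL": VarianceParams(20.0, 10.0, 3.0),
        }
    )
    noise_df: float = 10.0
    accession: str = "Sim"
    seed: int = 0

    def __post_init__(self):
        if self.n_plants_per_group < 2:
            raise ValueError("need at least 2 plants per group")
        d = np.asarray(self.days, float)
        if d.size < 2 or np.any(np.diff(d) <= 0):
            raise ValueError("days must be strictly increasing")
        if self.noise_df < 1:
            raise ValueError("noise_df must be >= 1")
        if set(self.params) != set(self.variance):
            raise ValueError("params and variance must cover the same groups")


def gen_growth_data(design: GrowthSimDesign):
    """Simulate per-plant area series.

    Returns a tidy frame (plant_id, accession, treatment, day, area_cm2) and
    a truth record with all generative parameters.
    """
    rng = _spawn(design.seed, "growth")
    days = np.asarray(design.days, float)
    rows = []
    for treatment in design.params:
        p, v = design.params[treatment], design.variance[treatment]
        mu = gompertz_mean(days, p)
        sd = variance_profile(days, v)
        for i in range(design.n_plants_per_group):
            noise = sd * rng.standard_t(design.noise_df, size=days.size)
            areas = mu + noise
            for d, a in zip(days, areas):
                rows.append(
                    {
                        "plant_id": f"{design.accession}-{treatment}-{i + 1:02d}",
                        "accession": design.accession,
                        "treatment": treatment,
                        "day": d,
                        "area_cm2": a,
                    }
                )
    truth = {
        "params": {g: vars(p) for g, p in design.params.items()},
        "variance": {g: vars(v) for g, v in design.variance.items()},
        "noise_df": design.noise_df,
        "n_plants_per_group": design.n_plants_per_group,
        "seed": design.seed,
    }
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionSimDesign:
    """Design for cosinor diel expression with planted WL responses.

    Expression is additive on the log2 scale:
    ``baseline + log2(bnc_bias)[BnC only] + amplitude*cos(2*pi*(ZT-phase)/24)
    + N(0, noise_sd)``.  In each accession a fraction
    ``responsive_fraction`` of ortholog groups responds to water limitation;
    a random non-empty subset of the group's homoeologs receives the
    response, which is either a phase shift from ``phase_shift_menu``
    (positive = WL peaks earlier, always a multiple of 6 h so the discrete
    phase classifier has a recoverable truth) or, for a drawn shift of 0, a
    median shift of ``median_shift`` log2 units.
    """

    n_ortholog_groups: int = 100
    copy_probs: tuple = (0.6, 0.3, 0.1)  # P(1, 2, 3 copies) per subgenome
    accessions: tuple = DEFAULT_ACCESSIONS
    baseline_log2: float = 4.0
    baseline_sd: float = 1.0
    amplitude: float = 1.0
    bnc_bias: float = 1.1
    responsive_fraction: float = 0.1
    phase_shift_menu: tuple = (0, 6, -6, 12, -12)
    median_shift: float = 1.0
    noise_sd: float = 0.2
    replicate_dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.accessions:
            raise ValueError("accession list must be non-empty")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise ValueError("responsive_fraction must lie in [0, 1]")
        if self.bnc_bias <= 0:
            raise ValueError("bnc_bias must be positive")
        if not set(self.phase_shift_menu) <= {0, 6, -6, 12, -12}:
            raise ValueError("phase shifts must be multiples of 6 in [-12, 12]")
        if abs(sum(self.copy_probs) - 1.0) > 1e-9 or len(self.copy_probs) != 3:
            raise ValueError("copy_probs must be a length-3 distribution over 1..3")


def gen_expression_data(design: ExpressionSimDesign):
    """Simulate diel expression courses plus a homoeolog map and truth record.

    Returns ``(courses, hmap, truth)`` where ``courses`` maps
    ``(accession, treatment)`` to an :class:`ExpressionTimeCourse`, ``hmap``
    is the gene -> subgenome / ortholog-group table and ``truth`` lists every
    responsive gene per accession with its planted phase and median shift.
    """
    rng = _spawn(design.seed, "expression")
    zts = np.asarray(ZT_GRID, float)

    # gene roster: variable numbers of BnA/BnC copies per ortholog group
    genes = []
    for g in range(design.n_ortholog_groups):
        group = f"OG{g:04d}"
        at_ortholog = f"AT{g:05d}"
        for sub in ("BnA", "BnC"):
            n_copies = 1 + rng.choice(3, p=design.copy_probs)
            for c in range(n_copies):
                genes.append(
                    {
                        "gene_id": f"{sub}.{group}.c{c + 1}",
                        "subgenome": sub,
                        "ortholog_group": group,
                        "arabidopsis_ortholog": at_ortholog,
                    }
                )
    hmap = pd.DataFrame(genes)
    n_genes = len(hmap)
    gene_ids = hmap["gene_id"].to_numpy()

    base = design.baseline_log2 + design.baseline_sd * rng.standard_normal(n_genes)
    base = base + np.where(hmap["subgenome"] == "BnC", np.log2(design.bnc_bias), 0.0)
    phase = rng.choice(ZT_GRID, size=n_genes).astype(float)

    group_index = {g: np.flatnonzero(hmap["ortholog_group"] == g)
                   for g in hmap["ortholog_group"].unique()}

    cols = expression_columns()
    courses = {}
    responsive_records = []
    dropout_records = []
    for acc in design.accessions:
        # plant the WL response: per ortholog group, a random homoeolog subset
        phase_shift = np.zeros(n_genes)
        med_shift = np.zeros(n_genes)
        for group, idx in group_index.items():
            if rng.random() >= design.responsive_fraction:
                continue
            k = 1 + rng.integers(len(idx))
            members = rng.choice(idx, size=k, replace=False)
            shift = rng.choice(design.phase_shift_menu) if design.phase_shift_menu else 0
            for m in members:
                if shift == 0:
                    med_shift[m] = design.median_shift * rng.choice([-1.0, 1.0])
                else:
                    phase_shift[m] = shift
                responsive_records.append(
                    {
                        "accession": acc,
                        "gene_id": gene_ids[m],
                        "subgenome": hmap["subgenome"].iloc[m],
                        "ortholog_group": group,
                        "phase_shift": int(shift),
                        "median_shift": float(med_shift[m]),
                    }
                )
        for treatment in ("WW", "WL"):
            if treatment == "WW":
                ph, mshift = phase, np.zeros(n_genes)
            else:
                # positive planted shift = WL peaks earlier
                ph = np.mod(phase - phase_shift, 24.0)
                mshift = med_shift
            signal = base[:, None] + mshift[:, None] + design.amplitude * np.cos(
                2.0 * np.pi * (zts[None, :] - ph[:, None]) / 24.0
            )
            vals = np.repeat(signal, len(REPLICATES), axis=1)
            vals = vals + design.noise_sd * rng.standard_normal(vals.shape)
            df = pd.DataFrame(vals, index=gene_ids, columns=cols)
            if design.replicate_dropout_rate > 0:
                # at most one of three replicates removed per gene x ZT
                drop = rng.random((n_genes, len(ZT_GRID))) < design.replicate_dropout_rate
                which = rng.integers(len(REPLICATES), size=(n_genes, len(ZT_GRID)))
                for gi, zi in zip(*np.nonzero(drop)):
                    zt, rep = ZT_GRID[zi], REPLICATES[which[gi, zi]]
                    df.iloc[gi, df.columns.get_loc((zt, rep))] = np.nan
                    dropout_records.append(
                        {
                            "accession": acc,
                            "treatment": treatment,
                            "gene_id": gene_ids[gi],
                            "zt": int(zt),
                            "replicate": int(rep),
                        }
                    )
            df.index.name = "gene_id"
            courses[(acc, treatment)] = ExpressionTimeCourse(acc, treatment, df)

    truth = {
        "responsive": responsive_records,
        "dropouts": dropout_records,
        "phase": dict(zip(gene_ids, phase)),
        "seed": design.seed,
    }
    return courses, hmap, truth


# --------------------------------------------------------------------------
# metabolites


@dataclass(frozen=True)
class MetabSimDesign:
    """Design for targeted metabolite feature tables.

    Each biological sample is injected ``n_injections`` times; every
    injection run carries its own multiplicative scale factor (lognormal
    with sd ``run_scale_sd`` unless given explicitly).  A block of stable
    "region" features inside the representative negative-mode window anchors
    the region-sum normalization.  Features carry one of three planted
    effects on the log scale: none, a ZT main effect, or a treatment x ZT
    interaction (the effect is added to WL at the last ZT only).  A fraction
    ``nd_fraction`` of the assayed features sits below the 2x-background
    limit of detection by construction.
    """

    n_features: int = 20
    n_region_features: int = 20
    n_bio_reps: int = 5
    n_injections: int = 3
    accession: str = "Sim"
    treatments: tuple = ("WW", "WL")
    zts: tuple = METAB_ZTS
    background_level: float = 5e3
    base_log_height: float = np.log(5e5)
    base_sd: float = 1.0
    nd_fraction: float = 0.1
    effect_probs: tuple = (0.5, 0.25, 0.25)  # none / zt / interaction
    zt_effect: float = 1.0
    interaction_effect: float = 1.0
    noise_sd: float = 0.3
    region_noise_sd: float = 0.01  # region block sums many stable background ions
    run_scale_sd: float = 0.2
    run_scale_factors: tuple | None = None
    area_per_height: float = 20.0
    region: tuple = (3.2, 6.9, 600.0, 1200.0)  # rt_min, rt_max, mz_min, mz_max
    seed: int = 0

    def __post_init__(self):
        if self.background_level <= 0:
            raise ValueError("background_level must be positive")
        if self.run_scale_factors is not None and any(
            f <= 0 for f in self.run_scale_factors
        ):
            raise ValueError("run scale factors must be positive")


def gen_metabolite_data(design: MetabSimDesign):
    """Simulate a long-format metabolite feature table plus truth record."""
    rng = _spawn(design.seed, "metab")
    rt_min, rt_max, mz_min, mz_max = design.region

    feats = []
    n_nd = int(round(design.nd_fraction * design.n_features))
    for i in range(design.n_features):
        effect = ("none", "zt", "interaction")[rng.choice(3, p=design.effect_probs)]
        below = i < n_nd
        if below:
            # censored-by-construction features carry no effect so every
            # observation stays under the 2x-background detection limit
            effect = "none"
            base = np.log(0.3 * design.background_level)
        else:
            base = design.base_log_height + design.base_sd * rng.standard_normal()
        feats.append(
            {
                "feature": f"F{i + 1:03d}",
                "mz": float(rng.uniform(100.0, 550.0)),
                "rt": float(rng.uniform(0.5, 3.0)),
                "effect": effect,
                "base_log_height": base,
                "below_lod": below,
            }
        )
    for i in range(design.n_region_features):
        feats.append(
            {
                "feature": f"R{i + 1:03d}",
                "mz": float(rng.uniform(mz_min, mz_max)),
                "rt": float(rng.uniform(rt_min, rt_max)),
                "effect": "none",
                "base_log_height": design.base_log_height,
                "below_lod": False,
            }
        )
    feat_df = pd.DataFrame(feats)

    runs = [
        (t, z, r, j)
        for t in design.treatments
        for z in design.zts
        for r in range(1, design.n_bio_reps + 1)
        for j in range(1, design.n_injections + 1)
    ]
    if design.run_scale_factors is not None:
        if len(design.run_scale_factors) != len(runs):
            raise ValueError(
                f"need {len(runs)} run scale factors, got {len(design.run_scale_factors)}"
            )
        scales = np.asarray(design.run_scale_factors, float)
    else:
        scales = rng.lognormal(0.0, design.run_scale_sd, size=len(runs))

    last_zt = design.zts[-1]
    zt_rank = {z: k for k, z in enumerate(design.zts)}
    bio_noise = {}  # biological replicate effect shared across injections
    rows = []
    for (t, z, r, j), scale in zip(runs, scales):
        sample = f"{design.accession}_{t}_ZT{z}_b{r}"
        run_id = f"{sample}_i{j}"
        for _, f in feat_df.iterrows():
            eff = 0.0
            if f["effect"] == "zt":
                eff = design.zt_effect * zt_rank[z] / (len(design.zts) - 1)
            elif f["effect"] == "interaction" and t == "WL" and z == last_zt:
                eff = design.interaction_effect
            is_region = f["feature"].startswith("R")
            sd_bio = design.region_noise_sd if is_region else design.noise_sd
            sd_inj = design.region_noise_sd / 2.0 if is_region else 0.05
            key = (f["feature"], t, z, r)
            if key not in bio_noise:
                bio_noise[key] = sd_bio * rng.standard_normal()
            log_h = f["base_log_height"] + eff + bio_noise[key]
            log_h += sd_inj * rng.standard_normal()  # injection-level jitter
            height = float(np.exp(log_h) * scale)
            rows.append(
                {
                    "feature": f["feature"],
                    "mz": f["mz"],
                    "rt": f["rt"],
                    "accession": design.accession,
                    "treatment": t,
                    "zt": z,
                    "bio_replicate": r,
                    "injection": j,
                    "run_id": run_id,
                    "height": height,
                    "area": height * design.area_per_height,
                }
            )
    table = pd.DataFrame(rows)
    truth = {
        "effects": dict(zip(feat_df["feature"], feat_df["effect"])),
        "below_lod": feat_df.loc[feat_df["below_lod"], "feature"].tolist(),
        "run_scale_factors": dict(
            zip([f"{design.accession}_{t}_ZT{z}_b{r}_i{j}" for t, z, r, j in runs],
                scales.tolist())
        ),
        "seed": design.seed,
    }
    return table, truth


# --------------------------------------------------------------------------
# response-score archetypes (module-recovery benchmark)


@dataclass(frozen=True)
class ResponseScoreSimDesign:
    """Planted archetypal response patterns for module-recovery benchmarks.

    ``n_archetypes`` mutually orthogonal temporal archetypes over
    ``n_accessions x 4 ZTs`` coordinates; each of the ``genes_per_archetype``
    member genes is archetype + Gaussian noise scaled so the expected
    within-archetype gene-gene correlation equals ``within_correlation``.
    """

    n_archetypes: int = 11
    genes_per_archetype: int = 200
    n_accessions: int = 14
    within_correlation: float = 0.9
    accessions: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.within_correlation < 1.0:
            raise ValueError("within_correlation must lie in (0, 1)")
        n_coord = 4 * self.n_accessions
        if self.n_archetypes > n_coord:
            raise ValueError("more archetypes than coordinates")


def gen_response_scores(design: ResponseScoreSimDesign):
    """Simulate a response-score matrix with planted archetype labels.

    Returns ``(scores, truth)``: a gene x (accession, ZT) frame and a Series
    mapping each gene to its archetype label.
    """
    rng = _spawn(design.seed, "response")
    accs = (
        list(design.accessions)
        if design.accessions is not None
        else [f"Acc{i + 1:02d}" for i in range(design.n_accessions)]
    )
    n_coord = 4 * len(accs)
    q, _ = np.linalg.qr(rng.standard_normal((n_coord, design.n_archetypes)))
    arch = q.T  # orthonormal rows
    arch = arch - arch.mean(axis=1, keepdims=True)
    arch = arch / arch.std(axis=1, keepdims=True)

    sd = np.sqrt(1.0 / design.within_correlation - 1.0)
    blocks, labels = [], []
    for k in range(design.n_archetypes):
        g = arch[k][None, :] + sd * rng.standard_normal(
            (design.genes_per_archetype, n_coord)
        )
        blocks.append(g)
        labels += [f"P{k + 1:02d}"] * design.genes_per_archetype
    mat = np.vstack(blocks)
    gene_ids = [f"gene{i + 1:05d}" for i in range(mat.shape[0])]
    cols = pd.MultiIndex.from_product([accs, list(ZT_GRID)], names=["accession", "zt"])
    scores = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    truth = pd.Series(labels, index=scores.index, name="archetype")
    return scores, truth
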