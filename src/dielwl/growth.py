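"""Bayesian distributional Gompertz growth model for plant-area time series.

The mean model is a three-parameter Gompertz curve

.. math::

    \\mu(t) = A \\exp(-\\exp(-C (t - B)))

with asymptote ``A`` (cm^2), inflection time ``B`` (days) and rate ``C``
(1/day), so the curve passes through ``A/e`` exactly at ``t = B``.  The
observation noise is Student-t with shared degrees of freedom ``nu`` and a
time-varying scale following a logistic profile

.. math::

    \\sigma(t) = subA / (1 + \\exp(-subC (t - subB)))

which lets the spread of plant areas grow as the plants themselves grow.
Each accession x treatment group gets its own (A, B, C, subA, subB, subC);
``nu`` is shared across the groups of one fit.

Priors are median-parameterized lognormals, LogNormal(log(center), 0.25),
centered at 130/15/0.25 for A/B/C and 20/10/3 for subA/subB/subC, plus a
Gamma(shape=2, rate=0.1) prior on ``nu`` truncated at 1.  Sampling is
adaptive random-walk Metropolis on log-parameters, initialized at the MAP.

Posterior hypothesis tests compare a parameter between the well-watered (WW)
and water-limited (WL) groups, e.g. "the WW asymptote is at least 50% larger
than the WL asymptote", reporting the posterior probability of the margin
being exceeded and the posterior-median percent difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "GompertzParams",
    "VarianceParams",
    "PriorSpec",
    "PosteriorDraws",
    "HypothesisResult",
    "gompertz_mean",
    "variance_profile",
    "fit_growth_model",
    "test_hypothesis",
    "diagnostics",
    "posterior_predictive",
]

GROWTH_PARAMS = ("A", "B", "C", "subA", "subB", "subC")

#: hypothesis id -> (parameter, default margin as a fraction of the WL value)
HYPOTHESES = {
    "asymptote_50": ("A", 0.50),
    "inflection_5": ("B", 0.05),
    "rate_5": ("C", 0.05),
}


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz mean-curve parameters (all strictly positive)."""

    A: float  # asymptote, cm^2
    B: float  # inflection time, days
    C: float  # growth rate, 1/day

    def __post_init__(self):
        if min(self.A, self.B, self.C) <= 0:
            raise ValueError("Gompertz parameters must be strictly positive")


@dataclass(frozen=True)
class VarianceParams:
    """Logistic noise-scale parameters (all strictly positive)."""

    subA: float  # asymptotic sd, cm^2
    subB: float  # sd inflection time, days
    subC: float  # sd increase rate, 1/day

    def __post_init__(self):
        if min(self.subA, self.subB, self.subC) <= 0:
            raise ValueError("variance parameters must be strictly positive")


def gompertz_mean(t, p: GompertzParams):
    """Gompertz mean area at time ``t`` (days): A*exp(-exp(-C*(t-B)))."""
    t = np.asarray(t, dtype=float)
    return p.A * np.exp(-np.exp(-p.C * (t - p.B)))


def variance_profile(t, v: VarianceParams):
    """Logistic noise sd at time ``t``: subA / (1 + exp(-subC*(t-subB)))."""
    t = np.asarray(t, dtype=float)
    return v.subA / (1.0 + np.exp(-v.subC * (t - v.subB)))


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the growth fit.

    ``centers`` holds the lognormal medians for the six curve parameters,
    ``sigma`` the shared lognormal scale on the log axis, and
    ``df_shape``/``df_rate`` the Gamma prior on the Student-t degrees of
    freedom (truncated at ``nu >= 1``).
    """

    centers: dict = field(
        default_factory=lambda: {
            "A": 130.0, "B": 15.0, "C": 0.25, "subA": 20.0, "subB": 10.0, "subC": 3.0,
        }
    )
    sigma: float = 0.25
    df_shape: float = 2.0
    df_rate: float = 0.1

    def __post_init__(self):
        if any(c <= 0 for c in self.centers.values()) or self.sigma <= 0:
            raise ValueError("prior centers and scale must be positive")
        if self.df_shape <= 0 or self.df_rate <= 0:
            raise ValueError("df prior shape and rate must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> dict:
        """Draw ``n`` iid samples from each prior (dict of arrays)."""
        out = {
            name: rng.lognormal(np.log(c), self.sigma, size=n)
            for name, c in self.centers.items()
        }
        nu = rng.gamma(self.df_shape, 1.0 / self.df_rate, size=4 * n)
        nu = nu[nu >= 1.0]
        while nu.size < n:  # pragma: no cover - truncation rarely needs a refill
            extra = rng.gamma(self.df_shape, 1.0 / self.df_rate, size=4 * n)
            nu = np.concatenate([nu, extra[extra >= 1.0]])
        out["nu"] = nu[:n]
        return out


@dataclass
class PosteriorDraws:
    """Post-warmup MCMC draws for one fit.

    ``draws`` has shape (chains, iterations, parameters); ``param_names``
    follow the pattern ``"WW:A"`` / ``"WL:subB"`` with a single shared
    ``"nu"``.  Diagnostics (split-Rhat, ESS) are attached by
    :func:`fit_growth_model` and recomputable with :func:`diagnostics`.
    """

    draws: np.ndarray
    param_names: list
    groups: list
    accession: str = ""
    rhat: pd.Series | None = None
    ess: pd.Series | None = None
    converged: bool | None = None

    def __post_init__(self):
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.param_names):
            raise ValueError("draws must be (chains, iterations, parameters)")

    def param(self, name: str) -> np.ndarray:
        """All draws of one parameter, shape (chains, iterations)."""
        return self.draws[:, :, self.param_names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.param(name).ravel()

    def median(self, name: str) -> float:
        return float(np.median(self.param(name)))

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(
            posterior={n: self.param(n) for n in self.param_names}
        )

    def summary(self) -> pd.DataFrame:
        """Median and central 95% interval per parameter, with diagnostics."""
        rows = []
        for n in self.param_names:
            x = self.flat(n)
            rows.append(
                {
                    "parameter": n,
                    "median": np.median(x),
                    "q2.5": np.percentile(x, 2.5),
                    "q97.5": np.percentile(x, 97.5),
                    "rhat": None if self.rhat is None else self.rhat.get(n),
                    "ess": None if self.ess is None else self.ess.get(n),
                }
            )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# log posterior


def _student_t_logpdf(y, nu, mu, sigma):
    z = (y - mu) / sigma
    return (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - np.log(sigma)
        - (nu + 1.0) / 2.0 * np.log1p(z * z / nu)
    )


class _GrowthPosterior:
    """Log posterior on log-parameters for a multi-group Gompertz fit.

    Parameter vector layout: for each group in order, log(A, B, C, subA,
    subB, subC); last entry log(nu).  Data enter as per-group (t, y) arrays.
    """

    def __init__(self, data_by_group, priors: PriorSpec, prior_only=False):
        self.groups = list(data_by_group)
        self.data = {g: (np.asarray(t, float), np.asarray(y, float)) for g, (t, y) in data_by_group.items()}
        self.priors = priors
        self.prior_only = prior_only
        self.ndim = 6 * len(self.groups) + 1
        self._mu0 = np.array(
            [np.log(priors.centers[p]) for _ in self.groups for p in GROWTH_PARAMS]
        )

    def param_names(self):
        names = [f"{g}:{p}" for g in self.groups for p in GROWTH_PARAMS]
        return names + ["nu"]

    def __call__(self, theta):
        theta = np.asarray(theta, float)
        log_nu = theta[-1]
        nu = np.exp(log_nu)
        if nu < 1.0 or not np.all(np.isfinite(theta)):
            return -np.inf
        s = self.priors.sigma
        lp = -0.5 * np.sum(((theta[:-1] - self._mu0) / s) ** 2) - theta[:-1].size * np.log(s)
        # Gamma prior on nu plus the log-transform Jacobian
        lp += (
            self.priors.df_shape * np.log(self.priors.df_rate)
            - gammaln(self.priors.df_shape)
            + (self.priors.df_shape - 1.0) * log_nu
            - self.priors.df_rate * nu
            + log_nu
        )
        if self.prior_only:
            return lp
        for i, g in enumerate(self.groups):
            a, b, c, sa, sb, sc = np.exp(theta[6 * i : 6 * i + 6])
            t, y = self.data[g]
            mu = a * np.exp(-np.exp(-c * (t - b)))
            sig = sa / (1.0 + np.exp(-sc * (t - sb)))
            if np.any(sig <= 0) or not np.all(np.isfinite(sig)):
                return -np.inf
            lp += np.sum(_student_t_logpdf(y, nu, mu, sig))
        if not np.isfinite(lp):
            return -np.inf
        return lp


def _laplace_cov(logpost, x, eps=1e-4):
    """Inverse negative Hessian at the mode by central finite differences.

    Used only to seed the Metropolis proposal; clipped to be positive
    definite, with a diagonal fallback if the curvature is unusable.
    """
    d = x.size
    h = np.zeros((d, d))
    e = np.eye(d) * eps
    for i in range(d):
        for j in range(i, d):
            f = (
                logpost(x + e[i] + e[j])
                - logpost(x + e[i] - e[j])
                - logpost(x - e[i] + e[j])
                + logpost(x - e[i] - e[j])
            ) / (4.0 * eps * eps)
            h[i, j] = h[j, i] = f
    try:
        cov = np.linalg.inv(-(h + h.T) / 2.0)
        w, v = np.linalg.eigh((cov + cov.T) / 2.0)
        if np.all(np.isfinite(w)) and np.max(w) > 0:
            # guard positive definiteness without flattening the geometry
            w = np.clip(w, np.max(w) * 1e-12, None)
            return (v * w) @ v.T
    except np.linalg.LinAlgError:  # pragma: no cover
        pass
    return np.eye(d) * 1e-3  # pragma: no cover


def _block_adaptive_metropolis(logpost, x0, blocks, cov0, warmup, draws, rng):
    """Adaptive Metropolis-within-Gibbs, one chain.

    Each parameter block (e.g. one treatment group's six curve parameters,
    or the shared degrees of freedom) is updated with its own random-walk
    proposal seeded from the Laplace covariance; per-block step scales
    follow a Robbins-Monro recursion toward standard acceptance targets and
    the block covariance switches to the running warmup covariance once
    enough samples accumulate.  Everything is frozen after warmup.
    """
    x = x0.copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        raise RuntimeError("invalid starting point for MCMC chain")
    state = []
    for idx in blocks:
        idx = np.asarray(idx)
        d = idx.size
        sub = cov0[np.ix_(idx, idx)] + 1e-10 * np.eye(d)
        state.append(
            {
                "idx": idx,
                "target": 0.44 if d == 1 else 0.234 + 0.2 / d,
                "log_scale": np.log(2.38**2 / d),
                "chol": np.linalg.cholesky(sub),
                "base": sub,
                "mean": x[idx].copy(),
                "m2": np.zeros((d, d)),
                "n": 1,
            }
        )
    kept = np.empty((draws, x.size))
    accepts = np.zeros(len(blocks))
    for i in range(warmup + draws):
        for bi, b in enumerate(state):
            idx = b["idx"]
            prop = x.copy()
            prop[idx] = x[idx] + np.exp(0.5 * b["log_scale"]) * (
                b["chol"] @ rng.standard_normal(idx.size)
            )
            lp_prop = logpost(prop)
            accepted = np.log(rng.random()) < lp_prop - lp
            if accepted:
                x, lp = prop, lp_prop
                if i >= warmup:
                    accepts[bi] += 1
            if i < warmup:
                b["n"] += 1
                delta = x[idx] - b["mean"]
                b["mean"] = b["mean"] + delta / b["n"]
                b["m2"] += np.outer(delta, x[idx] - b["mean"])
                b["log_scale"] += (float(accepted) - b["target"]) / max(
                    1.0, (i + 1) ** 0.6
                )
                if (i + 1) % 100 == 0 and b["n"] > 10 * idx.size:
                    cov = b["m2"] / (b["n"] - 1) + 1e-10 * np.eye(idx.size)
                    try:
                        b["chol"] = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:  # pragma: no cover
                        b["chol"] = np.linalg.cholesky(b["base"])
        if i >= warmup:
            kept[i - warmup] = x
    return kept, accepts / max(draws, 1)


def _find_map(logpost, x0):
    res = optimize.minimize(
        lambda th: -logpost(th), x0, method="L-BFGS-B",
        options={"maxiter": 500},
    )
    if np.isfinite(res.fun):
        return res.x
    return x0  # pragma: no cover - fallback if optimisation diverges


def _run_ensemble(post, x_map, cov0, chains, warmup, draws, seed):
    """Affine-invariant ensemble run; walkers double as diagnostic chains.

    Walkers are initialized from the Laplace approximation at the MAP and
    evolved with differential-evolution moves, which cope with the strongly
    anisotropic log-posterior the near-zero early-season noise scale
    induces.  ``warmup`` burn-in ensemble steps are discarded and ``draws``
    steps kept per walker.
    """
    import emcee

    ndim = post.ndim
    n_walkers = max(32, 2 * ndim + 2, 2 * chains)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov0 + 1e-14 * np.eye(ndim))
    p0 = x_map[None, :] + 0.5 * (rng.standard_normal((n_walkers, ndim)) @ chol.T)
    for k in range(n_walkers):  # nudge any invalid starts back to the MAP
        tries = 0
        while not np.isfinite(post(p0[k])) and tries < 100:
            p0[k] = x_map + 0.1 * (chol @ rng.standard_normal(ndim))
            tries += 1
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, post, moves=moves)
    rstate0 = np.random.RandomState(
        int(rng.integers(2**31 - 1))
    ).get_state()
    state = sampler.run_mcmc(p0, warmup, progress=False, rstate0=rstate0)
    sampler.reset()
    sampler.run_mcmc(state, draws, progress=False)
    return np.exp(np.swapaxes(sampler.get_chain(), 0, 1))


def fit_growth_model(
    series: pd.DataFrame,
    priors: PriorSpec | None = None,
    chains: int = 2,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
    prior_only: bool = False,
    rhat_threshold: float = 1.05,
    sampler: str = "ensemble",
    max_retries: int = 2,
) -> PosteriorDraws:
    """Fit the distributional Gompertz model to one accession's growth data.

    Parameters
    ----------
    series
        Tidy frame with columns ``plant_id, treatment, day, area_cm2`` (an
        optional ``accession`` column must be single-valued).  Each
        treatment level becomes one parameter group.
    chains, warmup, draws
        Draw budget.  With the default ensemble sampler, ``warmup`` and
        ``draws`` are burn-in and kept ensemble steps and the walkers (at
        least 32, at least ``2 * chains``) serve as the diagnostic chains;
        with ``sampler='metropolis'``, ``chains`` independent adaptive
        random-walk chains are run.
    prior_only
        If True, ignore the data and return iid draws from the priors (the
        exact no-data posterior), useful for prior-predictive checks.
    rhat_threshold
        Fits with any split-Rhat above this are flagged (``converged=False``
        and a warning), never silently accepted.
    max_retries
        A flagged fit is retried with doubled warmup (and a perturbed
        stream) up to this many times before the flag is reported.

    Returns
    -------
    PosteriorDraws
        Post-warmup draws with split-Rhat/ESS diagnostics attached.
    """
    priors = priors or PriorSpec()
    rng = np.random.default_rng(seed)
    if "accession" in series.columns:
        accs = series["accession"].unique()
        if len(accs) > 1:
            raise ValueError(
                "fit_growth_model handles one accession at a time; got "
                f"{sorted(accs)}"
            )
        accession = str(accs[0]) if len(accs) else ""
    else:
        accession = ""

    required = {"plant_id", "treatment", "day", "area_cm2"}
    if not required.issubset(series.columns):
        raise ValueError(f"growth table needs columns {sorted(required)}")

    groups = sorted(series["treatment"].unique(), reverse=True)  # WW before WL
    data_by_group = {}
    for g in groups:
        sub = series[series["treatment"] == g]
        if sub.empty:
            raise ValueError(f"empty treatment group {g!r}")
        if not prior_only:
            if sub["plant_id"].nunique() < 2:
                raise ValueError(f"group {g!r} needs at least 2 plants")
            if sub["day"].nunique() < 6:
                raise ValueError(f"group {g!r} needs at least 6 distinct days")
        data_by_group[g] = (sub["day"].to_numpy(float), sub["area_cm2"].to_numpy(float))

    post = _GrowthPosterior(data_by_group, priors, prior_only=prior_only)
    names = post.param_names()

    if prior_only:
        all_draws = np.empty((chains, draws, len(names)))
        for c in range(chains):
            samp = priors.sample(draws, rng)
            for j, n in enumerate(names):
                p = n.split(":")[-1]
                all_draws[c, :, j] = samp["nu"] if p == "nu" else samp[p]
        result = PosteriorDraws(all_draws, names, list(groups), accession)
        result.converged = True
        return result

    x0 = np.concatenate([post._mu0, [np.log(20.0)]])
    x_map = _find_map(post, x0)
    cov0 = _laplace_cov(post, x_map)

    if sampler not in {"ensemble", "metropolis"}:
        raise ValueError("sampler must be 'ensemble' or 'metropolis'")

    attempt_warmup, attempt_seed = warmup, seed
    result = None
    for attempt in range(max_retries + 1):
        if sampler == "ensemble":
            all_draws = _run_ensemble(
                post, x_map, cov0, chains, attempt_warmup, draws, attempt_seed
            )
        else:
            blocks = [list(range(6 * i, 6 * i + 6)) for i in range(len(groups))]
            blocks.append([post.ndim - 1])  # shared degrees of freedom
            all_draws = np.empty((chains, draws, len(names)))
            for c in range(chains):
                start = x_map + 0.02 * rng.standard_normal(post.ndim)
                while not np.isfinite(post(start)):  # pragma: no cover
                    start = x_map + 0.02 * rng.standard_normal(post.ndim)
                kept, _ = _block_adaptive_metropolis(
                    post, start, blocks, cov0, attempt_warmup, draws, rng
                )
                all_draws[c] = np.exp(kept)

        result = PosteriorDraws(all_draws, names, list(groups), accession)
        result.rhat, result.ess = diagnostics(result)
        worst = float(np.nanmax(result.rhat.to_numpy()))
        result.converged = bool(worst <= rhat_threshold)
        if result.converged or not np.isfinite(rhat_threshold):
            return result
        attempt_warmup *= 2
        attempt_seed = attempt_seed + 7919  # fresh stream for the retry

    warnings.warn(
        f"growth fit for {accession or 'data'}: split-Rhat up to "
        f"{float(np.nanmax(result.rhat.to_numpy())):.3f} exceeds "
        f"{rhat_threshold} after {max_retries} retries; treat estimates "
        "with caution",
        RuntimeWarning,
        stacklevel=2,
    )
    return result


def diagnostics(post: PosteriorDraws) -> tuple:
    """Rank-normalized split-Rhat and effective sample size per parameter.

    Requires at least 2 chains; chains that are identical constants yield
    NaN Rhat (flagged rather than reported as converged).
    """
    import arviz as az

    if post.draws.shape[0] < 2:
        raise ValueError("split-Rhat is undefined for a single chain")
    idata = post.to_inference_data()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat = pd.Series({n: float(rhat_ds[n].values) for n in post.param_names})
    ess = pd.Series({n: float(ess_ds[n].values) for n in post.param_names})
    return rhat, ess


@dataclass(frozen=True)
class HypothesisResult:
    hypothesis: str
    parameter: str
    margin: float
    probability: float  # posterior P[(x_WW - x_WL)/x_WL > margin]
    effect_size: float  # posterior median of 100*(x_WW - x_WL)/x_WL
    supported: bool

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("posterior probability must lie in [0, 1]")


def test_hypothesis(
    post: PosteriorDraws,
    hypothesis: str,
    margin: float | None = None,
    ww: str = "WW",
    wl: str = "WL",
    support_threshold: float = 0.95,
) -> HypothesisResult:
    """Posterior test of a WW-vs-WL margin on one Gompertz parameter.

    ``probability`` is the fraction of (paired) posterior draws in which the
    WW parameter exceeds the WL parameter by more than ``margin`` (a
    fraction of the WL value); ``supported`` requires probability >=
    ``support_threshold``.
    """
    if hypothesis not in HYPOTHESES:
        raise KeyError(f"unknown hypothesis {hypothesis!r}; one of {sorted(HYPOTHESES)}")
    par, default_margin = HYPOTHESES[hypothesis]
    margin = default_margin if margin is None else margin
    for g in (ww, wl):
        if f"{g}:{par}" not in post.param_names:
            raise ValueError(f"draws do not contain group {g!r}")
    x_ww = post.flat(f"{ww}:{par}")
    x_wl = post.flat(f"{wl}:{par}")
    rel = (x_ww - x_wl) / x_wl
    prob = float(np.mean(rel > margin))
    effect = float(np.median(100.0 * rel))
    return HypothesisResult(
        hypothesis, par, margin, prob, effect, prob >= support_threshold
    )


def hypothesis_table(post: PosteriorDraws, **kwargs) -> pd.DataFrame:
    """Run all three standard hypotheses and return a tidy table."""
    rows = []
    for h in HYPOTHESES:
        r = test_hypothesis(post, h, **kwargs)
        rows.append(
            {
                "hypothesis": r.hypothesis,
                "parameter": r.parameter,
                "margin": r.margin,
                "posterior_probability": r.probability,
                "effect_size_pct": r.effect_size,
                "supported": r.supported,
            }
        )
    return pd.DataFrame(rows)


def posterior_predictive(
    post: PosteriorDraws,
    days,
    quantiles=(2.5, 10, 25, 50, 75, 90, 97.5),
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate predictive observations and summarize quantile ribbons.

    For each requested day and group, observations are simulated from the
    Student-t observation model at parameter values resampled from the
    posterior; the returned frame has one row per (group, day) with the
    requested predictive quantiles.
    """
    rng = np.random.default_rng(seed)
    days = np.asarray(days, dtype=float)
    n_total = post.draws.shape[0] * post.draws.shape[1]
    idx = rng.integers(0, n_total, size=min(n_draws, n_total))
    rows = []
    nu = post.flat("nu")[idx]
    for g in post.groups:
        p = {name: post.flat(f"{g}:{name}")[idx] for name in GROWTH_PARAMS}
        mu = p["A"][:, None] * np.exp(
            -np.exp(-p["C"][:, None] * (days[None, :] - p["B"][:, None]))
        )
        sig = p["subA"][:, None] / (
            1.0 + np.exp(-p["subC"][:, None] * (days[None, :] - p["subB"][:, None]))
        )
        y = mu + sig * rng.standard_t(nu[:, None], size=mu.shape)
        qs = np.percentile(y, quantiles, axis=0)
        for j, d in enumerate(days):
            row = {"group": g, "day": d}
            row.update({f"q{q}": qs[i, j] for i, q in enumerate(quantiles)})
            rows.append(row)
    return pd.DataFrame(rows)
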