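"""Bayesian beta regression with location and precision submodels.

Bounded ratings y in (0, 1) are modeled as Beta(mu*phi, (1-mu)*phi) with

    logit(mu_i) = x_i' b + u_{subject(i)},      log(phi_i) = z_i' d,

where b are location coefficients, d precision coefficients, and u are
subject random intercepts with u_j ~ Normal(0, sigma_u^2). The location
submodel moves the mean of the rating distribution; the precision submodel
moves its homogeneity (Var = mu(1-mu)/(1+phi), so a positive d coefficient
means more homogeneous responses). Factors enter through effects coding, so
both intercepts estimate grand means.

Estimation is MCMC: adaptive random-walk Metropolis within Gibbs blocks
(b | d | u | log sigma_u), with diagonal proposal adaptation during burn-in
only. Hyperpriors: Normal(0, 10^2) on each b and d, half-Normal(0, 2.5) on
sigma_u. Model comparison uses DIC with Spiegelhalter's pD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "PosteriorDraws",
    "FitSummary",
    "DICResult",
    "rescale_to_unit",
    "effects_code",
    "build_design_matrix",
    "log_posterior",
    "fit",
    "summarize",
    "dic",
    "delta_dic",
    "interpret_delta_dic",
    "read_ratings",
    "write_summary",
]


def rescale_to_unit(values, scale_max: float = 100.0, n_total: int | None = None):
    """Compress a bounded scale onto the open unit interval.

    Applies ``y -> (y/scale_max * (n - 1) + 0.5) / n`` so that boundary
    responses (0 and ``scale_max``) land strictly inside (0, 1) and the
    transform is order-preserving. ``n_total`` defaults to the number of
    values, following the convention that the compression shrinks with the
    number of analyzed responses.
    """
    y = np.asarray(values, dtype=float)
    if np.any(y < 0) or np.any(y > scale_max):
        raise ValueError(f"values must lie in [0, {scale_max}]")
    n = len(y) if n_total is None else n_total
    if n < 2:
        raise ValueError("n_total must be at least 2")
    return (y / scale_max * (n - 1) + 0.5) / n


def effects_code(levels: Sequence[str], values) -> pd.DataFrame:
    """Effects (sum-to-zero) coding: k levels -> k-1 columns.

    The first entry of ``levels`` is the reference and codes as -1 in every
    column; non-reference level i gets an indicator in column i. Column sums
    over one copy of each level are zero, so intercepts estimate grand means.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("effects coding needs at least 2 levels")
    values = pd.Series(values).astype(str)
    unseen = set(values) - set(levels)
    if unseen:
        raise ValueError(f"unseen factor levels: {sorted(unseen)}")
    ref, rest = levels[0], levels[1:]
    out = {}
    for lvl in rest:
        col = np.where(values == lvl, 1.0, 0.0)
        col = np.where(values == ref, -1.0, col)
        out[lvl] = col
    return pd.DataFrame(out, index=values.index)


@dataclass(frozen=True)
class DesignSpec:
    """Model formula for the two submodels.

    ``location_terms`` / ``precision_terms`` are factor names or ``a:b``
    interactions; ``factor_levels`` fixes level order (first level =
    reference). Terms act on effects-coded columns; interactions are
    elementwise products of their parents' columns.
    """

    location_terms: tuple[str, ...]
    precision_terms: tuple[str, ...]
    factor_levels: Mapping[str, tuple[str, ...]]
    random_intercept: bool = True

    def drop(self, term: str) -> "DesignSpec":
        """Copy of the design without ``term`` in either submodel."""
        return DesignSpec(
            tuple(t for t in self.location_terms if t != term),
            tuple(t for t in self.precision_terms if t != term),
            self.factor_levels,
            self.random_intercept,
        )


def _term_columns(term: str, data: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    parts = term.split(":")
    blocks = []
    for p in parts:
        if p in spec.factor_levels:
            blocks.append(effects_code(spec.factor_levels[p], data[p]))
        else:
            blocks.append(pd.DataFrame({p: pd.to_numeric(data[p])}))  # covariate
    cols = blocks[0]
    for nxt in blocks[1:]:
        prod = {}
        for a in cols.columns:
            for b in nxt.columns:
                prod[f"{a}:{b}"] = cols[a].to_numpy() * nxt[b].to_numpy()
        cols = pd.DataFrame(prod, index=cols.index)
    return cols


def build_design_matrix(
    data: pd.DataFrame, terms: Sequence[str], spec: DesignSpec
) -> pd.DataFrame:
    """Design matrix with an intercept column followed by each term's columns."""
    out = [pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)]
    for term in terms:
        out.append(_term_columns(term, data, spec))
    return pd.concat(out, axis=1)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws (rows) for named parameters (columns)."""

    draws: pd.DataFrame
    n_subjects: int
    subject_index: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.draws.columns)


@dataclass
class FitSummary:
    """Posterior means, SDs and central 95% intervals, plus contrasts."""

    table: pd.DataFrame
    contrasts: pd.DataFrame | None = None


@dataclass(frozen=True)
class DICResult:
    dic: float
    dbar: float
    pd: float


# -- likelihood ------------------------------------------------------------


def _beta_loglik(y_logit_parts, eta_mu, eta_phi):
    """Record-wise Beta log-density given linear predictors."""
    log_y, log_1my = y_logit_parts
    mu = expit(eta_mu)
    phi = np.exp(np.clip(eta_phi, -30.0, 30.0))
    a = mu * phi
    b = (1.0 - mu) * phi
    return gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1.0) * log_y + (b - 1.0) * log_1my


class _Model:
    """Precomputed design pieces for fast log-posterior evaluation."""

    def __init__(self, data: pd.DataFrame, design: DesignSpec, response: str = "response"):
        y = np.asarray(data[response], dtype=float)
        if np.any(y <= 0.0) or np.any(y >= 1.0):
            raise ValueError("responses must lie strictly inside (0, 1); rescale first")
        self.y_parts = (np.log(y), np.log1p(-y))
        self.y = y
        self.X = build_design_matrix(data, design.location_terms, design).to_numpy()
        self.Z = build_design_matrix(data, design.precision_terms, design).to_numpy()
        self.x_names = list(build_design_matrix(data, design.location_terms, design).columns)
        self.z_names = list(build_design_matrix(data, design.precision_terms, design).columns)
        self.random_intercept = design.random_intercept
        subjects = pd.Categorical(data["subject"].astype(str))
        self.subject_index = np.asarray(subjects.codes)
        self.n_subjects = len(subjects.categories) if design.random_intercept else 0

    def loglik_records(self, b, d, u):
        eta_mu = self.X @ b
        if self.random_intercept:
            eta_mu = eta_mu + u[self.subject_index]
        return _beta_loglik(self.y_parts, eta_mu, self.Z @ d)


_B_PRIOR_SD = 10.0
_SIGMA_U_SCALE = 2.5


def _log_prior(b, d, u, sigma_u, random_intercept):
    lp = -0.5 * np.sum(b**2) / _B_PRIOR_SD**2 - 0.5 * np.sum(d**2) / _B_PRIOR_SD**2
    if random_intercept:
        lp += -0.5 * sigma_u**2 / _SIGMA_U_SCALE**2  # half-Normal on sigma_u
        lp += -u.size * np.log(sigma_u) - 0.5 * np.sum(u**2) / sigma_u**2
    return lp


def log_posterior(
    params: Mapping[str, np.ndarray],
    data: pd.DataFrame,
    design: DesignSpec,
    response: str = "response",
) -> float:
    """Unnormalized log posterior at one parameter point.

    ``params`` holds ``b``, ``d`` and, with a random intercept, ``u`` and
    ``sigma_u``. Provided mainly for testing and external samplers; the
    internal sampler uses the same pieces incrementally.
    """
    model = _Model(data, design, response)
    b = np.asarray(params["b"], dtype=float)
    d = np.asarray(params["d"], dtype=float)
    u = np.asarray(params.get("u", np.zeros(model.n_subjects)), dtype=float)
    sigma_u = float(params.get("sigma_u", 1.0))
    ll = float(np.sum(model.loglik_records(b, d, u)))
    return ll + float(_log_prior(b, d, u, sigma_u, model.random_intercept))


# -- sampler ---------------------------------------------------------------


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction for a single chain."""
    n = x.size // 2
    halves = np.stack([x[:n], x[n : 2 * n]])
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def fit(
    data: pd.DataFrame,
    design: DesignSpec,
    n_draws: int = 8000,
    n_burn: int = 4000,
    seed: int = 0,
    response: str = "response",
) -> PosteriorDraws:
    """Sample the posterior of the beta GLM by Metropolis-within-Gibbs.

    ``n_draws`` is the total chain length and ``n_burn`` the discarded
    initial segment, so ``n_draws - n_burn`` draws are retained. Identical
    seeds give identical draws. Proposal scales adapt toward a 0.2-0.5
    acceptance rate during burn-in only, so the retained chain is a valid
    fixed-kernel sample.
    """
    if n_burn >= n_draws:
        raise ValueError("n_burn must be smaller than n_draws")
    rng = np.random.default_rng(seed)
    model = _Model(data, design, response)
    p, q = model.X.shape[1], model.Z.shape[1]

    b = np.zeros(p)
    b[0] = float(logit(np.clip(model.y.mean(), 1e-3, 1 - 1e-3)))
    d = np.zeros(q)
    d[0] = 1.0
    nu = model.n_subjects
    u = np.zeros(nu)
    log_sigma = np.log(0.5)

    ll_rec = model.loglik_records(b, d, u)
    if not np.all(np.isfinite(ll_rec)):
        raise FloatingPointError("non-finite log-posterior at initialization")

    sb = np.full(p, 0.1)
    sd_ = np.full(q, 0.1)
    su = 0.3
    ss = 0.3
    acc = {"b": 0, "d": 0, "u": 0, "sigma": 0}
    kept = np.empty((n_draws - n_burn, p + q + nu + (1 if model.random_intercept else 0)))

    def prior_b(v):
        return -0.5 * np.sum(v**2) / _B_PRIOR_SD**2

    ll_sum = float(ll_rec.sum())
    for it in range(n_draws):
        adapting = it < n_burn
        # block 1: location coefficients (joint RW)
        prop_b = b + sb * rng.standard_normal(p)
        ll_prop = model.loglik_records(prop_b, d, u)
        ll_prop_sum = float(ll_prop.sum())
        if np.log(rng.random()) < (ll_prop_sum + prior_b(prop_b)) - (ll_sum + prior_b(b)):
            b, ll_rec, ll_sum = prop_b, ll_prop, ll_prop_sum
            acc["b"] += 1
            if adapting:
                sb *= 1.01
        elif adapting:
            sb *= 0.993

        # block 2: precision coefficients
        prop_d = d + sd_ * rng.standard_normal(q)
        ll_prop = model.loglik_records(b, prop_d, u)
        ll_prop_sum = float(ll_prop.sum())
        if np.log(rng.random()) < (ll_prop_sum + prior_b(prop_d)) - (ll_sum + prior_b(d)):
            d, ll_rec, ll_sum = prop_d, ll_prop, ll_prop_sum
            acc["d"] += 1
            if adapting:
                sd_ *= 1.01
        elif adapting:
            sd_ *= 0.993

        if model.random_intercept:
            sigma_u = np.exp(log_sigma)
            # block 3: subject intercepts, conditionally independent given
            # (b, d, sigma_u) -> vectorized per-subject accept/reject
            prop_u = u + su * rng.standard_normal(nu)
            ll_prop = model.loglik_records(b, d, prop_u)
            cur_subj = np.bincount(model.subject_index, weights=ll_rec, minlength=nu)
            prop_subj = np.bincount(model.subject_index, weights=ll_prop, minlength=nu)
            log_r = (prop_subj - cur_subj) - 0.5 * (prop_u**2 - u**2) / sigma_u**2
            accept = np.log(rng.random(nu)) < log_r
            u = np.where(accept, prop_u, u)
            if np.any(accept):
                ll_rec = model.loglik_records(b, d, u)
                ll_sum = float(ll_rec.sum())
            rate = accept.mean()
            acc["u"] += rate
            if adapting:
                su *= np.exp(0.05 * (rate - 0.35))

            # block 4: log sigma_u (prior + Jacobian; likelihood for u only)
            prop_ls = log_sigma + ss * rng.standard_normal()
            def u_logpost(ls):
                s = np.exp(ls)
                return (-nu * ls - 0.5 * np.sum(u**2) / s**2
                        - 0.5 * s**2 / _SIGMA_U_SCALE**2 + ls)
            if np.log(rng.random()) < u_logpost(prop_ls) - u_logpost(log_sigma):
                log_sigma = prop_ls
                acc["sigma"] += 1
                if adapting:
                    ss *= 1.01
            elif adapting:
                ss *= 0.993

        if it >= n_burn:
            row = kept[it - n_burn]
            row[:p] = b
            row[p : p + q] = d
            if model.random_intercept:
                row[p + q : p + q + nu] = u
                row[-1] = np.exp(log_sigma)

    names = [f"b[{n}]" for n in model.x_names] + [f"d[{n}]" for n in model.z_names]
    if model.random_intercept:
        names += [f"u[{j}]" for j in range(nu)] + ["sigma_u"]
    frame = pd.DataFrame(kept, columns=names)

    n_kept = n_draws - n_burn
    rates = {k: v / n_draws for k, v in acc.items()}
    rhat = {n: _split_rhat(frame[n].to_numpy()) for n in names[: p + q]}
    logger.info("acceptance rates: %s", {k: round(v, 3) for k, v in rates.items()})
    logger.info("max split-Rhat over coefficients: %.3f", max(rhat.values()))
    meta = {
        "n_draws": n_draws,
        "n_burn": n_burn,
        "n_retained": n_kept,
        "seed": seed,
        "acceptance": rates,
        "rhat": rhat,
        "p_location": p,
        "q_precision": q,
    }
    return PosteriorDraws(frame, nu, model.subject_index, meta)


# -- summaries -------------------------------------------------------------


def _summ(x: np.ndarray) -> dict[str, float]:
    lo, hi = np.quantile(x, [0.025, 0.975])
    return {"mean": float(x.mean()), "se": float(x.std(ddof=1)), "q2.5": float(lo), "q97.5": float(hi)}


def summarize(
    draws: PosteriorDraws,
    contrasts: Mapping[str, Mapping[str, float]] | None = None,
    odds_ratio_decimals: int = 2,
) -> FitSummary:
    """Posterior mean / SD / 95% interval per parameter, plus contrasts.

    Each contrast is a named linear combination of parameters, summarized
    from its per-draw values; location-scale contrasts are additionally
    reported as an odds ratio, ``exp`` of the posterior-mean estimate rounded
    to ``odds_ratio_decimals``.
    """
    if draws.draws.empty:
        raise ValueError("no retained draws to summarize")
    rows = {name: _summ(draws.draws[name].to_numpy()) for name in draws.names}
    table = pd.DataFrame(rows).T.rename_axis("parameter")
    ctab = None
    if contrasts:
        crow = {}
        for cname, weights in contrasts.items():
            vals = np.zeros(len(draws.draws))
            for pname, w in weights.items():
                vals = vals + w * draws.draws[pname].to_numpy()
            s = _summ(vals)
            s["odds_ratio"] = round(float(np.exp(s["mean"])), odds_ratio_decimals)
            crow[cname] = s
        ctab = pd.DataFrame(crow).T.rename_axis("contrast")
    return FitSummary(table, ctab)


# -- DIC -------------------------------------------------------------------


def _deviance(model: _Model, b, d, u) -> float:
    return -2.0 * float(np.sum(model.loglik_records(b, d, u)))


def dic(
    draws: PosteriorDraws,
    data: pd.DataFrame,
    design: DesignSpec,
    response: str = "response",
    thin: int = 1,
) -> DICResult:
    """Deviance information criterion with Spiegelhalter's pD.

    dbar is the posterior-mean deviance, pD = dbar - D(posterior-mean
    parameters), dic = dbar + pD. Lower is better.
    """
    model = _Model(data, design, response)
    p = draws.meta["p_location"]
    q = draws.meta["q_precision"]
    arr = draws.draws.to_numpy()[::thin]
    nu = draws.n_subjects
    devs = np.empty(arr.shape[0])
    for i, row in enumerate(arr):
        u = row[p + q : p + q + nu] if model.random_intercept else np.zeros(0)
        devs[i] = _deviance(model, row[:p], row[p : p + q], u)
    dbar = float(devs.mean())
    mean_row = arr.mean(axis=0)
    u_bar = mean_row[p + q : p + q + nu] if model.random_intercept else np.zeros(0)
    d_at_mean = _deviance(model, mean_row[:p], mean_row[p : p + q], u_bar)
    p_d = dbar - d_at_mean
    return DICResult(dic=dbar + p_d, dbar=dbar, pd=p_d)


def delta_dic(full: DICResult, reduced: DICResult) -> float:
    """DIC penalty for the reduced model: dic(reduced) - dic(full)."""
    return reduced.dic - full.dic


def interpret_delta_dic(delta: float) -> str:
    """Interpretation band for a DIC difference.

    <3 negligible, 3-7 substantial, 7-10 borderline, >10 definite.
    """
    a = abs(delta)
    if a < 3:
        return "negligible"
    if a <= 7:
        return "substantial"
    if a <= 10:
        return "borderline"
    return "definite"


# -- I/O -------------------------------------------------------------------

_RATING_COLUMNS = ["subject", "valence", "covariance", "question", "best", "min", "max"]


def read_ratings(path) -> pd.DataFrame:
    """Read a rating CSV (subject,valence,covariance,question,best,min,max
    with an optional precedence_belief column)."""
    frame = pd.read_csv(path)
    missing = [c for c in _RATING_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"rating CSV missing columns: {missing}")
    return frame


def write_summary(summary: FitSummary, path) -> None:
    """Write the coefficient table (parameter, mean, SE, 2.5%, 97.5%) as CSV."""
    out = summary.table.reset_index()
    out.columns = ["parameter", "coefficient", "SE", "2.5%", "97.5%"]
    out.to_csv(path, index=False)
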