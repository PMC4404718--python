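"""Computational models of causal judgment from 2x2 covariation data.

All models operate on a :class:`ContingencyTable` of effect x cause counts and
return predictions on the unit interval. The candidate cause combines with an
always-present background cause through a noisy-OR (generative valence) or
noisy-AND-NOT (preventive valence) parameterization with background strength
``w0`` and candidate strength ``w1``:

- generative: ``P(e|c) = w0 + w1 - w0*w1``,  ``P(e|not c) = w0``
- preventive: ``P(e|c) = w0*(1 - w1)``,      ``P(e|not c) = w0``

Point estimation (MLE) reduces to the classical causal-power statistic;
Bayesian estimation integrates over ``(w0, w1)`` on a grid under either a
uniform prior or a Strong-and-Sparse (SS) prior that favors strong candidate
causes and (for generative valence) weak backgrounds. Causal support compares
a graph with the candidate link (G1) against a null graph (G0); the structure
induction model forms diagnostic/predictive query predictions as the
structure-posterior-weighted average of the graph-conditional queries, and
causal attribution gives the probability the candidate cause produced an
observed effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Valence = Literal["generative", "preventive"]
GraphId = Literal["G0", "G1"]
Direction = Literal["diagnostic", "predictive"]

VALENCES: tuple[Valence, ...] = ("generative", "preventive")

__all__ = [
    "ContingencyTable",
    "PriorSpec",
    "Grid",
    "ModelVariant",
    "contingency_stats",
    "causal_power",
    "data_likelihood",
    "ss_prior_density",
    "marginal_likelihood",
    "structure_posterior",
    "posterior_strength",
    "query_probability",
    "structure_induction_predict",
    "causal_attribution",
    "mle_params",
    "default_registry",
    "enumerate_variants",
    "predictions_frame",
]


class MarginError(ValueError):
    """A cause margin of the contingency table is empty."""


class CeilingError(ValueError):
    """Causal power undefined: base rate at the relevant boundary."""


class NotApplicableError(ValueError):
    """Model family not defined for the requested valence."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of effect (e1/e0) by cause (c1/c0) occurrence."""

    n_e1c1: int
    n_e0c1: int
    n_e1c0: int
    n_e0c0: int

    def __post_init__(self) -> None:
        for name in ("n_e1c1", "n_e0c1", "n_e1c0", "n_e0c0"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n_c1(self) -> int:
        return self.n_e1c1 + self.n_e0c1

    @property
    def n_c0(self) -> int:
        return self.n_e1c0 + self.n_e0c0

    @property
    def n_total(self) -> int:
        return self.n_c1 + self.n_c0


@dataclass(frozen=True)
class PriorSpec:
    """Parameter and structure prior for the Bayesian models.

    ``kind="uniform"`` is flat on the unit square; ``kind="SS"`` is the
    Strong-and-Sparse prior with sharpness ``alpha`` (``alpha = 0`` reduces to
    uniform). ``structure_prior_g1`` is the prior probability of the graph
    with the candidate link.
    """

    kind: Literal["uniform", "SS"] = "uniform"
    alpha: float = 5.0
    structure_prior_g1: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "SS"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if not 0.0 <= self.structure_prior_g1 <= 1.0:
            raise ValueError("structure_prior_g1 must lie in [0, 1]")


@dataclass(frozen=True)
class Grid:
    """Uniform grid on [0, 1] used for trapezoid integration."""

    step: float = 0.005
    nodes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.step <= 1.0:
            raise ValueError("step must lie in (0, 1]")
        n = int(round(1.0 / self.step))
        object.__setattr__(self, "nodes", np.linspace(0.0, 1.0, n + 1))


def contingency_stats(table: ContingencyTable) -> dict[str, float]:
    """Conditional probabilities of the effect and their difference (delta P)."""
    if table.n_c1 == 0:
        raise MarginError("cause-present margin is empty")
    if table.n_c0 == 0:
        raise MarginError("cause-absent margin is empty")
    p1 = table.n_e1c1 / table.n_c1
    p0 = table.n_e1c0 / table.n_c0
    return {"p_e_given_c": p1, "p_e_given_notc": p0, "delta_p": p1 - p0}


def causal_power(table: ContingencyTable, valence: Valence = "generative") -> float:
    """Maximum-likelihood causal power of the candidate cause.

    Generative power = dP / (1 - P(e|not c)); preventive power =
    -dP / P(e|not c). A zero contingency maps to 0; tiny negative values from
    rounding are clamped to 0.
    """
    stats = contingency_stats(table)
    p0, dp = stats["p_e_given_notc"], stats["delta_p"]
    if valence == "generative":
        if p0 >= 1.0:
            raise CeilingError("generative power undefined when P(e|not c) = 1")
        power = dp / (1.0 - p0)
    elif valence == "preventive":
        if p0 <= 0.0:
            raise CeilingError("preventive power undefined when P(e|not c) = 0")
        power = -dp / p0
    else:
        raise ValueError(f"unknown valence {valence!r}")
    return float(np.clip(power, 0.0, 1.0))


def _p_e_given_c(w0, w1, valence: Valence):
    if valence == "generative":
        return w0 + w1 - w0 * w1
    if valence == "preventive":
        return w0 * (1.0 - w1)
    raise ValueError(f"unknown valence {valence!r}")


def data_likelihood(
    table: ContingencyTable,
    w0,
    w1,
    valence: Valence = "generative",
    graph: GraphId = "G1",
    log: bool = False,
):
    """(Log-)likelihood of the table under the noisy-OR/AND-NOT model.

    Accepts scalars or broadcastable arrays for ``w0``/``w1``; under G0 the
    candidate strength is forced to zero regardless of ``w1``.
    """
    w0 = np.asarray(w0, dtype=float)
    w1 = np.zeros_like(w0) if graph == "G0" else np.asarray(w1, dtype=float)
    p1 = _p_e_given_c(w0, w1, valence)
    p0 = w0
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            table.n_e1c1 * np.log(p1)
            + table.n_e0c1 * np.log1p(-p1)
            + table.n_e1c0 * np.log(p0)
            + table.n_e0c0 * np.log1p(-p0)
        )
    # 0*log(0) cells contribute 1, not nan
    for count, p, side in (
        (table.n_e1c1, p1, "lo"),
        (table.n_e0c1, p1, "hi"),
        (table.n_e1c0, p0, "lo"),
        (table.n_e0c0, p0, "hi"),
    ):
        if count == 0:
            bad = (p <= 0.0) if side == "lo" else (p >= 1.0)
            ll = np.where(bad & ~np.isfinite(ll), np.where(np.isnan(ll), 0.0, ll), ll)
    ll = np.where(np.isnan(ll), -np.inf, ll)
    out = ll if log else np.exp(ll)
    return float(out) if np.ndim(out) == 0 else out


def ss_prior_density(
    grid: Grid, valence: Valence = "generative", alpha: float = 5.0
) -> np.ndarray:
    """Strong-and-Sparse prior density over (w0, w1) on the grid, normalized.

    Unnormalized form ``exp(-a*w0 - a*(1-w1))`` for generative valence (weak
    background, strong candidate) and ``exp(-a*(1-w0) - a*(1-w1))`` for
    preventive (strong background available to be suppressed, strong
    candidate). Returned as a (len(nodes), len(nodes)) array indexed
    [w0, w1] whose trapezoid integral is 1.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    w = grid.nodes
    if valence == "generative":
        f0 = np.exp(-alpha * w)
    elif valence == "preventive":
        f0 = np.exp(-alpha * (1.0 - w))
    else:
        raise ValueError(f"unknown valence {valence!r}")
    f1 = np.exp(-alpha * (1.0 - w))
    dens = np.outer(f0, f1)
    z = np.trapezoid(np.trapezoid(dens, w, axis=1), w)
    return dens / z


def _prior_2d(prior: PriorSpec, grid: Grid, valence: Valence) -> np.ndarray:
    if prior.kind == "uniform":
        return np.ones((grid.nodes.size, grid.nodes.size))
    return ss_prior_density(grid, valence, prior.alpha)


def _prior_1d(prior: PriorSpec, grid: Grid, valence: Valence) -> np.ndarray:
    """Marginal prior over w0 under G0 (w1 integrated out / absent)."""
    dens2 = _prior_2d(prior, grid, valence)
    marg = np.trapezoid(dens2, grid.nodes, axis=1)
    return marg / np.trapezoid(marg, grid.nodes)


def _likelihood_grid(
    table: ContingencyTable, grid: Grid, valence: Valence, graph: GraphId
) -> np.ndarray:
    w = grid.nodes
    if graph == "G0":
        return data_likelihood(table, w, 0.0, valence, "G0")
    w0, w1 = np.meshgrid(w, w, indexing="ij")
    return data_likelihood(table, w0, w1, valence, "G1")


def marginal_likelihood(
    table: ContingencyTable,
    graph: GraphId,
    prior: PriorSpec = PriorSpec(),
    grid: Grid = Grid(),
    valence: Valence = "generative",
) -> float:
    """Marginal likelihood of the table under one graph, by grid integration."""
    if grid.nodes.size < 3:
        raise ValueError("grid too coarse for trapezoid integration")
    w = grid.nodes
    lik = _likelihood_grid(table, grid, valence, graph)
    if graph == "G0":
        integrand = lik * _prior_1d(prior, grid, valence)
        return float(np.trapezoid(integrand, w))
    integrand = lik * _prior_2d(prior, grid, valence)
    return float(np.trapezoid(np.trapezoid(integrand, w, axis=1), w))


def structure_posterior(
    table: ContingencyTable,
    prior: PriorSpec = PriorSpec(),
    grid: Grid = Grid(),
    valence: Valence = "generative",
) -> dict[str, float]:
    """Posterior over {G0, G1} and the causal support statistic.

    ``support`` is the log marginal-likelihood ratio log m(G1)/m(G0);
    ``p_g1`` additionally weights by the structure prior and normalizes.
    """
    if not 0.0 < prior.structure_prior_g1 < 1.0:
        # degenerate structure priors short-circuit to the certain graph
        p = float(prior.structure_prior_g1)
        m1 = marginal_likelihood(table, "G1", prior, grid, valence)
        m0 = marginal_likelihood(table, "G0", prior, grid, valence)
        return {"p_g1": p, "p_g0": 1.0 - p, "support": float(np.log(m1 / m0))}
    m1 = marginal_likelihood(table, "G1", prior, grid, valence)
    m0 = marginal_likelihood(table, "G0", prior, grid, valence)
    a1 = prior.structure_prior_g1 * m1
    a0 = (1.0 - prior.structure_prior_g1) * m0
    p_g1 = a1 / (a1 + a0)
    return {"p_g1": float(p_g1), "p_g0": float(1.0 - p_g1), "support": float(np.log(m1 / m0))}


def _posterior_2d(
    table: ContingencyTable, prior: PriorSpec, grid: Grid, valence: Valence
) -> np.ndarray:
    """Normalized posterior density over (w0, w1) under G1."""
    w = grid.nodes
    post = _likelihood_grid(table, grid, valence, "G1") * _prior_2d(prior, grid, valence)
    z = np.trapezoid(np.trapezoid(post, w, axis=1), w)
    return post / z


def _posterior_mean_2d(fvals: np.ndarray, post: np.ndarray, grid: Grid) -> float:
    w = grid.nodes
    return float(np.trapezoid(np.trapezoid(fvals * post, w, axis=1), w))


def posterior_strength(
    table: ContingencyTable,
    prior: PriorSpec = PriorSpec(),
    grid: Grid = Grid(),
    valence: Valence = "generative",
) -> float:
    """Posterior mean of the candidate strength w1 under G1."""
    post = _posterior_2d(table, prior, grid, valence)
    _, w1 = np.meshgrid(grid.nodes, grid.nodes, indexing="ij")
    return _posterior_mean_2d(w1, post, grid)


def query_probability(
    w0,
    w1,
    graph: GraphId,
    direction: Direction,
    valence: Valence = "generative",
    base_rate_c: float = 0.5,
):
    """Predictive P(e|c) or diagnostic P(c|e) query under one graph.

    Under G0 the cause and effect are independent, so the diagnostic query
    equals the base rate of the cause and the predictive query equals w0.
    """
    w0 = np.asarray(w0, dtype=float)
    w1 = np.zeros_like(w0) if graph == "G0" else np.asarray(w1, dtype=float)
    p1 = _p_e_given_c(w0, w1, valence)
    if direction == "predictive":
        out = p1
    elif direction == "diagnostic":
        if not 0.0 < base_rate_c < 1.0:
            raise ValueError("diagnostic query needs base_rate_c in (0, 1)")
        num = p1 * base_rate_c
        den = num + w0 * (1.0 - base_rate_c)
        with np.errstate(invalid="ignore"):
            out = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), np.nan)
        if np.ndim(out) == 0 and np.isnan(out):
            raise ZeroDivisionError("diagnostic query undefined: P(e) = 0")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if np.ndim(out) == 0 else out


def structure_induction_predict(
    table: ContingencyTable,
    direction: Direction,
    prior: PriorSpec = PriorSpec(),
    grid: Grid = Grid(),
    base_rate_c: float = 0.5,
    valence: Valence = "generative",
) -> float:
    """Structure induction model prediction for a diagnostic/predictive query.

    Weighted average over {G0, G1} of the posterior-mean query probability
    within each graph, weights given by the structure posterior.
    """
    if valence != "generative":
        raise NotApplicableError("structure induction model covers generative valence only")
    sp = structure_posterior(table, prior, grid, valence)
    w = grid.nodes
    # G1-conditional posterior mean of the query
    post1 = _posterior_2d(table, prior, grid, valence)
    w0g, w1g = np.meshgrid(w, w, indexing="ij")
    q1 = query_probability(w0g, w1g, "G1", direction, valence, base_rate_c)
    q1 = np.nan_to_num(q1, nan=base_rate_c)  # P(e)=0 corner of the grid
    v1 = _posterior_mean_2d(q1, post1, grid)
    # G0-conditional: diagnostic is the base rate; predictive is E[w0 | data, G0]
    if direction == "diagnostic":
        v0 = base_rate_c
    else:
        lik0 = _likelihood_grid(table, grid, valence, "G0") * _prior_1d(prior, grid, valence)
        v0 = float(np.trapezoid(w * lik0, w) / np.trapezoid(lik0, w))
    return sp["p_g1"] * v1 + sp["p_g0"] * v0


def mle_params(
    table: ContingencyTable, valence: Valence = "generative"
) -> tuple[float, float]:
    """Closed-form MLE (w0, w1) = (P(e|not c), causal power)."""
    stats = contingency_stats(table)
    return stats["p_e_given_notc"], causal_power(table, valence)


def _attribution(w0, w1):
    num = np.asarray(w1, dtype=float)
    den = np.asarray(w0 + w1 - w0 * w1, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), np.nan)
    return out


def causal_attribution(
    table: ContingencyTable,
    estimation: Literal["MLE", "bayes_uniform", "bayes_SS"] = "MLE",
    grid: Grid = Grid(),
    valence: Valence = "generative",
    alpha: float = 5.0,
) -> float:
    """Probability the candidate cause produced an observed effect.

    attribution = w1 / (w0 + w1 - w0*w1), evaluated at the MLE or averaged
    over the G1 parameter posterior.
    """
    if valence != "generative":
        raise NotApplicableError("causal attribution covers generative valence only")
    if estimation == "MLE":
        w0, w1 = mle_params(table, valence)
        a = _attribution(w0, w1)
        if np.isnan(a):
            raise ZeroDivisionError("attribution undefined: P(e|c) = 0 at the MLE")
        return float(a)
    prior = PriorSpec("uniform") if estimation == "bayes_uniform" else PriorSpec("SS", alpha)
    post = _posterior_2d(table, prior, grid, valence)
    w0g, w1g = np.meshgrid(grid.nodes, grid.nodes, indexing="ij")
    a = np.nan_to_num(_attribution(w0g, w1g), nan=0.0)  # w0=w1=0 corner, measure zero
    return _posterior_mean_2d(a, post, grid)


# ---------------------------------------------------------------------------
# Model-variant registry


@dataclass(frozen=True)
class ModelVariant:
    """One model family paired with one estimation method."""

    family: str
    estimation: str
    applicable_valences: tuple[Valence, ...] = VALENCES

    @property
    def name(self) -> str:
        return f"{self.family}:{self.estimation}"


_FAMILIES = (
    "power",
    "attribution",
    "structure_induction_diagnostic",
    "structure_induction_predictive",
    "conditional_diagnostic",
    "conditional_predictive",
)
_GENERATIVE_ONLY = ("attribution", "structure_induction_diagnostic", "structure_induction_predictive")


def default_registry() -> list[ModelVariant]:
    """The default 16 model/estimation combinations.

    Power, attribution and the two structure-induction families each appear
    with MLE, Bayesian-uniform and Bayesian-SS estimation (12); the two plain
    conditional-probability families appear with MLE and Bayesian-uniform
    estimation (4). Attribution and structure induction are defined for
    generative valence only.
    """
    variants: list[ModelVariant] = []
    for family in ("power", "attribution", "structure_induction_diagnostic",
                   "structure_induction_predictive"):
        for est in ("MLE", "bayes_uniform", "bayes_SS"):
            val = ("generative",) if family in _GENERATIVE_ONLY else VALENCES
            variants.append(ModelVariant(family, est, val))
    for family in ("conditional_diagnostic", "conditional_predictive"):
        for est in ("MLE", "bayes_uniform"):
            variants.append(ModelVariant(family, est, VALENCES))
    return variants


def _prior_for(estimation: str, alpha: float, structure_prior_g1: float) -> PriorSpec:
    kind = "SS" if estimation == "bayes_SS" else "uniform"
    return PriorSpec(kind, alpha, structure_prior_g1)


def _conditional_prediction(
    table: ContingencyTable,
    direction: Direction,
    estimation: str,
    base_rate_c: float,
) -> float:
    """Plain conditional-probability model: empirical or beta-smoothed P.

    Bayesian-uniform estimation places independent uniform priors on
    P(e|c) and P(e|not c) and reports the posterior mean of the query.
    """
    if estimation == "MLE":
        s = contingency_stats(table)
        p1, p0 = s["p_e_given_c"], s["p_e_given_notc"]
        if direction == "predictive":
            return p1
        den = p1 * base_rate_c + p0 * (1.0 - base_rate_c)
        if den == 0.0:
            raise ZeroDivisionError("diagnostic query undefined: P(e) = 0")
        return p1 * base_rate_c / den
    # posterior means under Beta(1,1) priors
    a1 = (table.n_e1c1 + 1) / (table.n_c1 + 2)
    a0 = (table.n_e1c0 + 1) / (table.n_c0 + 2)
    if direction == "predictive":
        return a1
    return a1 * base_rate_c / (a1 * base_rate_c + a0 * (1.0 - base_rate_c))


def _si_mle_prediction(
    table: ContingencyTable,
    direction: Direction,
    valence: Valence,
    base_rate_c: float,
) -> float:
    """MLE analog of structure induction: pick the ML graph, query at its MLE."""
    w0_hat, w1_hat = mle_params(table, valence)
    ll1 = data_likelihood(table, w0_hat, w1_hat, valence, "G1", log=True)
    s = contingency_stats(table)
    p_pooled = (table.n_e1c1 + table.n_e1c0) / table.n_total
    ll0 = data_likelihood(table, p_pooled, 0.0, valence, "G0", log=True)
    if ll1 >= ll0:
        return query_probability(w0_hat, w1_hat, "G1", direction, valence, base_rate_c)
    return query_probability(p_pooled, 0.0, "G0", direction, valence, base_rate_c)


def predict_one(
    variant: ModelVariant,
    table: ContingencyTable,
    valence: Valence,
    grid: Grid = Grid(),
    alpha: float = 5.0,
    structure_prior_g1: float = 0.5,
    base_rate_c: float = 0.5,
) -> float:
    """Prediction of one variant for one condition, on [0, 1]."""
    if valence not in variant.applicable_valences:
        raise NotApplicableError(f"{variant.name} not defined for {valence} valence")
    fam, est = variant.family, variant.estimation
    if fam == "power":
        if est == "MLE":
            return causal_power(table, valence)
        return posterior_strength(table, _prior_for(est, alpha, structure_prior_g1), grid, valence)
    if fam == "attribution":
        return causal_attribution(table, est, grid, valence, alpha)
    if fam.startswith("structure_induction"):
        direction: Direction = "diagnostic" if fam.endswith("diagnostic") else "predictive"
        if est == "MLE":
            return _si_mle_prediction(table, direction, valence, base_rate_c)
        prior = _prior_for(est, alpha, structure_prior_g1)
        return structure_induction_predict(table, direction, prior, grid, base_rate_c, valence)
    if fam.startswith("conditional"):
        direction = "diagnostic" if fam.endswith("diagnostic") else "predictive"
        return _conditional_prediction(table, direction, est, base_rate_c)
    raise ValueError(f"unknown model family {fam!r}")


def enumerate_variants(
    tables: dict[tuple[str, Valence], ContingencyTable],
    registry: Sequence[ModelVariant] | None = None,
    grid: Grid = Grid(),
    alpha: float = 5.0,
    structure_prior_g1: float = 0.5,
    base_rate_c: float = 0.5,
) -> pd.DataFrame:
    """Predictions of every variant for every (condition, valence) table.

    Parameters
    ----------
    tables
        Mapping from (condition label, valence) to its contingency table.
    registry
        Model variants to evaluate; defaults to :func:`default_registry`.

    Returns
    -------
    DataFrame with columns variant, family, estimation, condition, valence,
    prediction, sorted by (variant, condition, valence). Rows for valences a
    family does not cover are absent.
    """
    if registry is None:
        registry = default_registry()
    rows = []
    for variant in registry:
        for (condition, valence), table in tables.items():
            if valence not in variant.applicable_valences:
                continue
            pred = predict_one(variant, table, valence, grid, alpha,
                               structure_prior_g1, base_rate_c)
            rows.append(
                {
                    "variant": variant.name,
                    "family": variant.family,
                    "estimation": variant.estimation,
                    "condition": condition,
                    "valence": valence,
                    "prediction": pred,
                }
            )
    frame = pd.DataFrame(rows)
    return frame.sort_values(["variant", "condition", "valence"], ignore_index=True)


def predictions_frame(
    registry: Sequence[ModelVariant] | None = None, **kwargs
) -> pd.DataFrame:
    """Predictions over the full stimulus set (3 covariance x 2 valence)."""
    from causalq.synthetic import stimulus_tables

    return enumerate_variants(stimulus_tables(), registry, **kwargs)
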