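"""Stimulus contingencies and synthetic rating data.

The stimulus builder reproduces the three covariance conditions of the
gene/protein judgment task: two sets of 16 DNA strands (exposed / unexposed,
32 in total), with effect base rates

    generative  C1: P(E+|C-)=0.25, P(E+|C+)=0.50
                C2: P(E+|C-)=0.50, P(E+|C+)=0.75
                C3: P(E+|C-)=0.25, P(E+|C+)=0.75

and the two conditional probabilities swapped in the preventive valence.

The rating generator draws best estimates from the same beta GLM the
analysis module fits (logit location + log precision submodels, subject
random intercepts, effects coding), so parameter-recovery round trips are
exact by construction. Interval estimates are phenomenological: best-estimate
+/- a beta-distributed half-width, truncated to the response scale, with a
configurable fraction of invalid (min > max) pairs produced by swapping the
bounds. Study 2B adds a per-subject belief in the temporal precedence of the
cause that enters the location predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from causalq.beta_glm import DesignSpec, build_design_matrix
from causalq.causal_models import ContingencyTable, Valence, VALENCES

__all__ = [
    "StudyDesign",
    "TrueParams",
    "build_contingency",
    "stimulus_tables",
    "stimulus_strands",
    "generate_ratings",
    "filter_valid",
    "interval_widths",
    "study1_design",
    "study2a_design",
    "study2b_design",
    "default_true_params",
]

STRANDS_PER_SET = 16

# text-authoritative conditional probabilities, generative valence
_GENERATIVE_PROBS: dict[str, tuple[float, float]] = {
    # condition: (P(E+|C+), P(E+|C-))
    "C1": (0.50, 0.25),
    "C2": (0.75, 0.50),
    "C3": (0.75, 0.25),
}

QUESTIONS_S1 = ("structure", "strength", "predictive")
COVARIANCES = ("C1", "C2", "C3")


def build_contingency(condition: str, valence: Valence = "generative") -> ContingencyTable:
    """Contingency table for one covariance condition and valence.

    Counts are the condition's conditional probabilities times 16 strands per
    set; the preventive table is the generative one with P(E+|C+) and
    P(E+|C-) exchanged.
    """
    if condition not in _GENERATIVE_PROBS:
        raise ValueError(f"unknown covariance condition {condition!r}")
    p1, p0 = _GENERATIVE_PROBS[condition]
    if valence == "preventive":
        p1, p0 = p0, p1
    elif valence != "generative":
        raise ValueError(f"unknown valence {valence!r}")
    e1c1 = round(p1 * STRANDS_PER_SET)
    e1c0 = round(p0 * STRANDS_PER_SET)
    return ContingencyTable(e1c1, STRANDS_PER_SET - e1c1, e1c0, STRANDS_PER_SET - e1c0)


def stimulus_tables() -> dict[tuple[str, Valence], ContingencyTable]:
    """All six (condition, valence) contingency tables."""
    return {
        (c, v): build_contingency(c, v) for c in COVARIANCES for v in VALENCES
    }


def stimulus_strands(condition: str, valence: Valence = "generative") -> pd.DataFrame:
    """Per-strand display frame: 32 rows of (set, gene_state).

    The exposed and unexposed sets each hold 16 strands whose on/off counts
    reproduce the condition's contingency exactly.
    """
    t = build_contingency(condition, valence)
    rows = (
        [("exposed", 1)] * t.n_e1c1
        + [("exposed", 0)] * t.n_e0c1
        + [("unexposed", 1)] * t.n_e1c0
        + [("unexposed", 0)] * t.n_e0c0
    )
    return pd.DataFrame(rows, columns=["set", "gene_state"])


@dataclass(frozen=True)
class StudyDesign:
    """Factor layout of one study arm.

    ``between`` maps factor name -> (levels, subjects per level); ``within``
    maps factor name -> levels crossed within subject. ``question`` appears
    in one of the two maps depending on the study.
    """

    study: str
    between: Mapping[str, tuple[tuple[str, ...], tuple[int, ...]]]
    within: Mapping[str, tuple[str, ...]]
    covariance: tuple[str, ...] = COVARIANCES
    precedence_belief: bool = False


def study1_design(
    n_generative: int = 38, n_preventive: int = 35
) -> StudyDesign:
    """Study 1: valence between subjects; covariance and question within."""
    return StudyDesign(
        study="S1",
        between={"valence": (VALENCES, (n_generative, n_preventive))},
        within={"covariance": COVARIANCES, "question": QUESTIONS_S1},
    )


def study2a_design(n_per_cell: int = 25) -> StudyDesign:
    """Study 2A: valence x reasoning direction between subjects, C3 only."""
    return StudyDesign(
        study="S2A",
        between={
            "valence": (VALENCES, (2 * n_per_cell, 2 * n_per_cell)),
            "question": (("diagnostic", "predictive"), (2 * n_per_cell, 2 * n_per_cell)),
        },
        within={"covariance": ("C3",)},
        covariance=("C3",),
    )


def study2b_design(n_cue: int = 40, n_no_cue: int = 117) -> StudyDesign:
    """Study 2B: diagnostic question with/without a temporal-precedence cue,
    C3 only; no-cue subjects also report a precedence belief."""
    return StudyDesign(
        study="S2B",
        between={
            "valence": (VALENCES, None),
            "tpc_cue": (("cue", "no_cue"), (n_cue, n_no_cue)),
        },
        within={"covariance": ("C3",)},
        covariance=("C3",),
        precedence_belief=True,
    )


@dataclass(frozen=True)
class TrueParams:
    """Generating truth for synthetic ratings.

    ``b`` and ``d`` map design-matrix column names (as produced by
    :func:`causalq.beta_glm.build_design_matrix`) to location / log-precision
    coefficients; unnamed columns default to 0. Half-widths of the interval
    estimates are ``width_scale * Beta(width_a, width_b)`` on the rating
    scale.
    """

    b: Mapping[str, float] = field(default_factory=dict)
    d: Mapping[str, float] = field(default_factory=dict)
    sigma_u: float = 0.3
    invalid_interval_rate: float = 0.033
    precedence_belief_effect: float = 2.25
    width_scale: float = 60.0
    width_a: float = 2.0
    width_b: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.invalid_interval_rate < 0.5:
            raise ValueError("invalid_interval_rate must lie in [0, 0.5)")


def default_true_params() -> TrueParams:
    """Generator defaults emulating the qualitative Study 1 pattern.

    Location: grand mean near 56 on the 0-100 scale, C3 rated above and C2
    below the grand mean, slightly higher ratings for the strength question
    and lower for the predictive question, preventive slightly below
    generative. Precision: predictive questions are by far the most dispersed
    and strength the least (dispersion ordering predictive > structure >
    strength), and preventive ratings are more homogeneous than generative.
    Coefficients are on the logit (location) and log-precision scales under
    effects coding with references generative / C1 / structure.
    """
    return TrueParams(
        b={
            "intercept": 0.26,
            "preventive": -0.06,
            "C2": -0.13,
            "C3": 0.27,
            "strength": 0.06,
            "predictive": -0.06,
        },
        d={
            "intercept": 2.2,
            "preventive": 0.29,
            "C2": -0.17,
            "C3": 0.07,
            "strength": 0.19,
            "predictive": -0.18,
        },
        sigma_u=0.57,
    )


def dispersion_study_params() -> TrueParams:
    """Generating truth for the question-format dispersion mechanism study.

    A controlled condition in which question format manipulates only the
    homogeneity of the ratings, not their mean: group means are fixed across
    questions while the log-precision levels are separated by one unit per
    step (strength +1, structure 0, predictive -1 around a base of 1.4), so
    raw rating SDs run from roughly 15 points (strength) to over 30 points
    (predictive) — the heteroscedasticity regime in which any deterministic
    model's squared error is dominated by rating variance. The separation is
    sized so the induced MSE ordering clears the sampling noise of a
    73-subject design even for the model variants with the largest bias and
    the fewest applicable records.
    """
    return TrueParams(
        b={"intercept": 0.5, "preventive": -0.06, "C2": -0.13, "C3": 0.27},
        d={"intercept": 1.4, "preventive": 0.29, "strength": 1.0, "predictive": -1.0},
        sigma_u=0.3,
    )


def _subject_frame(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    """One row per subject with between-subject factor assignments."""
    factors = list(design.between.items())
    name0, (levels0, counts0) = factors[0]
    if design.study == "S2B":
        # cue cell sizes fixed; valence split near-evenly at random within cell
        _, (cue_levels, cue_counts) = ("tpc_cue", design.between["tpc_cue"])
        rows = []
        sid = 0
        for lvl, n in zip(cue_levels, cue_counts):
            for _ in range(n):
                rows.append({"subject": f"s{sid:04d}", "tpc_cue": lvl,
                             "valence": VALENCES[sid % 2]})
                sid += 1
        return pd.DataFrame(rows)
    if len(factors) == 1:
        rows = []
        sid = 0
        for lvl, n in zip(levels0, counts0):
            for _ in range(n):
                rows.append({"subject": f"s{sid:04d}", name0: lvl})
                sid += 1
        return pd.DataFrame(rows)
    # fully crossed between design (S2A): equal cells
    name1, (levels1, _) = factors[1]
    total = sum(counts0)
    per_cell = total // (len(levels0) * len(levels1))
    rows = []
    sid = 0
    for l0 in levels0:
        for l1 in levels1:
            for _ in range(per_cell):
                rows.append({"subject": f"s{sid:04d}", name0: l0, name1: l1})
                sid += 1
    return pd.DataFrame(rows)


def generate_ratings(
    design: StudyDesign,
    truth: TrueParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic rating records for one study arm.

    Returns a DataFrame with columns subject, valence, covariance, question,
    best, min, max (and precedence_belief / tpc_cue for Study 2B), one row
    per subject x within-cell. Best estimates are drawn from the beta GLM at
    the record's factor combination; a fraction ``invalid_interval_rate`` of
    interval pairs is swapped to be invalid (min > max).
    """
    if truth is None:
        truth = default_true_params()
    rng = np.random.default_rng(seed)
    subjects = _subject_frame(design, rng)

    # expand within-subject cells
    records = subjects.copy()
    for name, levels in design.within.items():
        if name in records.columns:
            continue
        records = records.merge(pd.DataFrame({name: list(levels)}), how="cross")
    if "covariance" not in records.columns:
        records = records.merge(pd.DataFrame({"covariance": list(design.covariance)}), how="cross")
    if "question" not in records.columns:
        records["question"] = "diagnostic"

    if design.precedence_belief:
        beliefs = dict(zip(subjects["subject"], rng.uniform(0, 1, len(subjects))))
        records["precedence_belief"] = records["subject"].map(beliefs)

    # linear predictors via the same effects coding the analysis uses
    factor_levels = {
        "valence": tuple(VALENCES),
        "covariance": COVARIANCES,
        "question": tuple(dict.fromkeys(records["question"]))
        if records["question"].nunique() > 1
        else ("diagnostic", "_unused"),
        "tpc_cue": ("cue", "no_cue"),
    }
    loc_terms = [t for t in ("valence", "covariance", "question", "tpc_cue")
                 if t in records.columns and records[t].nunique() > 1]
    spec = DesignSpec(tuple(loc_terms), tuple(loc_terms), factor_levels)
    X = build_design_matrix(records, spec.location_terms, spec)
    Z = build_design_matrix(records, spec.precision_terms, spec)

    eta_mu = sum(truth.b.get(c, 0.0) * X[c].to_numpy() for c in X.columns)
    eta_phi = sum(truth.d.get(c, 0.0) * Z[c].to_numpy() for c in Z.columns)
    if design.precedence_belief:
        no_cue = (records["tpc_cue"] == "no_cue").to_numpy()
        centered = records["precedence_belief"].to_numpy() - 0.5
        eta_mu = eta_mu + truth.precedence_belief_effect * centered * no_cue

    u = rng.normal(0.0, truth.sigma_u, len(subjects)) if truth.sigma_u > 0 else np.zeros(len(subjects))
    subj_codes = pd.Categorical(records["subject"]).codes
    mu = expit(eta_mu + u[subj_codes])
    phi = np.exp(eta_phi)
    best01 = rng.beta(mu * phi, (1.0 - mu) * phi)
    best = 100.0 * best01

    half = truth.width_scale * rng.beta(truth.width_a, truth.width_b, len(records)) / 2.0
    lo = np.clip(best - half, 0.0, 100.0)
    hi = np.clip(best + half, 0.0, 100.0)
    swap = (rng.random(len(records)) < truth.invalid_interval_rate) & (hi > lo)
    records["best"] = best
    records["min"] = np.where(swap, hi, lo)
    records["max"] = np.where(swap, lo, hi)

    lead = [c for c in ("subject", "valence", "covariance", "question", "tpc_cue",
                        "precedence_belief") if c in records.columns]
    return records[lead + ["best", "min", "max"]].reset_index(drop=True)


def filter_valid(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop records whose minimum estimate exceeds the maximum.

    Returns (valid records in original order, number removed).
    """
    ok = records["min"] <= records["max"]
    return records[ok].reset_index(drop=True), int((~ok).sum())


def interval_widths(records: pd.DataFrame) -> np.ndarray:
    """max - min per record; records must already be valid."""
    w = records["max"].to_numpy() - records["min"].to_numpy()
    if np.any(w < 0):
        raise ValueError("invalid records present (min > max); filter first")
    return w
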