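"""Synthetic two-trial ecosystems with known treatment-effect truth.

Real MAIC analyses compare an index treatment (with participant-level
data from placebo-controlled trials) against a comparator treatment
(with published aggregate results from its own placebo-controlled
trial).  Neither data set is public here, so this module generates the
whole ecosystem: covariates mimicking a smoking-cessation population
(a binary race indicator, cigarettes smoked per day, age, and the two
0-21 HADS subscales), binary outcomes of abstinence and adverse-event
type, and — crucially — *controlled effect modification*: treatment-by-
covariate interactions on the log-odds scale, so that shifting a
covariate's distribution between the two trial populations induces a
known bias in naive indirect comparisons that population adjustment
should remove.

The outcome model for participant i with covariates x and treatment
indicator T is

    logit P(y=1) = b0 + sum_j g_j (x_j - r_j) + T [bt + sum_j m_j (x_j - r_j)]

with prognostic coefficients g, treatment main effect bt, interaction
(modifier) coefficients m, and reference values r fixed at the index
population's covariate means — so bt is the index-population
conditional effect and interactions express how the effect drifts as
the population moves.

Everything is a pure function of (config, seed); per-trial child
streams are derived from the root seed by position so adding a trial
never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .errors import ConfigurationError, ValidationError
from .trial_data import (
    ARM_ACTIVE,
    ARM_CONTROL,
    AggregateTarget,
    ComparatorEffect,
    IPDTable,
)

COVARIATES = ("race", "cigarettes_per_day", "age", "hads_anxiety", "hads_depression")


@dataclass(frozen=True)
class CovariateModel:
    """Distributional law of one trial population's baseline covariates.

    ``cigarettes_per_day`` is a shifted lognormal (the shift encodes the
    >= 10 cigarettes/day eligibility floor); ``age`` is normal truncated
    to (18, 80); HADS subscales are Binomial(21, q).
    """

    race_p: float = 0.25
    cigs_log_mean: float = 2.2
    cigs_log_sd: float = 0.5
    cigs_shift: float = 10.0
    age_mean: float = 46.0
    age_sd: float = 11.0
    hads_anxiety_q: float = 0.22
    hads_depression_q: float = 0.15

    def __post_init__(self):
        for name, p in (
            ("race_p", self.race_p),
            ("hads_anxiety_q", self.hads_anxiety_q),
            ("hads_depression_q", self.hads_depression_q),
        ):
            if not (0.0 < p < 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1), got {p!r}")
        if self.cigs_log_sd <= 0 or self.age_sd <= 0:
            raise ConfigurationError("scale parameters must be positive")

    @property
    def cigs_mean(self) -> float:
        return self.cigs_shift + math.exp(self.cigs_log_mean + self.cigs_log_sd**2 / 2)

    @property
    def cigs_sd(self) -> float:
        s2 = self.cigs_log_sd**2
        return math.exp(self.cigs_log_mean + s2 / 2) * math.sqrt(math.expm1(s2))

    def draw(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        lo = (18.0 - self.age_mean) / self.age_sd
        hi = (80.0 - self.age_mean) / self.age_sd
        return pd.DataFrame(
            {
                "race": rng.binomial(1, self.race_p, n).astype(float),
                "cigarettes_per_day": np.minimum(
                    self.cigs_shift
                    + rng.lognormal(self.cigs_log_mean, self.cigs_log_sd, n),
                    199.0,
                ),
                "age": truncnorm.rvs(
                    lo, hi, loc=self.age_mean, scale=self.age_sd, size=n,
                    random_state=rng,
                ),
                "hads_anxiety": rng.binomial(21, self.hads_anxiety_q, n).astype(float),
                "hads_depression": rng.binomial(21, self.hads_depression_q, n).astype(float),
            }
        )

    def theoretical_means(self) -> dict[str, float]:
        return {
            "race": self.race_p,
            "cigarettes_per_day": self.cigs_mean,
            "age": self.age_mean,  # truncation at +-3 SD shifts the mean negligibly
            "hads_anxiety": 21 * self.hads_anxiety_q,
            "hads_depression": 21 * self.hads_depression_q,
        }


@dataclass(frozen=True)
class OutcomeModel:
    """Log-odds outcome model for one binary endpoint.

    ``treatment_effects`` maps a treatment name to its conditional main
    effect at the reference covariate values; ``interactions`` maps a
    treatment name to per-covariate modifier coefficients.  Prognostic
    coefficients act in both arms.
    """

    control_log_odds: float
    treatment_effects: Mapping[str, float] = field(default_factory=dict)
    interactions: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    prognostic: Mapping[str, float] = field(default_factory=dict)

    def linear_predictor(
        self,
        x: pd.DataFrame,
        treated: np.ndarray,
        treatment: str,
        reference: Mapping[str, float],
    ) -> np.ndarray:
        lp = np.full(len(x), self.control_log_odds)
        for cov, g in self.prognostic.items():
            lp += g * (x[cov].to_numpy() - reference[cov])
        effect = np.full(len(x), self.treatment_effects.get(treatment, 0.0))
        for cov, m in self.interactions.get(treatment, {}).items():
            effect += m * (x[cov].to_numpy() - reference[cov])
        return lp + treated * effect


@dataclass(frozen=True)
class TrialSpec:
    """One two-arm placebo-controlled trial: who is enrolled, what is tested."""

    trial_id: str
    treatment: str
    n_per_arm: int
    covariates: CovariateModel

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ConfigurationError(
                f"trial {self.trial_id!r}: need n_per_arm >= 2, got {self.n_per_arm}"
            )


@dataclass(frozen=True)
class ScenarioConfig:
    """A full two-population study scenario with known truth.

    ``index_trials`` carry IPD for the index treatment; ``comparator``
    is the aggregate-only trial of the comparator treatment.
    ``reference`` fixes the covariate values at which treatment main
    effects are defined (defaults to the first index trial's theoretical
    covariate means).
    """

    index_trials: tuple[TrialSpec, ...]
    comparator: TrialSpec
    outcomes: Mapping[str, OutcomeModel]
    seed: int
    reference: Mapping[str, float] | None = None

    def __post_init__(self):
        if not self.index_trials:
            raise ConfigurationError("need at least one index trial")
        ids = [t.trial_id for t in self.all_trials]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate trial ids: {ids}")
        if not self.outcomes:
            raise ConfigurationError("need at least one outcome model")
        if self.reference is None:
            object.__setattr__(
                self, "reference", self.index_trials[0].covariates.theoretical_means()
            )

    @property
    def all_trials(self) -> tuple[TrialSpec, ...]:
        return self.index_trials + (self.comparator,)

    def trial(self, trial_id: str) -> tuple[int, TrialSpec]:
        for i, t in enumerate(self.all_trials):
            if t.trial_id == trial_id:
                return i, t
        raise ConfigurationError(f"unknown trial id {trial_id!r}")


def _trial_rng(config: ScenarioConfig, trial_index: int) -> np.random.Generator:
    # child stream keyed by position: stable under edits to later trials
    return np.random.default_rng([int(config.seed), trial_index])


def generate_trial(config: ScenarioConfig, trial_id: str) -> IPDTable:
    """Draw one trial's IPD; identical output on identical (config, seed)."""
    idx, spec = config.trial(trial_id)
    rng = _trial_rng(config, idx)
    n = 2 * spec.n_per_arm
    x = spec.covariates.draw(n, rng)
    treated = np.zeros(n)
    treated[: spec.n_per_arm] = 1.0
    df = pd.DataFrame(
        {
            "patient_id": [f"{trial_id}-{i:05d}" for i in range(n)],
            "trial_id": trial_id,
            "arm": np.where(treated == 1, ARM_ACTIVE, ARM_CONTROL),
        }
    )
    df = pd.concat([df, x], axis=1)
    outcome_names = tuple(config.outcomes)
    for name in outcome_names:
        model = config.outcomes[name]
        p = expit(model.linear_predictor(x, treated, spec.treatment, config.reference))
        df[name] = rng.binomial(1, p).astype(float)
    return IPDTable(df, COVARIATES, outcome_names)


def generate_index_ipd(config: ScenarioConfig) -> IPDTable:
    """Pooled IPD across all index trials."""
    tables = [generate_trial(config, t.trial_id) for t in config.index_trials]
    df = pd.concat([t.data for t in tables], ignore_index=True)
    return IPDTable(df, tables[0].covariate_names, tables[0].outcome_names)


def summarize_to_target(
    ipd: IPDTable, label: str = "comparator", effect_form: str = "counts"
) -> tuple[AggregateTarget, dict[str, ComparatorEffect]]:
    """Collapse a trial's IPD into the aggregate view a MAIC consumes.

    Returns covariate means/variances as an :class:`AggregateTarget` and
    one :class:`ComparatorEffect` per outcome — in ``counts`` form, or in
    ``lor_se`` form via the Woolf estimator on the same 2x2 table.
    """
    if effect_form not in ("counts", "lor_se"):
        raise ValidationError(f"effect_form must be 'counts' or 'lor_se', got {effect_form!r}")
    df = ipd.data
    for arm in (ARM_ACTIVE, ARM_CONTROL):
        if not (df["arm"] == arm).any():
            raise ValidationError(f"cannot summarize: no participants in arm '{arm}'")
    target = AggregateTarget(
        population_label=label,
        means={c: float(df[c].mean()) for c in ipd.covariate_names},
        variances={c: float(df[c].var(ddof=1)) for c in ipd.covariate_names},
        sample_size=len(df),
    )
    comparators: dict[str, ComparatorEffect] = {}
    for out in ipd.outcome_names:
        counts = ipd.counts_2x2(out)
        if effect_form == "counts":
            comparators[out] = ComparatorEffect(label=f"{label}:{out}", counts=counts)
        else:
            from .effect_models import log_or_from_counts

            est = log_or_from_counts(counts)
            comparators[out] = ComparatorEffect(
                label=f"{label}:{out}", log_or=est.log_or, se=est.se
            )
    return target, comparators


def true_marginal_log_or(
    config: ScenarioConfig,
    outcome: str,
    population: str = "comparator",
    treatment: str | None = None,
    reps: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo truth: the marginal log OR of a treatment in a population.

    Draws ``reps`` covariate vectors from the named population's law
    (``"index"`` = the first index trial, ``"comparator"``), averages the
    event probability under T=1 and T=0, and returns the logit
    difference together with its linearised Monte-Carlo standard error.
    Marginal and conditional ORs differ when prognostic or interaction
    terms are present (non-collapsibility), which is why this oracle
    simulates instead of reading coefficients.
    """
    if outcome not in config.outcomes:
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    if population == "index":
        spec = config.index_trials[0]
    elif population == "comparator":
        spec = config.comparator
    else:
        raise ConfigurationError(f"population must be 'index' or 'comparator', got {population!r}")
    if treatment is None:
        treatment = spec.treatment
    model = config.outcomes[outcome]
    rng = np.random.default_rng([int(seed), 104729])  # oracle stream, separate from trials
    x = spec.covariates.draw(int(reps), rng)
    ones = np.ones(len(x))
    q1 = expit(model.linear_predictor(x, ones, treatment, config.reference))
    q0 = expit(model.linear_predictor(x, np.zeros(len(x)), treatment, config.reference))
    p1, p0 = float(q1.mean()), float(q0.mean())
    lor = float(logit(p1) - logit(p0))
    # delta method on the shared covariate draws
    h = q1 / (p1 * (1 - p1)) - q0 / (p0 * (1 - p0))
    mc_se = float(np.std(h, ddof=1) / math.sqrt(len(h)))
    return lor, mc_se


def true_itc_log_or(
    config: ScenarioConfig, outcome: str, reps: int = 200_000, seed: int = 0
) -> tuple[float, float]:
    """Truth for the anchored ITC estimand: index-vs-comparator marginal
    log OR in the *comparator* population (the population the MAIC
    adjusts towards)."""
    d_index, se1 = true_marginal_log_or(
        config, outcome, population="comparator",
        treatment=config.index_trials[0].treatment, reps=reps, seed=seed,
    )
    d_cmp, se2 = true_marginal_log_or(
        config, outcome, population="comparator",
        treatment=config.comparator.treatment, reps=reps, seed=seed + 1,
    )
    return d_index - d_cmp, math.hypot(se1, se2)


# ---------------------------------------------------------------------------
# Canonical scenarios

INDEX_TREATMENT = "index_active"
COMPARATOR_TREATMENT = "comparator_active"

_INDEX_COVARIATES = CovariateModel()
_COMPARATOR_COVARIATES = CovariateModel(
    race_p=0.32,
    cigs_log_mean=2.35,
    age_mean=47.0,
    age_sd=12.0,
    hads_anxiety_q=0.25,
    hads_depression_q=0.17,
)


def _default_outcomes() -> dict[str, OutcomeModel]:
    ln = math.log
    # abstinence-type outcomes: treatment raises the odds of quitting;
    # heavier smoking is prognostic of failure and modifies the index
    # treatment's effect.  TEAE-type outcomes: asymmetric by treatment
    # (the comparator drug is markedly more nauseogenic).
    return {
        "abstinence_9_12": OutcomeModel(
            control_log_odds=logit(0.09),
            treatment_effects={INDEX_TREATMENT: ln(2.6), COMPARATOR_TREATMENT: ln(2.2)},
            prognostic={"cigarettes_per_day": -0.03},
            interactions={INDEX_TREATMENT: {"cigarettes_per_day": 0.02}},
        ),
        "abstinence_9_24": OutcomeModel(
            control_log_odds=logit(0.06),
            treatment_effects={INDEX_TREATMENT: ln(2.4), COMPARATOR_TREATMENT: ln(1.7)},
            prognostic={"cigarettes_per_day": -0.03},
            interactions={INDEX_TREATMENT: {"cigarettes_per_day": 0.02}},
        ),
        "nausea": OutcomeModel(
            control_log_odds=logit(0.06),
            treatment_effects={INDEX_TREATMENT: ln(1.4), COMPARATOR_TREATMENT: ln(4.5)},
        ),
        "insomnia": OutcomeModel(
            control_log_odds=logit(0.07),
            treatment_effects={INDEX_TREATMENT: ln(1.5), COMPARATOR_TREATMENT: ln(1.3)},
        ),
        "abnormal_dreams": OutcomeModel(
            control_log_odds=logit(0.05),
            treatment_effects={INDEX_TREATMENT: ln(1.3), COMPARATOR_TREATMENT: ln(1.6)},
        ),
        "discontinuation_teae": OutcomeModel(
            control_log_odds=logit(0.025),
            treatment_effects={INDEX_TREATMENT: 0.0, COMPARATOR_TREATMENT: ln(1.1)},
        ),
    }


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """Two index trials of 400/arm, one aggregate comparator of 1000/arm,
    six binary outcomes, mild covariate shift and effect modification."""
    return ScenarioConfig(
        index_trials=(
            TrialSpec("INDEX-1", INDEX_TREATMENT, 400, _INDEX_COVARIATES),
            TrialSpec("INDEX-2", INDEX_TREATMENT, 400, _INDEX_COVARIATES),
        ),
        comparator=TrialSpec("COMPARATOR-1", COMPARATOR_TREATMENT, 1000, _COMPARATOR_COVARIATES),
        outcomes=_default_outcomes(),
        seed=seed,
    )


def null_scenario(seed: int = 0, n_index_per_arm: int = 250, n_comparator_per_arm: int = 500) -> ScenarioConfig:
    """No treatment effects, no interactions, identical populations: the
    ITC truth is exactly zero for every outcome (type-I-error scenario)."""
    cov = CovariateModel()
    outcome = OutcomeModel(
        control_log_odds=logit(0.10),
        treatment_effects={INDEX_TREATMENT: 0.0, COMPARATOR_TREATMENT: 0.0},
    )
    return ScenarioConfig(
        index_trials=(
            TrialSpec("INDEX-1", INDEX_TREATMENT, n_index_per_arm, cov),
            TrialSpec("INDEX-2", INDEX_TREATMENT, n_index_per_arm, cov),
        ),
        comparator=TrialSpec("COMPARATOR-1", COMPARATOR_TREATMENT, n_comparator_per_arm, cov),
        outcomes={"abstinence_9_12": outcome},
        seed=seed,
    )


def shifted_scenario(
    seed: int = 0,
    shift_sd: float = 1.0,
    interaction_per_sd: float = math.log(1.5),
    n_index_per_arm: int = 500,
    n_comparator_per_arm: int = 1000,
) -> ScenarioConfig:
    """Effect-modification scenario: the comparator population smokes
    ``shift_sd`` standard deviations more cigarettes per day, and the
    index treatment's effect grows by ``interaction_per_sd`` per SD.
    Naive anchored comparisons are biased for the comparator-population
    estimand by roughly the product of shift and interaction; moment
    matching on cigarettes/day removes the imbalance."""
    idx_cov = CovariateModel()
    sd = idx_cov.cigs_sd
    shifted_mean = idx_cov.cigs_mean + shift_sd * sd
    # solve the lognormal log-mean that delivers the shifted arithmetic mean
    new_log_mean = math.log(shifted_mean - idx_cov.cigs_shift) - idx_cov.cigs_log_sd**2 / 2
    cmp_cov = replace(idx_cov, cigs_log_mean=new_log_mean)
    outcome = OutcomeModel(
        control_log_odds=logit(0.10),
        treatment_effects={INDEX_TREATMENT: math.log(2.0), COMPARATOR_TREATMENT: math.log(2.0)},
        interactions={INDEX_TREATMENT: {"cigarettes_per_day": interaction_per_sd / sd}},
    )
    return ScenarioConfig(
        index_trials=(
            TrialSpec("INDEX-1", INDEX_TREATMENT, n_index_per_arm, idx_cov),
            TrialSpec("INDEX-2", INDEX_TREATMENT, n_index_per_arm, idx_cov),
        ),
        comparator=TrialSpec("COMPARATOR-1", COMPARATOR_TREATMENT, n_comparator_per_arm, cmp_cov),
        outcomes={"abstinence_9_12": outcome},
        seed=seed,
    )


BUILTIN_SCENARIOS = {
    "default": default_scenario,
    "null": null_scenario,
    "shifted": shifted_scenario,
}


# ---------------------------------------------------------------------------
# Config-dialect (de)serialisation, so scenario files round-trip through YAML


def scenario_to_dict(config: ScenarioConfig) -> dict:
    def trial(t: TrialSpec) -> dict:
        c = t.covariates
        return {
            "trial_id": t.trial_id,
            "treatment": t.treatment,
            "n_per_arm": int(t.n_per_arm),
            "covariates": {
                "race_p": float(c.race_p),
                "cigs_log_mean": float(c.cigs_log_mean),
                "cigs_log_sd": float(c.cigs_log_sd),
                "cigs_shift": float(c.cigs_shift),
                "age_mean": float(c.age_mean),
                "age_sd": float(c.age_sd),
                "hads_anxiety_q": float(c.hads_anxiety_q),
                "hads_depression_q": float(c.hads_depression_q),
            },
        }

    return {
        "seed": int(config.seed),
        "reference": {k: float(v) for k, v in config.reference.items()},
        "index_trials": [trial(t) for t in config.index_trials],
        "comparator": trial(config.comparator),
        "outcomes": {
            name: {
                "control_log_odds": float(m.control_log_odds),
                "treatment_effects": {k: float(v) for k, v in m.treatment_effects.items()},
                "interactions": {
                    k: {c: float(v) for c, v in d.items()}
                    for k, d in m.interactions.items()
                },
                "prognostic": {k: float(v) for k, v in m.prognostic.items()},
            }
            for name, m in config.outcomes.items()
        },
    }


def scenario_from_dict(doc: Mapping) -> ScenarioConfig:
    def trial(d: Mapping) -> TrialSpec:
        return TrialSpec(
            trial_id=str(d["trial_id"]),
            treatment=str(d["treatment"]),
            n_per_arm=int(d["n_per_arm"]),
            covariates=CovariateModel(**d.get("covariates", {})),
        )

    try:
        return ScenarioConfig(
            index_trials=tuple(trial(t) for t in doc["index_trials"]),
            comparator=trial(doc["comparator"]),
            outcomes={
                name: OutcomeModel(
                    control_log_odds=float(m["control_log_odds"]),
                    treatment_effects=dict(m.get("treatment_effects", {})),
                    interactions={k: dict(v) for k, v in m.get("interactions", {}).items()},
                    prognostic=dict(m.get("prognostic", {})),
                )
                for name, m in doc["outcomes"].items()
            },
            seed=int(doc.get("seed", 0)),
            reference=dict(doc["reference"]) if "reference" in doc else None,
        )
    except KeyError as exc:
        raise ConfigurationError(f"scenario config missing key {exc}") from exc
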