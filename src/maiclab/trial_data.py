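"""Domain types, file I/O and validation for anchored indirect comparisons.

The analysis consumes three kinds of evidence:

* individual patient data (IPD) for the *index* trials — one row per
  participant with trial id, randomised arm, baseline covariates and
  binary outcomes;
* an *aggregate target*: the comparator trial's published covariate
  summaries that the IPD will be reweighted to match;
* the comparator trial's *effect evidence* per outcome, either a
  published odds ratio with confidence interval or arm-level 2x2 counts.

Everything here is plain data with validation; no statistics happen in
this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParseError, ValidationError

ARM_ACTIVE = "active"
ARM_CONTROL = "control"
ARMS = (ARM_ACTIVE, ARM_CONTROL)

#: Closed/open range checks for the covariates the weight model understands.
#: ``race`` is a binary indicator (reference group vs not); HADS subscales
#: are 0-21 integers; the remaining ranges are loose sanity bounds.
COVARIATE_RANGES = {
    "race": (0.0, 1.0, True),
    "hads_anxiety": (0.0, 21.0, True),
    "hads_depression": (0.0, 21.0, True),
    "age": (0.0, 120.0, False),
    "cigarettes_per_day": (0.0, 200.0, False),
}

ID_COLUMNS = ("patient_id", "trial_id", "arm")


def _check_covariate_range(name: str, values: pd.Series) -> None:
    if name not in COVARIATE_RANGES:
        return
    lo, hi, closed = COVARIATE_RANGES[name]
    v = values.dropna()
    bad = (v < lo) | (v > hi) if closed else (v <= lo) | (v >= hi)
    if bad.any():
        row = int(bad[bad].index[0])
        raise ValidationError(
            f"covariate '{name}' out of range at row {row}: "
            f"value {v.loc[row]!r} not in {'[' if closed else '('}{lo}, {hi}{']' if closed else ')'}"
        )


@dataclass(frozen=True)
class IPDTable:
    """Validated participant-level data for one or more index trials.

    Parameters
    ----------
    data
        One row per participant.  Must contain ``patient_id``,
        ``trial_id``, ``arm`` plus the named covariate and outcome
        columns.  Outcome values may be missing (NaN); covariates named
        by an active modifier set may not.
    covariate_names, outcome_names
        Which columns are covariates / binary outcomes.
    """

    data: pd.DataFrame
    covariate_names: tuple[str, ...]
    outcome_names: tuple[str, ...]

    def __post_init__(self):
        df = self.data
        for col in ID_COLUMNS + self.covariate_names + self.outcome_names:
            if col not in df.columns:
                raise ValidationError(f"IPD is missing required column '{col}'")
        if df["patient_id"].isna().any() or df["trial_id"].isna().any():
            row = int(df.index[df["patient_id"].isna() | df["trial_id"].isna()][0])
            raise ValidationError(f"missing patient_id/trial_id at row {row}")
        if df["arm"].isna().any():
            row = int(df.index[df["arm"].isna()][0])
            raise ValidationError(f"missing arm at row {row}")
        bad_arm = ~df["arm"].isin(ARMS)
        if bad_arm.any():
            row = int(df.index[bad_arm][0])
            raise ValidationError(
                f"arm must be one of {ARMS} at row {row}: got {df.loc[row, 'arm']!r}"
            )
        for trial, grp in df.groupby("trial_id"):
            for arm in ARMS:
                n = int((grp["arm"] == arm).sum())
                if n < 2:
                    raise ValidationError(
                        f"arm coverage: trial {trial!r} has {n} participant(s) "
                        f"in arm '{arm}' (need >= 2 per arm)"
                    )
        for name in self.covariate_names:
            _check_covariate_range(name, df[name])
        for name in self.outcome_names:
            v = df[name].dropna()
            if not v.isin([0, 1, 0.0, 1.0]).all():
                row = int(v.index[~v.isin([0, 1, 0.0, 1.0])][0])
                raise ValidationError(
                    f"outcome '{name}' must be binary 0/1 at row {row}: got {v.loc[row]!r}"
                )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def trial_ids(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["trial_id"]))

    def require_covariates(self, names: Sequence[str]) -> None:
        """Raise unless every named covariate exists and is fully observed."""
        for name in names:
            if name not in self.covariate_names:
                raise ValidationError(f"covariate '{name}' not present in IPD")
            if self.data[name].isna().any():
                row = int(self.data.index[self.data[name].isna()][0])
                raise ValidationError(
                    f"covariate '{name}' has a missing value at row {row}; "
                    "covariates used for matching must be complete"
                )

    def counts_2x2(self, outcome: str, trial_id: str | None = None) -> tuple[int, int, int, int]:
        """(active events, active non-events, control events, control non-events).

        Missing outcome values are excluded pairwise (complete case per
        outcome).
        """
        if outcome not in self.outcome_names:
            raise ValidationError(f"outcome '{outcome}' not present in IPD")
        df = self.data
        if trial_id is not None:
            df = df[df["trial_id"] == trial_id]
        df = df[df[outcome].notna()]
        a = int(((df["arm"] == ARM_ACTIVE) & (df[outcome] == 1)).sum())
        b = int(((df["arm"] == ARM_ACTIVE) & (df[outcome] == 0)).sum())
        c = int(((df["arm"] == ARM_CONTROL) & (df[outcome] == 1)).sum())
        d = int(((df["arm"] == ARM_CONTROL) & (df[outcome] == 0)).sum())
        return (a, b, c, d)

    def write(self, path: str | Path) -> None:
        """Write as delimited text (CSV or TSV chosen by extension)."""
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.data.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class ModifierSet:
    """A named, ordered set of treatment effect modifiers to balance.

    ``moment_spec`` maps covariate name to ``"mean"`` (default) or
    ``"mean_var"`` (match mean and variance).
    """

    name: str
    covariate_names: tuple[str, ...]
    moment_spec: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.covariate_names:
            raise ConfigurationError(f"modifier set '{self.name}' has no covariates")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ConfigurationError(f"modifier set '{self.name}' has duplicate covariates")
        for cov, spec in self.moment_spec.items():
            if spec not in ("mean", "mean_var"):
                raise ConfigurationError(
                    f"modifier set '{self.name}': moment spec for '{cov}' must be "
                    f"'mean' or 'mean_var', got {spec!r}"
                )

    def moments_for(self, covariate: str) -> str:
        return self.moment_spec.get(covariate, "mean")


@dataclass(frozen=True)
class AggregateTarget:
    """Comparator-population covariate summaries to reweight towards."""

    population_label: str
    means: Mapping[str, float]
    variances: Mapping[str, float] = field(default_factory=dict)
    sample_size: int | None = None

    def __post_init__(self):
        for cov, v in self.variances.items():
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(
                    f"target variance for '{cov}' must be finite and >= 0, got {v!r}"
                )

    def require_for(self, mset: ModifierSet) -> None:
        for cov in mset.covariate_names:
            if cov not in self.means:
                raise ConfigurationError(
                    f"modifier set '{mset.name}' needs a target mean for '{cov}' "
                    f"but target '{self.population_label}' does not provide one"
                )
            if mset.moments_for(cov) == "mean_var":
                if cov not in self.variances or self.variances[cov] <= 0:
                    raise ConfigurationError(
                        f"variance matching requested for '{cov}' but target "
                        f"'{self.population_label}' has no positive variance for it"
                    )


@dataclass(frozen=True)
class ComparatorEffect:
    """The comparator trial's own treatment-vs-anchor evidence for one outcome.

    Exactly one form is populated: ``lor_se`` (a log odds ratio with its
    standard error, typically back-converted from a published OR and CI)
    or ``counts`` (arm-level 2x2 counts: active events, active
    non-events, control events, control non-events).
    """

    label: str
    log_or: float | None = None
    se: float | None = None
    counts: tuple[int, int, int, int] | None = None

    def __post_init__(self):
        has_lor = self.log_or is not None or self.se is not None
        has_counts = self.counts is not None
        if has_lor == has_counts:
            raise ConfigurationError(
                f"comparator '{self.label}': exactly one of lor_se or counts must be given"
            )
        if has_lor:
            if self.log_or is None or self.se is None:
                raise ConfigurationError(
                    f"comparator '{self.label}': log_or and se must both be given"
                )
            if not (math.isfinite(self.se) and self.se > 0):
                raise ConfigurationError(
                    f"comparator '{self.label}': se must be finite and > 0, got {self.se!r}"
                )
        else:
            cells = self.counts
            if len(cells) != 4 or any((not float(x).is_integer()) or x < 0 for x in cells):
                raise ConfigurationError(
                    f"comparator '{self.label}': counts must be 4 non-negative integers"
                )
            a, b, c, d = cells
            if a + b <= 0 or c + d <= 0:
                raise ConfigurationError(
                    f"comparator '{self.label}': each arm total must be > 0"
                )

    @property
    def form(self) -> str:
        return "counts" if self.counts is not None else "lor_se"


@dataclass(frozen=True)
class EffectEstimate:
    """A log odds ratio with its standard error and provenance tag."""

    log_or: float
    se: float
    method: str
    n_effective: float | None = None

    _METHODS = ("woolf", "weighted_sandwich", "iv_pooled", "mh_pooled", "from_ci")

    def __post_init__(self):
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"standard error must be finite and > 0, got {self.se!r}")
        if not math.isfinite(self.log_or):
            raise ValidationError(f"log OR must be finite, got {self.log_or!r}")
        if self.method not in self._METHODS:
            raise ValidationError(f"unknown estimate method {self.method!r}")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return (
            math.exp(self.log_or - z * self.se),
            math.exp(self.log_or + z * self.se),
        )


# ---------------------------------------------------------------------------
# File I/O


def counts_from_rate(rate: float, arm_size: int) -> int:
    """Convert a reported event rate into an integer event count.

    Rounds half away from zero so 0.5 cases round up; the result never
    exceeds ``arm_size``.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValidationError(f"rate must lie in [0, 1], got {rate!r}")
    if arm_size < 1:
        raise ValidationError(f"arm_size must be >= 1, got {arm_size!r}")
    return min(int(math.floor(rate * arm_size + 0.5)), int(arm_size))


def load_ipd(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    covariates: Sequence[str] | None = None,
    outcomes: Sequence[str] | None = None,
) -> IPDTable:
    """Read participant-level data from delimited text.

    Parameters
    ----------
    path
        CSV or TSV file (delimiter chosen by extension) with a header row.
    schema
        Optional map from canonical column name (``patient_id``,
        ``trial_id``, ``arm``, covariate and outcome names) to the column
        name used in the file.  Unmapped names are used as-is.
    covariates, outcomes
        Canonical names of covariate and outcome columns.  Defaults: the
        known covariates present in the file, and every remaining
        non-identifier column as an outcome.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"IPD file not found: {path}")
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    try:
        raw = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pandas raises several flavours
        raise ParseError(f"could not parse {path}: {exc}") from exc

    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items()}
    df = raw.rename(columns=rename)

    for col in ID_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}' (after schema mapping)")

    if covariates is None:
        covariates = [c for c in COVARIATE_RANGES if c in df.columns]
    if outcomes is None:
        outcomes = [
            c for c in df.columns if c not in ID_COLUMNS and c not in covariates
        ]

    df = df[list(ID_COLUMNS) + list(covariates) + list(outcomes)].copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["trial_id"] = df["trial_id"].astype(str)
    df = df.reset_index(drop=True)
    return IPDTable(df, tuple(covariates), tuple(outcomes))


_CONFIG_SECTIONS = {"modifier_sets", "target", "comparator", "outcomes", "options"}


@dataclass(frozen=True)
class AnalysisConfig:
    """Fully resolved analysis configuration."""

    modifier_sets: tuple[ModifierSet, ...]
    target: AggregateTarget
    comparators: Mapping[str, ComparatorEffect]
    outcomes: tuple[str, ...]
    options: Mapping[str, object]


def _comparator_from_dict(outcome: str, spec: Mapping) -> ComparatorEffect:
    label = spec.get("label", outcome)
    known = {"label", "or", "ci", "level", "log_or", "se", "counts", "rates"}
    unknown = set(spec) - known
    if unknown:
        raise ConfigurationError(f"comparator '{outcome}': unknown keys {sorted(unknown)}")
    if "counts" in spec:
        return ComparatorEffect(label=label, counts=tuple(int(x) for x in spec["counts"]))
    if "rates" in spec:
        r = spec["rates"]
        try:
            a = counts_from_rate(float(r["active_rate"]), int(r["active_n"]))
            c = counts_from_rate(float(r["control_rate"]), int(r["control_n"]))
            return ComparatorEffect(
                label=label,
                counts=(a, int(r["active_n"]) - a, c, int(r["control_n"]) - c),
            )
        except KeyError as exc:
            raise ConfigurationError(
                f"comparator '{outcome}': rates need active_rate/active_n/"
                f"control_rate/control_n (missing {exc})"
            ) from exc
    if "or" in spec:
        # back-conversion from a published OR and CI
        from .effect_models import effect_from_or_ci

        try:
            lcl, ucl = spec["ci"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(
                f"comparator '{outcome}': 'or' form needs ci: [low, high]"
            ) from exc
        est = effect_from_or_ci(
            float(spec["or"]), float(lcl), float(ucl), float(spec.get("level", 0.95))
        )
        return ComparatorEffect(label=label, log_or=est.log_or, se=est.se)
    if "log_or" in spec:
        return ComparatorEffect(
            label=label, log_or=float(spec["log_or"]), se=float(spec["se"])
        )
    raise ConfigurationError(
        f"comparator '{outcome}': need one of counts / rates / or+ci / log_or+se"
    )


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML/JSON analysis configuration.

    The file has five sections: ``modifier_sets``, ``target``,
    ``comparator`` (per-outcome evidence), ``outcomes`` and ``options``.
    Every covariate named by a modifier set must have a target mean (and
    a target variance if variance matching is requested).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"config file not found: {path}")
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    unknown = set(doc) - _CONFIG_SECTIONS
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    for required in ("modifier_sets", "target", "outcomes"):
        if required not in doc:
            raise ConfigurationError(f"config missing section '{required}'")

    msets = []
    for name, spec in doc["modifier_sets"].items():
        if isinstance(spec, list):
            covs, mspec = spec, {}
        else:
            covs = spec.get("covariates", [])
            mspec = spec.get("moments", {})
            unknown = set(spec) - {"covariates", "moments"}
            if unknown:
                raise ConfigurationError(
                    f"modifier set '{name}': unknown keys {sorted(unknown)}"
                )
        msets.append(ModifierSet(name=name, covariate_names=tuple(covs), moment_spec=dict(mspec)))

    tspec = doc["target"]
    unknown = set(tspec) - {"label", "means", "variances", "n"}
    if unknown:
        raise ConfigurationError(f"target: unknown keys {sorted(unknown)}")
    target = AggregateTarget(
        population_label=str(tspec.get("label", "comparator")),
        means={k: float(v) for k, v in tspec.get("means", {}).items()},
        variances={k: float(v) for k, v in tspec.get("variances", {}).items()},
        sample_size=int(tspec["n"]) if "n" in tspec else None,
    )
    for mset in msets:
        target.require_for(mset)

    comparators = {
        out: _comparator_from_dict(out, spec)
        for out, spec in (doc.get("comparator") or {}).items()
    }
    outcomes = tuple(doc["outcomes"])
    if not outcomes:
        raise ConfigurationError("outcomes list is empty")
    options = dict(doc.get("options") or {})
    level = float(options.get("level", 0.95))
    if not (0.0 < level < 1.0):
        raise ConfigurationError(f"options.level must be in (0, 1), got {level}")
    options["level"] = level
    return AnalysisConfig(tuple(msets), target, comparators, outcomes, options)
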