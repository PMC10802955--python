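"""Synthetic time-to-MCI cohort generator.

Emulates a ten-feature slice of an Alzheimer's observational cohort:
independent feature marginals, event times drawn from exponential, Weibull
or log-logistic hazards driven by a log-linear risk score, and a floored
normal censoring process.  Sex-by-cognitive-status heterogeneity is encoded
through two interaction dummy features whose coefficients shift the female
cognitive-status effects away from the male ones.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "WeightScheme",
    "SurvivalSpec",
    "SurvivalDataset",
    "ScenarioConfig",
    "NACC_FEATURES",
    "DEFAULT_BASE_WEIGHTS",
    "DEFAULT_BASE_SCALE",
    "HETEROGENEITY_SHIFTS",
    "generate_features",
    "build_interaction_dummies",
    "resolve_weights",
    "expand_design",
    "linear_predictor",
    "sample_event_times",
    "sample_censoring",
    "assemble_dataset",
    "simulate_cohort",
]


class ConfigurationError(ValueError):
    """A feature spec, weight map or scenario config is inconsistent."""


@dataclass(frozen=True)
class FeatureSpec:
    """Marginal distribution of one generated feature.

    kind is one of ``bernoulli`` (support = category codes, usually (0, 1)),
    ``multinomial`` (arbitrary integer codes with given probabilities) or
    ``uniform`` (support = (low, high) bounds of a continuous uniform).
    """

    name: str
    kind: str
    support: tuple
    probabilities: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind in ("bernoulli", "multinomial"):
            if self.probabilities is None:
                raise ConfigurationError(f"{self.name}: probabilities required")
            if len(self.probabilities) != len(self.support):
                raise ConfigurationError(f"{self.name}: support/probability length mismatch")
            if abs(sum(self.probabilities) - 1.0) > 1e-12:
                raise ConfigurationError(f"{self.name}: probabilities must sum to 1")
            if len(set(self.support)) != len(self.support):
                raise ConfigurationError(f"{self.name}: duplicate category codes")
        elif self.kind == "uniform":
            low, high = self.support
            if not low < high:
                raise ConfigurationError(f"{self.name}: uniform bounds need low < high")
        else:
            raise ConfigurationError(f"{self.name}: unknown feature kind {self.kind!r}")


#: The ten cohort features with their marginal distributions.  SEX = 1 codes
#: female; COGSTAT uses the clinical codes 0 (normal), 1 (abnormal score) and
#: 9 (clinician unable to render an opinion); TRAVEL uses severity codes 0-2.
NACC_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("SEX", "bernoulli", (0, 1), (0.5, 0.5)),
    FeatureSpec("AGE", "uniform", (55.0, 85.0)),
    FeatureSpec("EDUCATION", "uniform", (0.0, 36.0)),
    FeatureSpec("MEMORY", "bernoulli", (0, 1), (0.917, 0.083)),
    FeatureSpec("JUDGMENT", "bernoulli", (0, 1), (0.96, 0.04)),
    FeatureSpec("DECCLIN", "bernoulli", (0, 1), (0.95, 0.05)),
    FeatureSpec("TRAVEL", "multinomial", (0, 1, 2), (0.95, 0.03, 0.02)),
    FeatureSpec("MOTREM", "bernoulli", (0, 1), (0.99, 0.01)),
    FeatureSpec("COGSTAT", "multinomial", (0, 1, 9), (0.7, 0.16, 0.14)),
    FeatureSpec("DECIN", "bernoulli", (0, 1), (0.88, 0.12)),
)

FEATURE_NAMES = tuple(s.name for s in NACC_FEATURES)

#: Documented default generating coefficients for the non-COGSTAT design
#: terms.  Continuous features enter per decade, centred at the midpoint of
#: their uniform range, so the overall event-time scale is insensitive to
#: the calibration factor.  Signs and magnitudes follow clinical direction:
#: reported impairments raise MCI progression risk, education is protective.
DEFAULT_BASE_WEIGHTS: dict[str, float] = {
    "SEX": -0.10,
    "AGE_PER_DECADE": 0.45,
    "EDUCATION_PER_DECADE": -0.25,
    "MEMORY": 0.90,
    "JUDGMENT": 0.70,
    "DECCLIN": 0.60,
    "TRAVEL_1": 0.50,
    "TRAVEL_2": 0.90,
    "MOTREM": 0.40,
    "DECIN": 0.70,
}

#: Multiplier applied to the non-COGSTAT base weights.  Produced by
#: ``mcibench.runner.calibrate_base_scale``, which scales the base vector so
#: the Cox model's held-out C-index in the baseline exponential scenario at
#: N=6,000 lands at the reference value 0.73.
DEFAULT_BASE_SCALE: float = 1.54

#: Male cognitive-status log-hazard coefficients (reference level 0).
MALE_COGSTAT: tuple[float, float] = (0.57, -0.44)

#: Female-minus-male shifts of the COGSTAT coefficients by heterogeneity
#: level: mean, mean + 1 SD, mean + 2 SD of the estimated interaction values
#: (means -0.13 and -0.31, SDs 0.13 and 0.16 for codes 1 and 9).
HETEROGENEITY_SHIFTS: dict[str, tuple[float, float]] = {
    "none": (0.0, 0.0),
    "small": (-0.13, -0.31),
    "medium": (-0.13 - 0.13, -0.31 - 0.16),
    "large": (-0.13 - 2 * 0.13, -0.31 - 2 * 0.16),
}


@dataclass(frozen=True)
class WeightScheme:
    """Generating coefficient vector, including the heterogeneity design.

    ``base_weights`` covers every design term except the COGSTAT indicators;
    ``base_scale`` multiplies them (the calibration knob).  COGSTAT enters
    through the male coefficients plus, for females, the level-specific shift.
    """

    base_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_WEIGHTS)
    )
    base_scale: float = DEFAULT_BASE_SCALE
    male_cogstat: tuple[float, float] = MALE_COGSTAT
    heterogeneity_level: str = "none"

    def __post_init__(self) -> None:
        if self.heterogeneity_level not in HETEROGENEITY_SHIFTS:
            raise ConfigurationError(
                f"unknown heterogeneity level {self.heterogeneity_level!r}"
            )

    @property
    def female_cogstat(self) -> tuple[float, float]:
        s1, s9 = HETEROGENEITY_SHIFTS[self.heterogeneity_level]
        return (self.male_cogstat[0] + s1, self.male_cogstat[1] + s9)


@dataclass(frozen=True)
class SurvivalSpec:
    """Event-time family, its shape, and the censoring distribution."""

    family: str = "exponential"
    shape: float = 1.5
    censor_mu: float = 2.0
    censor_sigma: float = 3.611

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "weibull", "loglogistic"):
            raise ConfigurationError(f"unknown survival family {self.family!r}")
        if self.shape <= 0:
            raise ConfigurationError("shape must be positive")
        if self.censor_sigma <= 0:
            raise ConfigurationError("censor_sigma must be positive")


@dataclass
class SurvivalDataset:
    """Feature table plus right-censored follow-up for one cohort.

    ``event`` is the event indicator delta (1 = MCI conversion observed);
    the complementary censoring flag C = 1 - delta is what the pair
    construction T = min(T_event, T_censor) records when censoring wins.
    ``true_event_time`` is retained for diagnostics only: a fitted model
    never sees it.
    """

    features: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    true_event_time: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.features)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int8)
        if len(self.time) != n or len(self.event) != n:
            raise ValueError("features, time and event must have equal length")
        if np.any(self.time < 0):
            raise ValueError("observed times must be nonnegative")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def censored(self) -> np.ndarray:
        """Censoring indicator C = 1 - delta."""
        return (1 - self.event).astype(np.int8)

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        tet = None if self.true_event_time is None else self.true_event_time[idx]
        return SurvivalDataset(
            self.features.iloc[idx].reset_index(drop=True),
            self.time[idx],
            self.event[idx],
            tet,
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.features.copy()
        out["observed_time"] = self.time
        out["event"] = self.event
        out["censored"] = self.censored
        return out

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurvivalDataset":
        feats = frame.drop(columns=["observed_time", "event", "censored"], errors="ignore")
        return cls(feats.reset_index(drop=True),
                   frame["observed_time"].to_numpy(),
                   frame["event"].to_numpy())

    @classmethod
    def from_csv(cls, path_or_buf) -> "SurvivalDataset":
        return cls.from_frame(pd.read_csv(path_or_buf))


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation cell of the study grid."""

    name: str = "scenario"
    n_subjects: int = 2000
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    weights: WeightScheme = field(default_factory=WeightScheme)
    omitted_features: tuple[str, ...] = ()
    replicates: int = 50
    split_ratio: float = 0.8
    seed: int = 0
    #: None = give the Cox model the interaction dummies exactly when the
    #: generating scheme is heterogeneous; True/False overrides.
    cox_interaction_dummies: bool | None = None
    models: tuple[str, ...] = ("coxph", "rsf", "deepsurv")

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigurationError("split_ratio must lie in (0, 1)")
        unknown = set(self.omitted_features) - set(FEATURE_NAMES)
        if unknown:
            raise ConfigurationError(f"omitted features not in feature set: {sorted(unknown)}")

    @property
    def cox_uses_dummies(self) -> bool:
        if self.cox_interaction_dummies is not None:
            return self.cox_interaction_dummies
        return self.weights.heterogeneity_level != "none"


# ---------------------------------------------------------------------------
# feature generation


def generate_features(
    spec_list: Sequence[FeatureSpec], n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` independent rows from the given feature marginals."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    cols: dict[str, np.ndarray] = {}
    for spec in spec_list:
        if spec.kind == "uniform":
            low, high = spec.support
            cols[spec.name] = rng.uniform(low, high, size=n)
        elif spec.kind in ("bernoulli", "multinomial"):
            codes = np.asarray(spec.support)
            cols[spec.name] = rng.choice(codes, size=n, p=np.asarray(spec.probabilities))
        else:  # pragma: no cover - rejected at FeatureSpec construction
            raise ConfigurationError(f"unknown feature kind {spec.kind!r}")
    return pd.DataFrame(cols)


def build_interaction_dummies(features: pd.DataFrame) -> pd.DataFrame:
    """Append the sex-by-cognitive-status dummies F_COGSTAT_1 and F_COGSTAT_9.

    F_COGSTAT_k = SEX * I{COGSTAT == k}: only females (SEX = 1) with the
    given cognitive-status code are flagged, so a weight on the dummy moves
    female risk relative to males with the same code.
    """
    for col in ("SEX", "COGSTAT"):
        if col not in features.columns:
            raise KeyError(f"column {col!r} required to build interaction dummies")
    out = features.copy()
    sex = features["SEX"].to_numpy()
    cog = features["COGSTAT"].to_numpy()
    out["F_COGSTAT_1"] = (sex * (cog == 1)).astype(np.int8)
    out["F_COGSTAT_9"] = (sex * (cog == 9)).astype(np.int8)
    return out


def resolve_weights(scheme: WeightScheme) -> dict[str, float]:
    """Effective design-term coefficient map for a weight scheme.

    COGSTAT indicator terms carry the male coefficients; the interaction
    dummies carry the female-minus-male shift for the scheme's level (zero
    under ``none``, so females and males share the printed values).
    """
    s1, s9 = HETEROGENEITY_SHIFTS[scheme.heterogeneity_level]
    eff = {k: scheme.base_scale * v for k, v in scheme.base_weights.items()}
    eff["COGSTAT_1"] = scheme.male_cogstat[0]
    eff["COGSTAT_9"] = scheme.male_cogstat[1]
    eff["F_COGSTAT_1"] = s1
    eff["F_COGSTAT_9"] = s9
    return eff


#: Centres/scales for the continuous design terms (midpoints of the uniform
#: ranges, per decade).
_CONTINUOUS_TERMS = {
    "AGE_PER_DECADE": ("AGE", 70.0, 10.0),
    "EDUCATION_PER_DECADE": ("EDUCATION", 18.0, 10.0),
}


def expand_design(features: pd.DataFrame, include_interactions: bool = False) -> pd.DataFrame:
    """Indicator-coded design matrix over whatever features are present.

    Categorical codes are labels, not magnitudes, so TRAVEL and COGSTAT enter
    as level indicators against reference level 0.  Continuous features are
    centred at their range midpoint and scaled to decades.  Columns for
    omitted features are simply absent.
    """
    cols: dict[str, np.ndarray] = {}
    if "SEX" in features:
        cols["SEX"] = features["SEX"].to_numpy(dtype=float)
    for term, (src, centre, scale) in _CONTINUOUS_TERMS.items():
        if src in features:
            cols[term] = (features[src].to_numpy(dtype=float) - centre) / scale
    for name in ("MEMORY", "JUDGMENT", "DECCLIN", "MOTREM", "DECIN"):
        if name in features:
            cols[name] = features[name].to_numpy(dtype=float)
    if "TRAVEL" in features:
        trv = features["TRAVEL"].to_numpy()
        cols["TRAVEL_1"] = (trv == 1).astype(float)
        cols["TRAVEL_2"] = (trv == 2).astype(float)
    if "COGSTAT" in features:
        cog = features["COGSTAT"].to_numpy()
        cols["COGSTAT_1"] = (cog == 1).astype(float)
        cols["COGSTAT_9"] = (cog == 9).astype(float)
    if include_interactions:
        if "F_COGSTAT_1" in features:
            cols["F_COGSTAT_1"] = features["F_COGSTAT_1"].to_numpy(dtype=float)
            cols["F_COGSTAT_9"] = features["F_COGSTAT_9"].to_numpy(dtype=float)
        elif "SEX" in features and "COGSTAT" in features:
            dum = build_interaction_dummies(features[["SEX", "COGSTAT"]])
            cols["F_COGSTAT_1"] = dum["F_COGSTAT_1"].to_numpy(dtype=float)
            cols["F_COGSTAT_9"] = dum["F_COGSTAT_9"].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=features.index)


def linear_predictor(design: pd.DataFrame, weights: Mapping[str, float]) -> np.ndarray:
    """Per-subject hazard rate multiplier lambda_i = exp(x_i . beta)."""
    missing = [k for k, v in weights.items() if v != 0.0 and k not in design.columns]
    if missing:
        raise ConfigurationError(f"weights reference absent design columns: {missing}")
    eta = np.zeros(len(design))
    for term, beta in weights.items():
        if term in design.columns and beta != 0.0:
            eta += beta * design[term].to_numpy(dtype=float)
    return np.exp(eta)


# ---------------------------------------------------------------------------
# survival and censoring times


def sample_event_times(
    lam: np.ndarray, spec: SurvivalSpec, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-transform event times with rate multiplier ``lam``.

    exponential:   T = -log(U) / lambda
    weibull:       T = (-log(U) / lambda)^(1/shape)
    log-logistic:  T = (1/lambda) * (U / (1-U))^(1/shape)
    """
    lam = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
        raise ValueError("rates must be finite and positive")
    u = rng.uniform(size=lam.shape)
    if spec.family == "exponential":
        return -np.log(u) / lam
    if spec.family == "weibull":
        return (-np.log(u) / lam) ** (1.0 / spec.shape)
    # log-logistic
    return (1.0 / lam) * (u / (1.0 - u)) ** (1.0 / spec.shape)


def sample_censoring(n: int, spec: SurvivalSpec, rng: np.random.Generator) -> np.ndarray:
    """Censoring times max(0, Normal(mu, sigma)).

    This is the floored-normal construction, not a renormalised truncated
    normal: the negative mass collapses to an exact point mass at zero
    (subjects censored immediately, contributing no follow-up).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    return np.maximum(0.0, rng.normal(spec.censor_mu, spec.censor_sigma, size=n))


def assemble_dataset(
    features: pd.DataFrame,
    event_times: np.ndarray,
    censoring_times: np.ndarray,
    omitted_features: Sequence[str] = (),
) -> SurvivalDataset:
    """Pair event and censoring times and release the (possibly reduced) table.

    The observed time is min(T_event, T_censor); a tie counts as an observed
    event.  Columns in ``omitted_features`` are removed from the released
    table although they did shape the event times — that is exactly
    unobserved heterogeneity.
    """
    event_times = np.asarray(event_times, dtype=float)
    censoring_times = np.asarray(censoring_times, dtype=float)
    if not (len(features) == len(event_times) == len(censoring_times)):
        raise ValueError("features and time vectors must have equal length")
    observed = np.minimum(event_times, censoring_times)
    delta = (event_times <= censoring_times).astype(np.int8)
    released = features.drop(columns=list(omitted_features), errors="raise")
    return SurvivalDataset(released, observed, delta, true_event_time=event_times)


def simulate_cohort(config: ScenarioConfig, rng: np.random.Generator) -> SurvivalDataset:
    """Full data-generating mechanism for one replicate of a scenario."""
    feats = generate_features(NACC_FEATURES, config.n_subjects, rng)
    feats = build_interaction_dummies(feats)
    weights = resolve_weights(config.weights)
    design = expand_design(feats, include_interactions=True)
    lam = linear_predictor(design, weights)
    t_event = sample_event_times(lam, config.survival, rng)
    t_cens = sample_censoring(config.n_subjects, config.survival, rng)
    base = feats[list(FEATURE_NAMES)]  # dummies are rebuilt downstream when needed
    return assemble_dataset(base, t_event, t_cens, config.omitted_features)
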