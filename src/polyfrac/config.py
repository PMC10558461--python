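"""Study configuration: population model, risk model, and pipeline settings.

Defaults emulate the structure of a Japanese elderly claims population:
patients aged 65-100 with the age peak in the 80s, ~71% female, chapter
prevalences and medication-category use rates anchored to the control-group
marginals of the descriptive table (mean ~5.3 concurrent medications,
~6.4 comorbid chapters), and a logistic risk model for the hip-fracture
outcome.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import yaml

from .categories import N_CHAPTERS, N_MED_CATEGORIES
from .errors import ConfigError


# ---------------------------------------------------------------------------
# date window
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class DateWindow:
    """Closed calendar interval [start, end]."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ConfigError("study_window: end precedes start")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end

    def random_dates(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n uniformly random dates in the window, as datetime64[D]."""
        offs = rng.integers(0, self.n_days, size=n)
        return np.datetime64(self.start, "D") + offs.astype("timedelta64[D]")

    @classmethod
    def parse(cls, value) -> "DateWindow":
        if isinstance(value, DateWindow):
            return value
        if isinstance(value, str):
            a, _, b = value.partition(":")
            return cls(date.fromisoformat(a), date.fromisoformat(b))
        a, b = value
        if isinstance(a, str):
            a, b = date.fromisoformat(a), date.fromisoformat(b)
        return cls(a, b)


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------
def stage_seed(master_seed: int, label: str) -> int:
    """Derive a per-stage seed from the master seed by a fixed label.

    Keyed by CRC32 of the label so adding patients to one stage does not
    perturb the pseudo-random stream of another.
    """
    return int(
        np.random.SeedSequence(
            [int(master_seed) & 0x7FFFFFFF, zlib.crc32(label.encode()) & 0x7FFFFFFF]
        ).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def stage_rng(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, label))


# ---------------------------------------------------------------------------
# risk model
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class RiskModel:
    """Logistic data-generating model for the binary fracture outcome.

    P(case) = logistic(intercept + beta_count * med_count
                       + beta_chapter . chapters + beta_med . meds),
    with ``beta_count`` optionally rescaled per age stratum via
    ``age_group_modifiers`` (keys "early" / "late", multipliers on
    beta_count) to emulate an early-/late-elderly contrast.
    """

    intercept: float = -2.6
    beta_count: float = float(np.log(1.05))
    beta_chapter: np.ndarray = field(default=None)  # type: ignore[assignment]
    beta_med: np.ndarray = field(default=None)  # type: ignore[assignment]
    age_group_modifiers: dict | None = None

    def __post_init__(self) -> None:
        bc = np.zeros(N_CHAPTERS) if self.beta_chapter is None else np.asarray(
            self.beta_chapter, dtype=float
        )
        bm = np.zeros(N_MED_CATEGORIES) if self.beta_med is None else np.asarray(
            self.beta_med, dtype=float
        )
        if bc.shape != (N_CHAPTERS,):
            raise ConfigError(f"risk_model.beta_chapter: expected length {N_CHAPTERS}")
        if bm.shape != (N_MED_CATEGORIES,):
            raise ConfigError(f"risk_model.beta_med: expected length {N_MED_CATEGORIES}")
        for name, v in [("intercept", self.intercept), ("beta_count", self.beta_count)]:
            if not np.isfinite(v):
                raise ConfigError(f"risk_model.{name}: not finite")
        if not (np.isfinite(bc).all() and np.isfinite(bm).all()):
            raise ConfigError("risk_model.beta_chapter/beta_med: not finite")
        object.__setattr__(self, "beta_chapter", bc)
        object.__setattr__(self, "beta_med", bm)

    @classmethod
    def default(cls) -> "RiskModel":
        """Moderate, sparse associations: a handful of chapters and drug
        categories carry signal, the rest are null."""
        bc = np.zeros(N_CHAPTERS)
        bm = np.zeros(N_MED_CATEGORIES)
        # chapters: nervous, musculoskeletal, digestive up; circulatory down
        bc[[5, 12, 10]] = np.log([1.35, 1.25, 1.2])
        bc[8] = np.log(0.85)
        # meds (0-based indices into the 60 categories):
        # anti-Parkinson's (52), psychoanaleptics (54) up;
        # constipation drugs (6), analgesics (50) down
        bm[51] = np.log(1.9)
        bm[53] = np.log(1.3)
        bm[5] = np.log(0.75)
        bm[49] = np.log(0.8)
        return cls(intercept=-2.45, beta_count=float(np.log(1.06)),
                   beta_chapter=bc, beta_med=bm)


# ---------------------------------------------------------------------------
# population config
# ---------------------------------------------------------------------------
def _default_age_distribution() -> np.ndarray:
    """Discretized truncated normal on 65..100, mean 82.7, sd 7.6."""
    ages = np.arange(65, 101)
    w = np.exp(-0.5 * ((ages - 82.7) / 7.6) ** 2)
    return w / w.sum()


def _default_chapter_prevalence() -> np.ndarray:
    # Control-group chapter marginals where reported; field-plausible
    # values for the remaining six chapters.
    return np.array(
        [
            0.411,  # infectious
            0.530,  # neoplasms
            0.389,  # blood
            0.623,  # endocrine
            0.250,  # mental
            0.362,  # nervous
            0.300,  # eye
            0.100,  # ear
            0.791,  # circulatory
            0.530,  # respiratory
            0.659,  # digestive
            0.250,  # skin
            0.450,  # musculoskeletal
            0.424,  # genitourinary
            0.464,  # symptoms
            0.200,  # injury
        ]
    )


def _default_med_baseline() -> np.ndarray:
    """Baseline activation probability per medication category.

    Anchored to the ten control-group use rates of the descriptive table;
    the remaining 50 categories get small rates chosen so the expected
    concurrent-medication count is ~5.3.
    """
    p = np.full(N_MED_CATEGORIES, 0.045)
    anchored = {
        1: 0.614,  # antacids/anti-ulcers
        13: 0.319,  # antithrombotics
        23: 0.291,  # calcium antagonists
        24: 0.259,  # renin-angiotensin agents
        52: 0.267,  # psycholeptics
        25: 0.213,  # lipid-regulating
        18: 0.215,  # diuretics
        9: 0.153,  # vitamins
        5: 0.232,  # constipation drugs
        8: 0.045,  # antidiabetics: 0.117 marginal via endocrine link below
    }
    for k, v in anchored.items():
        p[k] = v
    p[49] = 0.150  # analgesics
    p[44] = 0.120  # anti-inflammatory/anti-rheumatic
    p[36] = 0.100  # systemic antibacterials
    p[51] = 0.020  # anti-Parkinson's baseline; nervous link below
    return p


def _default_med_given_chapter() -> np.ndarray:
    """Sparse conditional links from chapters to medication categories.

    Activation probability for category j is
    clip(baseline_j + sum_k chapter_k * M[j, k], 0, 1).
    """
    m = np.zeros((N_MED_CATEGORIES, N_CHAPTERS))
    m[8, 3] = 0.115  # antidiabetics | endocrine  -> ~0.117 marginal
    m[51, 5] = 0.10  # anti-Parkinson's | nervous -> ~0.056 marginal
    m[53, 4] = 0.20  # psychoanaleptics | mental
    m[16, 8] = 0.10  # cardiac therapy | circulatory
    m[56, 9] = 0.10  # anti-asthma/COPD | respiratory
    m[2, 10] = 0.10  # functional GI drugs | digestive
    return m


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the synthetic claims population."""

    n_patients: int = 5000
    study_window: DateWindow = field(
        default_factory=lambda: DateWindow(date(2015, 1, 1), date(2020, 12, 31))
    )
    sex_female_prob: float = 0.714
    age_distribution: np.ndarray = field(default=None)  # type: ignore[assignment]
    chapter_prevalence: np.ndarray = field(default=None)  # type: ignore[assignment]
    med_baseline_prob: np.ndarray = field(default=None)  # type: ignore[assignment]
    med_given_chapter: np.ndarray = field(default=None)  # type: ignore[assignment]
    risk_model: RiskModel = field(default_factory=RiskModel.default)
    #: per-chain probability of one 8-30 day refill disruption (creates a
    #: second, non-concomitant episode and exercises the grace-period rule)
    gap_disruption_prob: float = 0.15
    #: probability that an inactive category still leaves a stale, long-
    #: discontinued episode in the claims stream (decoy history)
    decoy_med_prob: float = 0.05
    #: probability of a stale/unconfirmed decoy diagnosis per inactive chapter
    decoy_dx_prob: float = 0.10
    refill_days: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients: must be non-negative")
        probs = {
            "sex_female_prob": np.atleast_1d(self.sex_female_prob),
            "gap_disruption_prob": np.atleast_1d(self.gap_disruption_prob),
            "decoy_med_prob": np.atleast_1d(self.decoy_med_prob),
            "decoy_dx_prob": np.atleast_1d(self.decoy_dx_prob),
        }
        defaults = {
            "age_distribution": (_default_age_distribution, (36,)),
            "chapter_prevalence": (_default_chapter_prevalence, (N_CHAPTERS,)),
            "med_baseline_prob": (_default_med_baseline, (N_MED_CATEGORIES,)),
            "med_given_chapter": (
                _default_med_given_chapter,
                (N_MED_CATEGORIES, N_CHAPTERS),
            ),
        }
        for name, (factory, shape) in defaults.items():
            v = getattr(self, name)
            v = factory() if v is None else np.asarray(v, dtype=float)
            if v.shape != shape:
                raise ConfigError(f"{name}: expected shape {shape}, got {v.shape}")
            object.__setattr__(self, name, v)
            if name != "med_given_chapter":
                probs[name] = v
        for name, v in probs.items():
            if np.any(v < 0) or np.any(v > 1):
                raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
        if abs(self.age_distribution.sum() - 1) > 1e-8:
            raise ConfigError("age_distribution: probabilities must sum to 1")
        if self.refill_days < 1:
            raise ConfigError("refill_days: must be >= 1")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(65, 101)


# ---------------------------------------------------------------------------
# study config
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class StudyConfig:
    """One document driving the whole generate -> evaluate pipeline."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    cohort_window: DateWindow | None = None  # defaults to the population window
    band_width: int = 5
    control_exclusion: str = "through_index"
    grace_days: int = 7
    count_window: str = "pre"
    n_lambda: int = 60
    lambda_min_ratio: float = 0.01
    cv_folds: int = 5
    lambda_rule: str = "min"
    strata: tuple = ("all", "early", "late")
    run_stepwise: bool = False
    validation_window: DateWindow | None = None
    validation_n_patients: int | None = None
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_width < 1:
            raise ConfigError("band_width: must be >= 1")
        if self.count_window not in ("pre", "centered"):
            raise ConfigError("count_window: must be 'pre' or 'centered'")
        if self.control_exclusion not in ("through_index", "ever"):
            raise ConfigError("control_exclusion: must be 'through_index' or 'ever'")
        if self.lambda_rule not in ("min", "1se"):
            raise ConfigError("lambda_rule: must be 'min' or '1se'")
        if self.validation_window is not None:
            if self.validation_window.end >= self.window.start:
                raise ConfigError(
                    "validation_window: must end before the main cohort window starts"
                )

    @property
    def window(self) -> DateWindow:
        return self.cohort_window or self.population.study_window

    @classmethod
    def from_dict(cls, doc: dict) -> "StudyConfig":
        doc = dict(doc or {})
        pop = dict(doc.pop("population", {}))
        if "study_window" in pop:
            pop["study_window"] = DateWindow.parse(pop["study_window"])
        if "risk_model" in pop:
            pop["risk_model"] = RiskModel(**pop["risk_model"])
        for key in ("cohort_window", "validation_window"):
            if doc.get(key) is not None:
                doc[key] = DateWindow.parse(doc[key])
        if "strata" in doc:
            doc["strata"] = tuple(doc["strata"])
        try:
            return cls(population=PopulationConfig(**pop), **doc)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_seed(self, seed: int) -> "StudyConfig":
        return replace(self, seed=seed, population=replace(self.population, seed=seed))
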