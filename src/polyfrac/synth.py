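"""Seeded synthetic claims-data generator.

Emits the three raw tables the analysis pipeline consumes — patients,
dated diagnosis events, dated prescription events — plus a latent-truth
table that records the chapter/medication indicators each patient was
generated with.  The latent truth exists only so tests can verify that the
exposure-derivation stage recovers the intended covariates; the analysis
stages never see it.

Exposures are persistent: active diagnoses are open-ended and active
medication categories are emitted as 30-day refill chains spanning the
whole study window (with small jitter gaps and an occasional 8-30-day
disruption, so both branches of the grace-period chaining rule occur in
the stream).  Derivation at *any* index date inside the window therefore
recovers the latent indicators, up to the deliberately planted gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .categories import N_CHAPTERS, N_MED_CATEGORIES, default_maps
from .config import DateWindow, PopulationConfig, RiskModel, stage_rng
from .errors import ConfigError

# two representative ICD-10 codes per chapter, in chapter order; the injury
# chapter deliberately avoids the case-defining S72 prefix
_CHAPTER_CODES = [
    ("A09", "B37"), ("C34", "C61"), ("D64", "D69"), ("E11", "E78"),
    ("F03", "F32"), ("G20", "G62"), ("H25", "H40"), ("H81", "H90"),
    ("I10", "I50"), ("J18", "J44"), ("K21", "K59"), ("L30", "L89"),
    ("M16", "M81"), ("N18", "N39"), ("R26", "R52"), ("S32", "T81"),
]

CASE_DIAGNOSIS_CODE = "S72.0"

DIAGNOSIS_COLUMNS = ["patient_id", "icd10_code", "confirmed", "start_date", "end_date"]
PRESCRIPTION_COLUMNS = ["patient_id", "drug_code", "start_date", "days_supplied"]


def _dates_to_ns(df: pd.DataFrame, columns) -> pd.DataFrame:
    for c in columns:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c]).astype("datetime64[ns]")
    return df


def age_in_years(birth_dates, at_dates) -> np.ndarray:
    """Completed age in years, by elapsed days / 365.25 (floor)."""
    days = (
        np.asarray(at_dates, dtype="datetime64[D]")
        - np.asarray(birth_dates, dtype="datetime64[D]")
    ).astype(int)
    return (days / 365.25).astype(int)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------
def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Sample the patient table: id, sex, birth_date.

    Ages are drawn on the integer support 65..100 from
    ``config.age_distribution`` and anchored at the start of the study
    window; birth dates are back-computed so each patient has exactly the
    drawn completed age on the window start date.
    """
    rng = stage_rng(config.seed, "population")
    n = config.n_patients
    ids = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    sex = np.where(rng.random(n) < config.sex_female_prob, "female", "male")
    ages = rng.choice(config.ages, size=n, p=config.age_distribution)
    # birth = window start - (age years + a sub-year offset); the offset
    # keeps the completed age at window start equal to the drawn age
    back_days = np.ceil(ages * 365.25).astype(int) + rng.integers(0, 365, size=n)
    birth = np.datetime64(config.study_window.start, "D") - back_days.astype(
        "timedelta64[D]"
    )
    return pd.DataFrame({"patient_id": ids, "sex": sex, "birth_date": birth})


# ---------------------------------------------------------------------------
# claims events
# ---------------------------------------------------------------------------
def _latent_indicators(n: int, config: PopulationConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    chapters = (rng.random((n, N_CHAPTERS)) < config.chapter_prevalence).astype(np.int8)
    act_prob = np.clip(
        config.med_baseline_prob + chapters @ config.med_given_chapter.T, 0.0, 1.0
    )
    meds = (rng.random((n, N_MED_CATEGORIES)) < act_prob).astype(np.int8)
    return chapters, meds


def _diagnosis_events(patients, chapters, config, rng) -> pd.DataFrame:
    w = config.study_window
    start0 = np.datetime64(w.start, "D")
    end0 = np.datetime64(w.end, "D")
    pid = patients["patient_id"].to_numpy()
    frames = []

    # active chapters: confirmed, started before the window, open-ended or
    # ending after the window (so the flag holds at every in-window date)
    pi, ci = np.nonzero(chapters)
    m = len(pi)
    if m:
        codes = np.array(
            [_CHAPTER_CODES[c][k] for c, k in zip(ci, rng.integers(0, 2, m))]
        )
        starts = start0 - rng.integers(30, 1001, m).astype("timedelta64[D]")
        ends = np.full(m, np.datetime64("NaT"), dtype="datetime64[D]")
        late = rng.random(m) < 0.15
        ends[late] = end0 + rng.integers(1, 301, late.sum()).astype("timedelta64[D]")
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid[pi],
                    "icd10_code": codes,
                    "confirmed": True,
                    "start_date": starts,
                    "end_date": ends,
                }
            )
        )

    # decoys on inactive chapters: unconfirmed, or confirmed but closed
    # before the window begins; neither may produce a flag
    di, dc = np.nonzero((chapters == 0) & (rng.random(chapters.shape) < config.decoy_dx_prob))
    m = len(di)
    if m:
        codes = np.array(
            [_CHAPTER_CODES[c][k] for c, k in zip(dc, rng.integers(0, 2, m))]
        )
        unconfirmed = rng.random(m) < 0.5
        ends = np.full(m, np.datetime64("NaT"), dtype="datetime64[D]")
        closed = ~unconfirmed
        end_closed = start0 - rng.integers(10, 201, closed.sum()).astype("timedelta64[D]")
        ends[closed] = end_closed
        starts = np.where(
            unconfirmed,
            start0 - rng.integers(30, 1001, m).astype("timedelta64[D]"),
            ends - rng.integers(30, 401, m).astype("timedelta64[D]"),
        )
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid[di],
                    "icd10_code": codes,
                    "confirmed": ~unconfirmed,
                    "start_date": starts.astype("datetime64[D]"),
                    "end_date": ends,
                }
            )
        )

    if not frames:
        return pd.DataFrame(columns=DIAGNOSIS_COLUMNS)
    out = _dates_to_ns(
        pd.concat(frames, ignore_index=True)[DIAGNOSIS_COLUMNS],
        ["start_date", "end_date"],
    )
    return out.sort_values(["patient_id", "start_date"], kind="stable").reset_index(
        drop=True
    )


def _prescription_events(patients, meds, config, rng) -> pd.DataFrame:
    w = config.study_window
    start0 = np.datetime64(w.start, "D")
    end0 = np.datetime64(w.end, "D")
    pid = patients["patient_id"].to_numpy()
    prefixes = np.array(default_maps().med_prefixes)
    rd = config.refill_days
    frames = []

    pi, mi = np.nonzero(meds)
    n_chain = len(pi)
    if n_chain:
        lead = rng.integers(30, 121, n_chain)
        n_refill = int(np.ceil((121 + w.n_days) / rd)) + 8
        # refill-to-refill increments: nominal spacing plus small jitter,
        # with an occasional 8-30 day disruption splitting the chain
        gaps = rng.integers(0, 4, (n_chain, n_refill)) * (
            rng.random((n_chain, n_refill)) < 0.25
        )
        disrupted = np.nonzero(rng.random(n_chain) < config.gap_disruption_prob)[0]
        if len(disrupted):
            cols = rng.integers(1, max(2, n_refill - 4), len(disrupted))
            gaps[disrupted, cols] = rng.integers(8, 31, len(disrupted))
        inc = gaps + rd
        inc[:, 0] = 0
        starts = (
            (start0 - lead.astype("timedelta64[D]"))[:, None]
            + np.cumsum(inc, axis=1).astype("timedelta64[D]")
        )
        keep = starts <= end0
        rows, _ = np.nonzero(keep)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid[pi[rows]],
                    "drug_code": np.char.add(prefixes[mi[rows]], "001"),
                    "start_date": starts[keep],
                    "days_supplied": rd,
                }
            )
        )

    # stale decoy chains on inactive categories, fully discontinued more
    # than the grace period before the window begins
    di, dm = np.nonzero((meds == 0) & (rng.random(meds.shape) < config.decoy_med_prob))
    m = len(di)
    if m:
        last_end = start0 - rng.integers(15, 121, m).astype("timedelta64[D]")
        chain_start = last_end - np.timedelta64(3 * rd - 1, "D")
        starts = chain_start[:, None] + (
            np.arange(3) * rd
        ).astype("timedelta64[D]")[None, :]
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(pid[di], 3),
                    "drug_code": np.repeat(np.char.add(prefixes[dm], "001"), 3),
                    "start_date": starts.ravel(),
                    "days_supplied": rd,
                }
            )
        )

    if not frames:
        return pd.DataFrame(columns=PRESCRIPTION_COLUMNS)
    out = _dates_to_ns(
        pd.concat(frames, ignore_index=True)[PRESCRIPTION_COLUMNS], ["start_date"]
    )
    return out.sort_values(
        ["patient_id", "drug_code", "start_date"], kind="stable"
    ).reset_index(drop=True)


def generate_claims_events(
    patients: pd.DataFrame, config: PopulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (diagnoses, prescriptions, latent_truth) for a population.

    The latent-truth table holds each patient's chapter indicators
    (``cm_*``), medication-category indicators (``rx*``) and the implied
    concurrent-medication count; it is test scaffolding, not analysis input.
    """
    if patients.empty:
        raise ConfigError("patients: table is empty")
    rng = stage_rng(config.seed, "claims")
    n = len(patients)
    chapters, meds = _latent_indicators(n, config, rng)

    maps = default_maps()
    latent = pd.DataFrame({"patient_id": patients["patient_id"].to_numpy()})
    latent[maps.chapter_variables] = chapters
    latent[maps.med_variables] = meds
    latent["med_count"] = meds.sum(axis=1)

    diagnoses = _diagnosis_events(patients, chapters, config, rng)
    prescriptions = _prescription_events(patients, meds, config, rng)
    return diagnoses, prescriptions, latent


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------
def assign_outcomes(
    latent: pd.DataFrame,
    risk_model: RiskModel,
    patients: pd.DataFrame,
    window: DateWindow,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the binary fracture outcome from the logistic risk model.

    Every patient receives a uniformly random index date in the window;
    cases additionally receive a confirmed S72 diagnosis event on that
    date.  Returns (outcomes, case_diagnosis_events).
    """
    rng = stage_rng(seed, "outcomes")
    maps = default_maps()
    lat = latent.merge(patients[["patient_id", "birth_date"]], on="patient_id")
    n = len(lat)
    index_dates = window.random_dates(rng, n)
    ages = age_in_years(lat["birth_date"].to_numpy(), index_dates)

    beta_count = np.full(n, risk_model.beta_count)
    if risk_model.age_group_modifiers:
        mods = risk_model.age_group_modifiers
        beta_count = np.where(
            ages < 75, beta_count * mods.get("early", 1.0), beta_count * mods.get("late", 1.0)
        )
    lp = (
        risk_model.intercept
        + beta_count * lat["med_count"].to_numpy()
        + lat[maps.chapter_variables].to_numpy() @ risk_model.beta_chapter
        + lat[maps.med_variables].to_numpy() @ risk_model.beta_med
    )
    if not np.isfinite(lp).all():
        raise ValueError("assign_outcomes: non-finite linear predictor")
    case = rng.random(n) < expit(lp)

    outcomes = _dates_to_ns(
        pd.DataFrame(
            {
                "patient_id": lat["patient_id"].to_numpy(),
                "hip_fracture": case,
                "index_date": index_dates,
            }
        ),
        ["index_date"],
    )
    case_dx = _dates_to_ns(
        pd.DataFrame(
            {
                "patient_id": outcomes.loc[case, "patient_id"].to_numpy(),
                "icd10_code": CASE_DIAGNOSIS_CODE,
                "confirmed": True,
                "start_date": index_dates[case],
                "end_date": np.datetime64("NaT"),
            }
        )[DIAGNOSIS_COLUMNS],
        ["start_date", "end_date"],
    )
    return outcomes, case_dx


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------
@dataclass
class SyntheticStudyData:
    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    latent: pd.DataFrame
    outcomes: pd.DataFrame


def generate_study_data(config: PopulationConfig) -> SyntheticStudyData:
    """Full generator: population, claims streams, outcomes.

    The case-defining S72 events are appended to the diagnosis table, as
    they would appear in a real claims extract.
    """
    patients = generate_population(config)
    if patients.empty:
        return SyntheticStudyData(
            patients,
            pd.DataFrame(columns=DIAGNOSIS_COLUMNS),
            pd.DataFrame(columns=PRESCRIPTION_COLUMNS),
            pd.DataFrame(),
            pd.DataFrame(columns=["patient_id", "hip_fracture", "index_date"]),
        )
    diagnoses, prescriptions, latent = generate_claims_events(patients, config)
    outcomes, case_dx = assign_outcomes(
        latent, config.risk_model, patients, config.study_window, config.seed
    )
    frames = [f for f in (diagnoses, case_dx) if not f.empty]
    if frames:
        diagnoses = (
            pd.concat(frames, ignore_index=True)
            .sort_values(["patient_id", "start_date"], kind="stable")
            .reset_index(drop=True)
        )
    return SyntheticStudyData(patients, diagnoses, prescriptions, latent, outcomes)


def write_claims(data: SyntheticStudyData, out_dir) -> None:
    """Persist the generated tables as UTF-8 CSVs with ISO-8601 dates."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.patients.to_csv(out / "patients.csv", index=False)
    data.diagnoses.to_csv(out / "diagnoses.csv", index=False)
    data.prescriptions.to_csv(out / "prescriptions.csv", index=False)
    data.latent.to_csv(out / "latent_truth.csv", index=False)
    data.outcomes.to_csv(out / "outcomes.csv", index=False)


# ---------------------------------------------------------------------------
# desk-scale matched-pair simulator
# ---------------------------------------------------------------------------
def simulate_matched_pairs(
    beta,
    n_pairs: int,
    prevalence=0.3,
    count_index: int | None = None,
    count_mean: float = 5.3,
    seed: int = 0,
) -> np.ndarray:
    """Simulate case-minus-control difference rows with known log-ORs.

    Two exchangeable pair members are drawn i.i.d. (binary covariates with
    the given prevalence(s); optionally one truncated-Poisson count column
    at ``count_index``), and the case label is assigned within each pair
    with probability sigmoid((x1 - x2) . beta) for member one — exactly the
    conditional likelihood of the matched design, so the returned
    difference matrix has true coefficient vector ``beta``.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    p = len(beta)
    prev = np.broadcast_to(np.asarray(prevalence, dtype=float), (p,))
    x1 = (rng.random((n_pairs, p)) < prev).astype(float)
    x2 = (rng.random((n_pairs, p)) < prev).astype(float)
    if count_index is not None:
        x1[:, count_index] = rng.poisson(count_mean, n_pairs)
        x2[:, count_index] = rng.poisson(count_mean, n_pairs)
    diff = x1 - x2
    first_is_case = rng.random(n_pairs) < expit(diff @ beta)
    return np.where(first_is_case[:, None], diff, -diff)
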