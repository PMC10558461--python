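"""Case/control selection and 1:1 matching on sex and 5-year age band.

Cases are patients aged >= 65 whose *initial* confirmed femoral-fracture
diagnosis (ICD-10 prefix S72) falls inside the selection window; the
diagnosis date is the index date.  Controls are the remaining elderly
patients, each assigned a uniformly random index date in the window.
Matching is greedy without replacement in randomized case order, exact on
sex and on 5-year age bands anchored at the 65-year eligibility floor
([65,70), [70,75), ..., top band 95+).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import CASE_CODE_PREFIX
from .config import DateWindow, stage_rng
from .errors import SchemaError
from .synth import age_in_years

COHORT_COLUMNS = [
    "pair_id",
    "role",
    "patient_id",
    "index_date",
    "age_at_index",
    "sex",
    "age_band",
]


def age_band(ages, band_width: int = 5) -> np.ndarray:
    """Age-band label anchored at 65; the top band absorbs ages >= 95
    (more generally, everything from the last full band upward)."""
    ages = np.asarray(ages)
    top = (100 - 65 - 1) // band_width
    return np.minimum((ages - 65) // band_width, top)


def _parse_dates(frame: pd.DataFrame, column: str) -> pd.Series:
    try:
        return pd.to_datetime(frame[column], format="ISO8601")
    except (ValueError, TypeError) as e:
        bad = pd.to_datetime(frame[column], format="ISO8601", errors="coerce")
        rows = list(frame.index[bad.isna() & frame[column].notna()][:10])
        raise SchemaError(f"{column}: unparseable dates at rows {rows}") from e


def _qualifying_first_dx(diagnoses: pd.DataFrame, code_prefixes) -> pd.DataFrame:
    """Earliest confirmed diagnosis per patient whose code starts with any
    configured prefix (searched over all time, not only the window)."""
    dx = diagnoses.copy()
    dx["start_date"] = _parse_dates(dx, "start_date")
    prefixes = tuple(code_prefixes)
    hit = dx["confirmed"].astype(bool) & dx["icd10_code"].astype(str).str.startswith(
        prefixes
    )
    qual = dx.loc[hit, ["patient_id", "start_date"]]
    return qual.groupby("patient_id", as_index=False)["start_date"].min()


def select_cases(
    diagnoses: pd.DataFrame,
    patients: pd.DataFrame,
    window: DateWindow,
    code_prefixes=(CASE_CODE_PREFIX,),
) -> pd.DataFrame:
    """Case records: (patient_id, index_date, age_at_index, sex).

    A patient whose earliest qualifying diagnosis precedes the window is
    excluded outright (the in-window event would not be the initial one);
    one whose earliest falls after the window is simply not a case.
    """
    first = _qualifying_first_dx(diagnoses, code_prefixes)
    first = first.merge(patients[["patient_id", "sex", "birth_date"]], on="patient_id")
    start = pd.Timestamp(window.start)
    end = pd.Timestamp(window.end)
    inside = first[(first["start_date"] >= start) & (first["start_date"] <= end)].copy()
    inside["age_at_index"] = age_in_years(
        inside["birth_date"].to_numpy(), inside["start_date"].to_numpy().astype("datetime64[D]")
    )
    inside = inside[inside["age_at_index"] >= 65]
    out = inside.rename(columns={"start_date": "index_date"})[
        ["patient_id", "index_date", "age_at_index", "sex"]
    ]
    return out.sort_values("patient_id", kind="stable").reset_index(drop=True)


def select_controls(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    window: DateWindow,
    seed: int,
    exclusion: str = "through_index",
    code_prefixes=(CASE_CODE_PREFIX,),
) -> pd.DataFrame:
    """Control candidates: every non-case elderly patient with a uniformly
    random index date in the window.

    ``exclusion`` governs the fracture-free requirement: "through_index"
    demands no qualifying diagnosis on or before the candidate's own index
    date (incidence-density style); "ever" excludes any patient with a
    qualifying diagnosis at any time.
    """
    cases = select_cases(diagnoses, patients, window, code_prefixes)
    pool = patients[~patients["patient_id"].isin(cases["patient_id"])].copy()
    if pool.empty:
        return pd.DataFrame(columns=["patient_id", "index_date", "age_at_index", "sex"])
    rng = stage_rng(seed, "controls")
    pool = pool.sort_values("patient_id", kind="stable").reset_index(drop=True)
    pool["index_date"] = window.random_dates(rng, len(pool))

    first = _qualifying_first_dx(diagnoses, code_prefixes)
    pool = pool.merge(
        first.rename(columns={"start_date": "first_qual"}), on="patient_id", how="left"
    )
    if exclusion == "ever":
        pool = pool[pool["first_qual"].isna()]
    else:
        pool = pool[
            pool["first_qual"].isna()
            | (pool["first_qual"] > pd.to_datetime(pool["index_date"]))
        ]
    pool["age_at_index"] = age_in_years(
        pool["birth_date"].to_numpy(), pool["index_date"].to_numpy()
    )
    pool = pool[pool["age_at_index"] >= 65]
    return pool[["patient_id", "index_date", "age_at_index", "sex"]].reset_index(
        drop=True
    )


@dataclass
class MatchedCohort:
    """1:1 matched pairs plus the log of unmatchable cases."""

    pairs: pd.DataFrame  # pair_id, case_*, control_* columns
    band_width: int
    seed: int
    selection_log: list = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        """Long format, one row per subject (cohort.csv layout)."""
        rows = []
        for role in ("case", "control"):
            part = self.pairs[
                ["pair_id", f"{role}_patient_id", f"{role}_index_date",
                 f"{role}_age", "sex", "age_band"]
            ].copy()
            part.columns = COHORT_COLUMNS[:1] + ["patient_id", "index_date",
                                                 "age_at_index", "sex", "age_band"]
            part.insert(1, "role", role)
            rows.append(part)
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["pair_id", "role"], kind="stable").reset_index(drop=True)


def match_pairs(
    cases: pd.DataFrame,
    candidates: pd.DataFrame,
    band_width: int = 5,
    seed: int = 0,
) -> MatchedCohort:
    """Greedy 1:1 matching without replacement, exact on (sex, age band).

    Cases are visited in a seed-determined random order; each draws one
    control uniformly at random from the unused candidates of its stratum.
    Within a stratum this is equivalent to pairing independent random
    permutations of its cases and candidates, which is how it is computed.
    Unmatched cases are dropped and logged.
    """
    rng = stage_rng(seed, "matching")
    cases = cases.copy()
    candidates = candidates.copy()
    cases["age_band"] = age_band(cases["age_at_index"], band_width)
    candidates["age_band"] = age_band(candidates["age_at_index"], band_width)

    # global randomized case order; determines who loses out in deficient
    # strata and the pair numbering
    case_order = rng.permutation(len(cases))
    cases = cases.iloc[case_order].reset_index(drop=True)

    log: list = []
    matched = []
    for (sex, band), grp in cases.groupby(["sex", "age_band"], sort=True):
        pool = candidates[
            (candidates["sex"] == sex) & (candidates["age_band"] == band)
        ]
        pool = pool.iloc[rng.permutation(len(pool))]
        m = min(len(grp), len(pool))
        take_cases = grp.iloc[:m]
        take_ctrl = pool.iloc[:m]
        for _, row in grp.iloc[m:].iterrows():
            log.append(
                {
                    "patient_id": row["patient_id"],
                    "sex": sex,
                    "age_band": int(band),
                    "reason": "no unused control in stratum",
                }
            )
        if m == 0:
            continue
        block = pd.DataFrame(
            {
                "case_order": take_cases.index.to_numpy(),
                "case_patient_id": take_cases["patient_id"].to_numpy(),
                "case_index_date": take_cases["index_date"].to_numpy(),
                "case_age": take_cases["age_at_index"].to_numpy(),
                "control_patient_id": take_ctrl["patient_id"].to_numpy(),
                "control_index_date": take_ctrl["index_date"].to_numpy(),
                "control_age": take_ctrl["age_at_index"].to_numpy(),
                "sex": sex,
                "age_band": int(band),
            }
        )
        matched.append(block)

    if matched:
        pairs = pd.concat(matched, ignore_index=True)
        pairs = pairs.sort_values("case_order", kind="stable").reset_index(drop=True)
        pairs.insert(0, "pair_id", np.arange(1, len(pairs) + 1))
        pairs = pairs.drop(columns="case_order")
    else:
        pairs = pd.DataFrame(
            columns=[
                "pair_id", "case_patient_id", "case_index_date", "case_age",
                "control_patient_id", "control_index_date", "control_age",
                "sex", "age_band",
            ]
        )
    return MatchedCohort(pairs=pairs, band_width=band_width, seed=seed, selection_log=log)


def build_cohort(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    window: DateWindow,
    band_width: int = 5,
    seed: int = 0,
    control_exclusion: str = "through_index",
) -> MatchedCohort:
    """select_cases + select_controls + match_pairs in one call."""
    cases = select_cases(diagnoses, patients, window)
    controls = select_controls(
        patients, diagnoses, window, seed=seed, exclusion=control_exclusion
    )
    return match_pairs(cases, controls, band_width=band_width, seed=seed)
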