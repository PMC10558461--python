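"""From raw claims events to the 77 analysis covariates per subject.

Prescriptions are first collapsed into drug *episodes*: per (patient, raw
drug code), each prescription covers [start, start + days_supplied - 1] and
consecutive coverage intervals separated by a gap of at most ``grace_days``
(default 7) are chained into one episode.  A medication-category flag is on
when some episode started before the index date and ran to within 7 days
of it; the medication count is the maximum number of distinct raw drugs
simultaneously covered on any day of the 7-day pre-index window.
Comorbidity flags require a confirmed diagnosis started before the index
date with no end date registered by it.

The module also produces the case/control descriptive table with
standardized differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import CategoryMaps, default_maps
from .errors import MappingError, SchemaError

RECENCY_DAYS = 7  # "discontinued within 7 days of the index date"

EPISODE_COLUMNS = ["patient_id", "drug_code", "med_category", "episode_start", "episode_end"]


# ---------------------------------------------------------------------------
# drug episodes
# ---------------------------------------------------------------------------
def build_drug_intervals(
    prescriptions: pd.DataFrame,
    maps: CategoryMaps | None = None,
    grace_days: int = 7,
) -> pd.DataFrame:
    """Chain prescriptions into continuous-treatment episodes.

    Two coverage intervals of the same (patient, drug) belong to one
    episode when the uncovered gap between them (next start - previous
    end - 1, in days) does not exceed ``grace_days``; overlaps always merge.
    """
    maps = maps or default_maps()
    if prescriptions.empty:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    rx = prescriptions.copy()
    rx["start_date"] = pd.to_datetime(rx["start_date"])
    days = rx["days_supplied"].astype(int)
    if (days < 1).any():
        raise SchemaError("days_supplied: must be >= 1")
    cat = maps.med_indices(rx["drug_code"].astype(str))
    rx["med_category"] = np.asarray(maps.med_variables, dtype=object)[cat]
    rx["end_date"] = rx["start_date"] + pd.to_timedelta(days - 1, unit="D")

    rx = rx.sort_values(["patient_id", "drug_code", "start_date"], kind="stable")
    keys = [rx["patient_id"], rx["drug_code"]]
    prev_end = rx["end_date"].groupby(keys, sort=False).cummax().groupby(keys, sort=False).shift()
    new_episode = prev_end.isna() | (
        rx["start_date"] > prev_end + pd.Timedelta(days=grace_days + 1)
    )
    eid = new_episode.groupby(keys, sort=False).cumsum()
    episodes = (
        rx.assign(_eid=eid)
        .groupby(["patient_id", "drug_code", "med_category", "_eid"], sort=False)
        .agg(episode_start=("start_date", "min"), episode_end=("end_date", "max"))
        .reset_index()
        .drop(columns="_eid")
    )
    return episodes[EPISODE_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# single-subject rules (reference semantics; the bulk path vectorizes them)
# ---------------------------------------------------------------------------
def concomitant_flags(
    episodes: pd.DataFrame, index_date, maps: CategoryMaps | None = None
) -> np.ndarray:
    """60 medication-category flags for one subject.

    Flag = 1 iff some episode started strictly before the index date and
    ended no earlier than (index - 7 days).
    """
    maps = maps or default_maps()
    flags = np.zeros(len(maps.med_variables), dtype=np.int8)
    if episodes.empty:
        return flags
    idx = pd.Timestamp(index_date)
    ok = (episodes["episode_start"] < idx) & (
        episodes["episode_end"] >= idx - pd.Timedelta(days=RECENCY_DAYS)
    )
    pos = {v: i for i, v in enumerate(maps.med_variables)}
    for cat in episodes.loc[ok, "med_category"].unique():
        flags[pos[cat]] = 1
    return flags


def medication_count(
    episodes: pd.DataFrame, index_date, count_window: str = "pre"
) -> int:
    """Maximum daily count of distinct raw drugs near the index date.

    Counts, for each day of the window ([index-7, index] for "pre",
    [index-7, index+7] for "centered"), the distinct raw drugs with an
    episode covering that day, and returns the maximum.
    """
    if episodes.empty:
        return 0
    idx = pd.Timestamp(index_date)
    offsets = range(-RECENCY_DAYS, 1) if count_window == "pre" else range(
        -RECENCY_DAYS, RECENCY_DAYS + 1
    )
    best = 0
    for k in offsets:
        day = idx + pd.Timedelta(days=k)
        m = (episodes["episode_start"] <= day) & (episodes["episode_end"] >= day)
        best = max(best, int(episodes.loc[m, "drug_code"].nunique()))
    return best


def comorbidity_flags(
    diagnoses: pd.DataFrame, index_date, maps: CategoryMaps | None = None
) -> np.ndarray:
    """16 chapter flags for one subject.

    Flag = 1 iff a confirmed diagnosis in the chapter started strictly
    before the index date and has no end date registered by it (no end, or
    an end after the index date).
    """
    maps = maps or default_maps()
    flags = np.zeros(len(maps.chapter_variables), dtype=np.int8)
    if diagnoses.empty:
        return flags
    dx = diagnoses.copy()
    dx["start_date"] = pd.to_datetime(dx["start_date"])
    dx["end_date"] = pd.to_datetime(dx.get("end_date"))
    idx = pd.Timestamp(index_date)
    ok = (
        dx["confirmed"].astype(bool)
        & (dx["start_date"] < idx)
        & (dx["end_date"].isna() | (dx["end_date"] > idx))
    )
    for code in dx.loc[ok, "icd10_code"].astype(str).unique():
        ch = maps.chapter_index(code)
        if ch is None:
            raise MappingError(f"unmapped ICD-10 code: {code!r}")
        flags[ch] = 1
    return flags


# ---------------------------------------------------------------------------
# bulk derivation
# ---------------------------------------------------------------------------
def derive_covariates(
    subjects: pd.DataFrame,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    maps: CategoryMaps | None = None,
    grace_days: int = 7,
    count_window: str = "pre",
) -> pd.DataFrame:
    """Covariate vectors for many subjects at their own index dates.

    ``subjects`` needs columns patient_id and index_date (one row per
    subject).  Returns one row per subject with med_count, the 60 rx*
    flags and the 16 cm_* flags.
    """
    maps = maps or default_maps()
    sub = subjects[["patient_id", "index_date"]].copy()
    sub["index_date"] = pd.to_datetime(sub["index_date"])
    if sub["patient_id"].duplicated().any():
        dup = sub.loc[sub["patient_id"].duplicated(), "patient_id"].tolist()[:5]
        raise SchemaError(f"subjects: duplicate patient ids {dup}")
    out = pd.DataFrame({"patient_id": sub["patient_id"].to_numpy()})
    for v in ["med_count", *maps.chapter_variables, *maps.med_variables]:
        out[v] = 0
    out = out.set_index("patient_id")

    wanted = set(sub["patient_id"])
    rx = prescriptions[prescriptions["patient_id"].isin(wanted)]
    episodes = build_drug_intervals(rx, maps, grace_days)
    if not episodes.empty:
        ep = episodes.merge(sub, on="patient_id")
        idx = ep["index_date"]
        active = (ep["episode_start"] < idx) & (
            ep["episode_end"] >= idx - pd.Timedelta(days=RECENCY_DAYS)
        )
        flags = (
            ep.loc[active]
            .groupby(["patient_id", "med_category"])
            .size()
            .clip(upper=1)
            .unstack(fill_value=0)
        )
        out.loc[flags.index, flags.columns] = flags.astype(np.int8)

        offsets = range(-RECENCY_DAYS, 1) if count_window == "pre" else range(
            -RECENCY_DAYS, RECENCY_DAYS + 1
        )
        start = ep["episode_start"].to_numpy()
        end = ep["episode_end"].to_numpy()
        idx_np = idx.to_numpy()
        pid = ep["patient_id"].to_numpy()
        best = pd.Series(0, index=out.index)
        for k in offsets:
            day = idx_np + np.timedelta64(k, "D")
            covered = (start <= day) & (end >= day)
            # episodes of one drug are >grace apart, so rows covering a
            # given day are automatically distinct raw drugs
            cnt = pd.Series(covered).groupby(pid).sum()
            best.loc[cnt.index] = np.maximum(best.loc[cnt.index], cnt)
        out["med_count"] = best

    dx = diagnoses[diagnoses["patient_id"].isin(wanted)]
    if not dx.empty:
        dx = dx.copy()
        dx["start_date"] = pd.to_datetime(dx["start_date"])
        dx["end_date"] = pd.to_datetime(dx.get("end_date"))
        codes = dx["icd10_code"].astype(str)
        chapter_by_code = {}
        for code in codes.unique():
            ch = maps.chapter_index(code)
            if ch is None:
                raise MappingError(f"unmapped ICD-10 code: {code!r}")
            chapter_by_code[code] = maps.chapter_variables[ch]
        dx["chapter"] = codes.map(chapter_by_code)
        dxm = dx.merge(sub, on="patient_id")
        ok = (
            dxm["confirmed"].astype(bool)
            & (dxm["start_date"] < dxm["index_date"])
            & (dxm["end_date"].isna() | (dxm["end_date"] > dxm["index_date"]))
        )
        cflags = (
            dxm.loc[ok]
            .groupby(["patient_id", "chapter"])
            .size()
            .clip(upper=1)
            .unstack(fill_value=0)
        )
        out.loc[cflags.index, cflags.columns] = cflags.astype(np.int8)

    return out.reset_index()


# ---------------------------------------------------------------------------
# analysis dataset
# ---------------------------------------------------------------------------
@dataclass
class AnalysisDataset:
    """Matched pairs with their covariate vectors, ready for modelling.

    ``data`` holds one row per subject: pair_id, role (case/control),
    patient_id, stratum ("early"/"late"), age_at_index, sex, and the
    analysis variables.
    """

    data: pd.DataFrame
    variables: list
    labels: dict

    @property
    def n_pairs(self) -> int:
        return self.data["pair_id"].nunique()

    @property
    def strata(self) -> pd.Series:
        """Stratum label per pair, indexed by pair_id (sorted)."""
        return (
            self.data[self.data["role"] == "case"]
            .set_index("pair_id")["stratum"]
            .sort_index()
        )

    def filter(self, stratum: str = "all") -> "AnalysisDataset":
        if stratum == "all":
            return self
        keep = self.data["stratum"] == stratum
        return AnalysisDataset(
            self.data[keep].reset_index(drop=True), self.variables, self.labels
        )

    def _matrix(self, role: str) -> np.ndarray:
        part = self.data[self.data["role"] == role].sort_values("pair_id")
        return part[self.variables].to_numpy(dtype=float)

    def case_matrix(self) -> np.ndarray:
        return self._matrix("case")

    def control_matrix(self) -> np.ndarray:
        return self._matrix("control")

    def pair_ids(self) -> np.ndarray:
        return np.sort(self.data["pair_id"].unique())

    def subject_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) over all subjects: covariates and case indicator."""
        X = self.data[self.variables].to_numpy(dtype=float)
        y = (self.data["role"] == "case").to_numpy()
        return X, y


def build_design(
    cohort_frame: pd.DataFrame,
    covariates: pd.DataFrame,
    maps: CategoryMaps | None = None,
) -> AnalysisDataset:
    """Join the matched cohort with derived covariates.

    Pair stratum is "early" when the case's age at index is < 75, "late"
    otherwise; with 5-year bands anchored at 65 both pair members fall on
    the same side of the cutoff.
    """
    maps = maps or default_maps()
    variables = ["med_count", *maps.chapter_variables, *maps.med_variables]
    if cohort_frame.empty:
        data = pd.DataFrame(
            columns=["pair_id", "role", "patient_id", "stratum", "age_at_index", "sex"]
            + variables
        )
        return AnalysisDataset(data, variables, maps.variable_labels())
    merged = cohort_frame.merge(covariates, on="patient_id", how="left")
    missing = merged.loc[merged[variables[0]].isna(), "patient_id"].tolist()
    if missing:
        raise SchemaError(f"missing covariate vectors for patients: {missing[:10]}")
    case_age = merged[merged["role"] == "case"].set_index("pair_id")["age_at_index"]
    merged["stratum"] = np.where(
        merged["pair_id"].map(case_age) < 75, "early", "late"
    )
    cols = ["pair_id", "role", "patient_id", "stratum", "age_at_index", "sex"] + variables
    data = merged[cols].sort_values(["pair_id", "role"], kind="stable").reset_index(drop=True)
    return AnalysisDataset(data, variables, maps.variable_labels())


# ---------------------------------------------------------------------------
# standardized differences and the descriptive table
# ---------------------------------------------------------------------------
def standardized_difference_binary(count1: int, n1: int, count2: int, n2: int) -> float:
    """(p1 - p2) / sqrt((p1 q1 + p2 q2) / 2) from exact counts."""
    p1, p2 = count1 / n1, count2 / n2
    pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2
    if pooled == 0:
        return 0.0 if p1 == p2 else math.copysign(float("inf"), p1 - p2)
    return (p1 - p2) / math.sqrt(pooled)


def standardized_difference_continuous(m1: float, s1: float, m2: float, s2: float) -> float:
    """(m1 - m2) / sqrt((s1^2 + s2^2) / 2), the unpooled-average form."""
    pooled = (s1 * s1 + s2 * s2) / 2
    if pooled == 0:
        return 0.0 if m1 == m2 else math.copysign(float("inf"), m1 - m2)
    return (m1 - m2) / math.sqrt(pooled)


def standardized_difference(case, control, kind: str = "binary") -> float:
    """Dispatch form: binary takes (count, n) per group, continuous (mean, sd)."""
    if kind == "binary":
        return standardized_difference_binary(case[0], case[1], control[0], control[1])
    if kind == "continuous":
        return standardized_difference_continuous(case[0], case[1], control[0], control[1])
    raise ValueError(f"kind must be 'binary' or 'continuous', got {kind!r}")


def _fmt_binary(n: int, total: int) -> str:
    return f"{n:,} ({100 * n / total:.1f})"


def _fmt_continuous(mean: float, sd: float) -> str:
    return f"{mean:.1f} ({sd:.1f})"


def descriptive_table(dataset: AnalysisDataset, count_cap: int = 15) -> pd.DataFrame:
    """Case/control characteristics with standardized differences.

    Matched variables (age category, sex) are balanced by construction and
    reported with std_diff = NaN (rendered as a dash).  Medication-count
    categories 0..14 and >= 15 are binary rows; the mean medication and
    comorbidity counts are continuous rows.
    """
    if dataset.data.empty:
        raise ValueError("descriptive_table: empty dataset")
    d = dataset.data
    cases = d[d["role"] == "case"]
    ctrls = d[d["role"] == "control"]
    n1, n2 = len(cases), len(ctrls)
    chapter_vars = [v for v in dataset.variables if v.startswith("cm_")]
    med_vars = [v for v in dataset.variables if v.startswith("rx")]
    rows = []

    def add_binary(name, c1, c2, matched=False):
        sd = np.nan if matched else standardized_difference_binary(c1, n1, c2, n2)
        rows.append(
            {
                "variable": name,
                "kind": "binary",
                "case_stat": _fmt_binary(c1, n1),
                "control_stat": _fmt_binary(c2, n2),
                "case_n": c1,
                "control_n": c2,
                "std_diff": np.nan if matched else round(sd, 3),
                "matched": matched,
            }
        )

    def add_continuous(name, x1, x2):
        m1, s1 = float(np.mean(x1)), float(np.std(x1, ddof=1))
        m2, s2 = float(np.mean(x2)), float(np.std(x2, ddof=1))
        rows.append(
            {
                "variable": name,
                "kind": "continuous",
                "case_stat": _fmt_continuous(m1, s1),
                "control_stat": _fmt_continuous(m2, s2),
                "case_n": np.nan,
                "control_n": np.nan,
                "std_diff": round(standardized_difference_continuous(m1, s1, m2, s2), 3),
                "matched": False,
            }
        )

    add_binary(
        "Age category: early elderly",
        int((cases["age_at_index"] < 75).sum()),
        int((ctrls["age_at_index"] < 75).sum()),
        matched=True,
    )
    add_binary(
        "Age category: late elderly",
        int((cases["age_at_index"] >= 75).sum()),
        int((ctrls["age_at_index"] >= 75).sum()),
        matched=True,
    )
    for sex in ("male", "female"):
        add_binary(
            f"Sex: {sex}",
            int((cases["sex"] == sex).sum()),
            int((ctrls["sex"] == sex).sum()),
            matched=True,
        )
    ccount = cases["med_count"].to_numpy()
    kcount = ctrls["med_count"].to_numpy()
    for k in range(count_cap):
        add_binary(f"Number of medications: {k}", int((ccount == k).sum()), int((kcount == k).sum()))
    add_binary(
        f"Number of medications: >= {count_cap}",
        int((ccount >= count_cap).sum()),
        int((kcount >= count_cap).sum()),
    )
    add_continuous("Number of medications, mean (SD)", ccount, kcount)
    add_continuous(
        "Number of comorbidities, mean (SD)",
        cases[chapter_vars].sum(axis=1).to_numpy(),
        ctrls[chapter_vars].sum(axis=1).to_numpy(),
    )
    for v in chapter_vars + med_vars:
        add_binary(
            dataset.labels.get(v, v), int(cases[v].sum()), int(ctrls[v].sum())
        )
    return pd.DataFrame(rows)
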