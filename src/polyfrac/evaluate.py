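"""Predictive evaluation: ROC/AUC, Youden cutoff, odds-ratio forests,
nested variable-set comparison, stepwise baseline, external validation.

AUC is the Mann-Whitney statistic (ties counted half) with an asymptotic
rank-covariance (DeLong-type) confidence interval by default; a
subject-level stratified bootstrap is available as an alternative.
Subjects are scored with the fitted linear predictor x . beta-hat; in the
matched design both pair members are scored and treated as independent
observations with prevalence one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .exposure import AnalysisDataset
from .model import (
    ConditionalLogisticLasso,
    ConditionalLogisticRegression,
    DiffMatrix,
    FitResult,
    neg_log_clik,
    pair_difference,
)

_Z975 = 1.959963984540054


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------
def _beta_names(fit) -> tuple[np.ndarray, list]:
    if isinstance(fit, FitResult):
        return fit.beta, list(fit.names)
    return fit.coef_, list(fit.names_)


def score_subjects(fit, dataset: AnalysisDataset) -> pd.DataFrame:
    """Linear predictor per subject with the case/control label.

    Non-estimable (NaN) coefficients contribute zero, i.e. the variable is
    omitted from the score.
    """
    beta, names = _beta_names(fit)
    missing = [n for n in names if n not in dataset.data.columns]
    if missing:
        raise ValueError(f"dataset lacks fitted variables: {missing[:10]}")
    X = dataset.data[names].to_numpy(dtype=float)
    scores = X @ np.nan_to_num(beta, nan=0.0)
    return pd.DataFrame(
        {
            "pair_id": dataset.data["pair_id"].to_numpy(),
            "role": dataset.data["role"].to_numpy(),
            "patient_id": dataset.data["patient_id"].to_numpy(),
            "label": (dataset.data["role"] == "case").to_numpy(),
            "score": scores,
        }
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------
def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def _delong(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney AUC and its DeLong variance."""
    m, n = len(cases), len(controls)
    tz = _midranks(np.concatenate([cases, controls]))
    tx = _midranks(cases)
    ty = _midranks(controls)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components per case
    v10 = 1.0 - (tz[m:] - ty) / m  # per control
    var = 0.0
    if m > 1:
        var += v01.var(ddof=1) / m
    if n > 1:
        var += v10.var(ddof=1) / n
    return float(auc), float(var)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    ci_method: str
    scores: np.ndarray
    labels: np.ndarray

    def points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_auc(
    scores,
    labels,
    ci_method: str = "delong",
    n_boot: int = 500,
    seed: int = 0,
) -> ROCResult:
    """Empirical ROC and AUC with a 95% confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cases, controls = scores[labels], scores[~labels]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("roc_auc: both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc, var = _delong(cases, controls)
    if ci_method == "delong":
        half = _Z975 * np.sqrt(var)
        lo, hi = auc - half, auc + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        stats = np.empty(n_boot)
        for b in range(n_boot):
            cs = rng.choice(cases, len(cases))
            ks = rng.choice(controls, len(controls))
            stats[b] = _delong(cs, ks)[0]
        lo, hi = np.quantile(stats, [0.025, 0.975])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ROCResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        ci_low=float(max(0.0, lo)),
        ci_high=float(min(1.0, hi)),
        ci_method=ci_method,
        scores=scores,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Youden cutoff
# ---------------------------------------------------------------------------
@dataclass
class MetricsAtCutoff:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def youden_cutoff(roc: ROCResult) -> MetricsAtCutoff:
    """Cutoff maximizing sensitivity + specificity - 1.

    A subject is called a predicted case when score >= cutoff; among tied
    maximizers the lowest cutoff (highest sensitivity) is returned.
    """
    s, y = roc.scores, roc.labels
    case_sorted = np.sort(s[y])
    ctrl_sorted = np.sort(s[~y])
    m, n = len(case_sorted), len(ctrl_sorted)
    cand = np.unique(s)
    sens = (m - np.searchsorted(case_sorted, cand, side="left")) / m
    spec = np.searchsorted(ctrl_sorted, cand, side="left") / n
    j = int(np.argmax(sens + spec - 1.0))  # first max = lowest cutoff
    c = float(cand[j])
    tp = float(m * sens[j])
    fn = m - tp
    tn = float(n * spec[j])
    fp = n - tn
    ppv = tp / (tp + fp) if tp + fp > 0 else np.nan
    npv = tn / (tn + fn) if tn + fn > 0 else np.nan
    return MetricsAtCutoff(
        cutoff=c,
        sensitivity=float(sens[j]),
        specificity=float(spec[j]),
        ppv=float(ppv),
        npv=float(npv),
    )


# ---------------------------------------------------------------------------
# medication-count odds-ratio forest
# ---------------------------------------------------------------------------
def medcount_forest(
    dataset: AnalysisDataset,
    strata=("all", "early", "late"),
    count_cap: int = 15,
) -> pd.DataFrame:
    """Odds ratios by medication-count category, reference category 0.

    One unpenalized conditional logistic fit per stratum, on indicator
    differences for categories 1..count_cap-1 and >= count_cap.  Empty or
    constant categories come back as not-estimable rows (NaN), as does an
    entire stratum when the fit is non-identifiable.
    """

    def one_hot(counts):
        cats = np.minimum(counts.astype(int), count_cap)
        out = np.zeros((len(cats), count_cap))  # columns: 1..count_cap
        for j in range(1, count_cap + 1):
            out[:, j - 1] = cats == j
        return out

    labels_ = [str(k) for k in range(count_cap)] + [f">= {count_cap}"]
    names = [f"count_{k}" for k in range(1, count_cap + 1)]
    rows = []
    for st in strata:
        ds = dataset.filter(st)
        entry = {lab: (np.nan, np.nan, np.nan) for lab in labels_[1:]}
        if ds.n_pairs > 0:
            cc = ds.data.loc[ds.data["role"] == "case"].sort_values("pair_id")
            kk = ds.data.loc[ds.data["role"] == "control"].sort_values("pair_id")
            Dm = one_hot(cc["med_count"].to_numpy()) - one_hot(kk["med_count"].to_numpy())
            # sparse top categories with one-sided discordance separate the
            # conditional likelihood; report them as not estimable instead
            usable = [
                j
                for j in range(count_cap)
                if np.abs(Dm[:, j]).sum() >= 5
                and (Dm[:, j] > 0).any()
                and (Dm[:, j] < 0).any()
            ]
            try:
                if not usable:
                    raise ValueError("no estimable categories")
                fit = ConditionalLogisticRegression().fit(
                    DiffMatrix(Dm[:, usable], [names[j] for j in usable])
                )
                with np.errstate(over="ignore"):
                    for k, j in enumerate(usable):
                        entry[labels_[j + 1]] = (
                            fit.odds_ratios_[k],
                            float(np.exp(fit.ci_low_[k])),
                            float(np.exp(fit.ci_high_[k])),
                        )
            except ValueError:
                pass  # non-identifiable stratum: all rows not estimable
        rows.append(
            {
                "stratum": st,
                "category": "0",
                "odds_ratio": 1.0,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "reference": True,
            }
        )
        for lab in labels_[1:]:
            or_, lo, hi = entry[lab]
            rows.append(
                {
                    "stratum": st,
                    "category": lab,
                    "odds_ratio": or_,
                    "ci_low": lo,
                    "ci_high": hi,
                    "reference": False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nested variable-set comparison
# ---------------------------------------------------------------------------
def _variable_sets(dataset: AnalysisDataset):
    cm = [v for v in dataset.variables if v.startswith("cm_")]
    rx = [v for v in dataset.variables if v.startswith("rx")]
    return (
        ("count", ["med_count"]),
        ("count+comorbidities", ["med_count"] + cm),
        ("count+medications", ["med_count"] + rx),
        ("all", ["med_count"] + cm + rx),
    )


def nested_model_comparison(
    dataset: AnalysisDataset,
    seed: int = 0,
    strata=("all", "early", "late"),
    n_lambda: int = 60,
    lambda_min_ratio: float = 0.01,
    cv: int = 5,
    rule: str = "min",
    tol: float = 1e-6,
) -> pd.DataFrame:
    """AUC/sensitivity/specificity/PPV/NPV over four nested variable sets.

    The one-variable model (medication count only) is fitted by plain
    conditional logistic regression; the larger sets by the conditional
    lasso at the cross-validation-selected penalty.  Failures are recorded
    per cell and the grid continues.
    """
    rows = []
    for st in strata:
        ds = dataset.filter(st)
        for set_name, variables in _variable_sets(dataset):
            row = {
                "stratum": st,
                "variable_set": set_name,
                "n_variables": len(variables),
            }
            try:
                sub = AnalysisDataset(ds.data, variables, dataset.labels)
                Dm = pair_difference(sub)
                if len(variables) == 1:
                    fit = ConditionalLogisticRegression().fit(Dm).result()
                else:
                    est = ConditionalLogisticLasso(
                        lam="cv",
                        n_lambda=n_lambda,
                        lambda_min_ratio=lambda_min_ratio,
                        cv=cv,
                        rule=rule,
                        tol=tol,
                        random_state=seed,
                    )
                    fit = est.fit(Dm).result()
                scored = score_subjects(fit, sub)
                roc = roc_auc(scored["score"], scored["label"])
                mk = youden_cutoff(roc)
                row.update(
                    n_selected=len(fit.selected),
                    auc=roc.auc,
                    auc_ci_low=roc.ci_low,
                    auc_ci_high=roc.ci_high,
                    sensitivity=mk.sensitivity,
                    specificity=mk.specificity,
                    ppv=mk.ppv,
                    npv=mk.npv,
                    error="",
                )
            except (ValueError, np.linalg.LinAlgError) as e:
                row.update(
                    n_selected=np.nan,
                    auc=np.nan,
                    auc_ci_low=np.nan,
                    auc_ci_high=np.nan,
                    sensitivity=np.nan,
                    specificity=np.nan,
                    ppv=np.nan,
                    npv=np.nan,
                    error=str(e),
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stepwise baseline
# ---------------------------------------------------------------------------
@dataclass
class StepwiseResult:
    selected: list
    aic: float
    fit: FitResult | None
    auc: float | None
    converged: bool


def stepwise_logistic(
    data,
    criterion: str = "AIC",
    max_steps: int = 200,
) -> StepwiseResult:
    """Forward-backward stepwise selection on the pair-difference model.

    Operates on the same intercept-free conditional likelihood as the
    lasso, adding or removing one variable at a time while the information
    criterion improves.  Accepts an AnalysisDataset (AUC of the final
    model is then computed on subjects) or a DiffMatrix.
    """
    if criterion != "AIC":
        raise ValueError("criterion: only 'AIC' is supported")
    if isinstance(data, AnalysisDataset):
        dataset, Dm = data, pair_difference(data)
    elif isinstance(data, DiffMatrix):
        dataset, Dm = None, data
    else:
        arr = np.asarray(data, dtype=float)
        dataset = None
        Dm = DiffMatrix(arr, [f"x{j}" for j in range(arr.shape[1])])
    names = list(Dm.names)
    active = {n for n, a in zip(names, Dm.active) if a}
    cols = {n: j for j, n in enumerate(names)}
    n = Dm.n_pairs

    def aic_of(subset):
        if not subset:
            return 2.0 * n * np.log(2.0), None
        sub = sorted(subset, key=cols.get)
        M = Dm.D[:, [cols[v] for v in sub]]
        fit = ConditionalLogisticRegression().fit(DiffMatrix(M, sub)).result()
        with np.errstate(all="ignore"):
            nll = neg_log_clik(np.nan_to_num(fit.beta, nan=0.0), M)
        return 2.0 * len(sub) + 2.0 * nll, fit

    selected: set = set()
    current_aic, current_fit = aic_of(selected)
    converged = True
    for _ in range(max_steps):
        best = (current_aic, None, None)  # aic, action, variable
        for v in sorted(active - selected):
            try:
                a, _ = aic_of(selected | {v})
            except (ValueError, np.linalg.LinAlgError):
                continue
            if a < best[0] - 1e-8:
                best = (a, "add", v)
        for v in sorted(selected):
            try:
                a, _ = aic_of(selected - {v})
            except (ValueError, np.linalg.LinAlgError):
                continue
            if a < best[0] - 1e-8:
                best = (a, "drop", v)
        if best[1] is None:
            break
        if best[1] == "add":
            selected.add(best[2])
        else:
            selected.discard(best[2])
        current_aic, current_fit = aic_of(selected)
    else:
        converged = False

    auc = None
    if dataset is not None and current_fit is not None:
        scored = score_subjects(current_fit, dataset)
        auc = roc_auc(scored["score"], scored["label"]).auc
    return StepwiseResult(
        selected=sorted(selected, key=cols.get),
        aic=current_aic,
        fit=current_fit,
        auc=auc,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------
def external_validation(fit, validation_dataset: AnalysisDataset, **roc_kwargs) -> ROCResult:
    """Score a disjoint validation cohort with the frozen coefficients."""
    scored = score_subjects(fit, validation_dataset)
    return roc_auc(scored["score"], scored["label"], **roc_kwargs)
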