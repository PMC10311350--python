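"""Right-censored survival modelling and evaluation.

Random-survival-forest risk models over per-sample feature matrices, with
patient-grouped or leave-one-coverslip-out cross-validation evaluated by
Harrell's concordance index; permutation importance; patient-level risk
aggregation and log-rank-optimal risk stratification; and Mann–Whitney
cohort enrichment tests with Bonferroni correction.

Observed data per patient is (T, δ): T the observed time and δ the event
indicator, δ = 0 meaning the observation is censored (the patient was alive
at T). Samples inherit their patient's outcome for model fitting; predicted
sample risks are averaged per patient for stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spatprot.datamodel import ClinicalTable
from spatprot.features import FeatureMatrix

__all__ = [
    "CVScheme",
    "RiskModel",
    "CohortSplit",
    "LogrankResult",
    "CVResult",
    "harrell_c",
    "fit_rsf",
    "make_folds",
    "cross_validate",
    "permutation_importance",
    "patient_risk",
    "kaplan_meier",
    "logrank_test",
    "stratify_patients",
    "cohort_feature_tests",
]

#: mandatory caveat attached to every stratification result: the threshold
#: is chosen to maximize the log-rank statistic, so the reported p-value is
#: optimistically biased (no selection adjustment is applied).
SELECTION_BIAS_CAVEAT = (
    "selection-biased p-value: the log-rank p is computed at the "
    "cutpoint that maximizes the statistic and is not adjusted for the search"
)


def harrell_c(times, events, risks) -> float:
    """Harrell's concordance index for right-censored data.

    A pair (i, j) is comparable when the shorter time is an observed event
    and times differ (pairs with equal times are excluded). The index is the
    fraction of comparable pairs in which the shorter-lived subject has the
    higher predicted risk, with risk ties counted 1/2.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    r = np.asarray(risks, dtype=float)
    if not (len(t) == len(e) == len(r)):
        raise ValueError("times, events and risks must have equal length")
    # comparable: t_i < t_j and event_i == 1
    comp = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = comp.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    conc = comp & (r[:, None] > r[None, :])
    ties = comp & (r[:, None] == r[None, :])
    return float((conc.sum() + 0.5 * ties.sum()) / n_comp)


@dataclass
class RiskModel:
    """Fitted ensemble survival model; higher predicted risk means shorter
    predicted survival. Deterministic given the fitting seed."""

    model: object
    feature_names: list[str]

    def predict_risk(self, X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.data
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy()
        return np.asarray(self.model.predict(np.atleast_2d(X)))


DEFAULT_RSF_HYPER = {
    "n_estimators": 1000,
    "max_features": "sqrt",
    "min_samples_leaf": 3,
}


def _as_structured(times, events) -> np.ndarray:
    from sksurv.util import Surv

    return Surv.from_arrays(
        event=np.asarray(events, dtype=bool), time=np.asarray(times, dtype=float)
    )


def fit_rsf(
    features: FeatureMatrix | pd.DataFrame,
    outcomes: pd.DataFrame,
    hyper: dict | None = None,
    seed: int = 0,
) -> RiskModel:
    """Fit a random survival forest (log-rank splitting) on sample rows.

    ``outcomes`` carries ``time``/``event`` per sample row, aligned with the
    feature rows (sample-level outcomes are the patient outcome copied to
    each of the patient's samples). Defaults: 1000 trees, √p candidate
    features per split.
    """
    from sksurv.ensemble import RandomSurvivalForest

    X = features.data if isinstance(features, FeatureMatrix) else features
    outcomes = outcomes.loc[X.index] if isinstance(outcomes.index, pd.Index) and set(
        X.index
    ) <= set(outcomes.index) else outcomes
    if len(outcomes) != len(X):
        raise ValueError("one outcome row is required per feature row")
    if int(outcomes["event"].sum()) == 0:
        raise ValueError("degenerate outcomes: no events observed")
    params = dict(DEFAULT_RSF_HYPER)
    if hyper:
        params.update(hyper)
    rsf = RandomSurvivalForest(random_state=seed, n_jobs=1, **params)
    rsf.fit(X.to_numpy(), _as_structured(outcomes["time"], outcomes["event"]))
    return RiskModel(rsf, list(X.columns))


@dataclass(frozen=True)
class CVScheme:
    """Grouped cross-validation scheme.

    ``patient_kfold`` partitions patients into ``n_folds`` folds (no patient
    spans folds); ``leave_one_coverslip_out`` holds out each coverslip/batch
    in turn, one fold per coverslip.
    """

    kind: str = "patient_kfold"
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("patient_kfold", "leave_one_coverslip_out"):
            raise ValueError(f"unknown CV scheme {self.kind!r}")


def make_folds(clinical: ClinicalTable, scheme: CVScheme) -> list[tuple[list, list]]:
    """Partition samples into (train_ids, test_ids) folds per the scheme."""
    df = clinical.data
    if scheme.kind == "leave_one_coverslip_out":
        slips = sorted(df["coverslip_id"].unique())
        folds = []
        for slip in slips:
            test = df.loc[df["coverslip_id"] == slip, "sample_id"].tolist()
            train = df.loc[df["coverslip_id"] != slip, "sample_id"].tolist()
            folds.append((train, test))
        return folds
    patients = np.array(sorted(df["patient_id"].unique()))
    if len(patients) < scheme.n_folds:
        raise ValueError(
            f"{len(patients)} patients cannot fill {scheme.n_folds} folds"
        )
    rng = np.random.default_rng(scheme.seed)
    rng.shuffle(patients)
    folds = []
    for chunk in np.array_split(patients, scheme.n_folds):
        test_pat = set(chunk)
        test = df.loc[df["patient_id"].isin(test_pat), "sample_id"].tolist()
        train = df.loc[~df["patient_id"].isin(test_pat), "sample_id"].tolist()
        folds.append((train, test))
    return folds


def _sample_outcomes(clinical: ClinicalTable, sample_ids) -> pd.DataFrame:
    df = clinical.data.set_index("sample_id")
    return df.loc[list(sample_ids), ["time", "event"]]


@dataclass
class CVResult:
    """Cross-validation summary: per-repeat fold-averaged concordance."""

    per_repeat: np.ndarray
    scheme: CVScheme

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_repeat))

    def ci95(self) -> tuple[float, float]:
        """Normal-approximation 95% confidence interval over repeats."""
        m = self.mean
        if len(self.per_repeat) < 2:
            return (m, m)
        half = 1.96 * np.std(self.per_repeat, ddof=1) / np.sqrt(len(self.per_repeat))
        return (m - half, m + half)


def cross_validate(
    features: FeatureMatrix | pd.DataFrame,
    clinical: ClinicalTable,
    scheme: CVScheme,
    hyper: dict | None = None,
    n_repeats: int = 100,
    seed: int = 0,
    level: str = "sample",
) -> CVResult:
    """Repeated grouped cross-validation of an RSF on the feature matrix.

    Each repeat redraws the folds (for ``patient_kfold``) and the forest
    seed, fits on the training folds and scores held-out concordance per
    fold; the per-repeat value is the fold average. ``level="patient"``
    scores concordance on patient-averaged risks instead of samples.
    """
    X = features.data if isinstance(features, FeatureMatrix) else features
    per_repeat = []
    for rep in range(n_repeats):
        rep_seed = seed + rep
        folds = make_folds(
            clinical, CVScheme(scheme.kind, scheme.n_folds, seed=rep_seed)
        )
        fold_cs = []
        for train_ids, test_ids in folds:
            train_out = _sample_outcomes(clinical, train_ids)
            model = fit_rsf(X.loc[train_ids], train_out, hyper, seed=rep_seed)
            risks = model.predict_risk(X.loc[test_ids])
            test_out = _sample_outcomes(clinical, test_ids)
            if level == "patient":
                s2p = clinical.sample_to_patient()
                pr = patient_risk(pd.Series(risks, index=test_ids), s2p)
                po = clinical.patient_outcomes().loc[pr.index]
                fold_cs.append(harrell_c(po["time"], po["event"], pr))
            else:
                fold_cs.append(harrell_c(test_out["time"], test_out["event"], risks))
        per_repeat.append(np.mean(fold_cs))
    return CVResult(np.asarray(per_repeat), scheme)


def permutation_importance(
    model: RiskModel,
    features: FeatureMatrix | pd.DataFrame,
    outcomes: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importance: mean concordance drop per feature.

    Each feature column is permuted across samples ``n_perm`` times; the
    importance is the mean drop in Harrell's C relative to the unpermuted
    baseline. Returns a DataFrame (feature, delta_c) in descending order.
    Constant features have importance exactly 0.
    """
    X = (features.data if isinstance(features, FeatureMatrix) else features).copy()
    t, e = outcomes["time"].to_numpy(), outcomes["event"].to_numpy()
    baseline = harrell_c(t, e, model.predict_risk(X))
    rng = np.random.default_rng(seed)
    rows = []
    for col in X.columns:
        original = X[col].to_numpy().copy()
        if np.ptp(original) == 0:
            rows.append((col, 0.0))
            continue
        drops = np.empty(n_perm)
        for p in range(n_perm):
            X[col] = rng.permutation(original)
            drops[p] = baseline - harrell_c(t, e, model.predict_risk(X))
        X[col] = original
        rows.append((col, float(drops.mean())))
    out = pd.DataFrame(rows, columns=["feature", "delta_c"])
    return out.sort_values("delta_c", ascending=False, ignore_index=True)


def patient_risk(sample_risks: pd.Series, sample_to_patient: dict) -> pd.Series:
    """Average per-sample risks to one risk per patient."""
    unmapped = [s for s in sample_risks.index if s not in sample_to_patient]
    if unmapped:
        raise ValueError(f"sample {unmapped[0]!r} has no patient mapping")
    patients = sample_risks.index.map(sample_to_patient)
    return sample_risks.groupby(patients).mean().sort_index()


def kaplan_meier(times, events) -> pd.DataFrame:
    """Kaplan–Meier product-limit survival curve.

    Returns a step-function table with columns ``time`` and ``survival``,
    starting at S(0) = 1 and right-continuous.
    """
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter().fit(
        np.asarray(times, dtype=float), np.asarray(events, dtype=int)
    )
    sf = km.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    warning: str | None = None


def _logrank_statistic(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square statistic (hypergeometric sums)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for tk in event_times:
        at_risk = t >= tk
        nk = at_risk.sum()
        n1k = (at_risk & grp_a).sum()
        died = (t == tk) & (e == 1)
        dk = died.sum()
        d1k = (died & grp_a).sum()
        o_minus_e += d1k - dk * n1k / nk
        if nk > 1:
            var += dk * (n1k / nk) * (1 - n1k / nk) * (nk - dk) / (nk - 1)
    if var <= 0:
        return 0.0
    return float(o_minus_e**2 / var)


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test (chi-square with 1 df, asymptotic p-value).

    If a group has no observed events the statistic is still returned with a
    warning flag set.
    """
    from scipy.stats import chi2

    stat = _logrank_statistic(times_a, events_a, times_b, events_b)
    p = float(chi2.sf(stat, df=1))
    warning = None
    if np.sum(events_a) == 0 or np.sum(events_b) == 0:
        warning = "a group has no observed events; the test is degenerate"
    return LogrankResult(stat, p, warning)


@dataclass
class CohortSplit:
    """Low/high-risk patient partition at a log-rank-optimal risk threshold."""

    labels: pd.Series  # patient -> "low" | "high"
    threshold: float
    statistic: float
    p_value: float
    caveat: str = SELECTION_BIAS_CAVEAT


def stratify_patients(
    patient_risks: pd.Series,
    outcomes: pd.DataFrame,
    min_fraction: float = 0.10,
) -> CohortSplit:
    """Split patients into low-/high-risk cohorts at the risk cutpoint that
    maximizes the log-rank statistic between their survival curves.

    Candidate thresholds are midpoints between consecutive sorted unique
    patient risks, restricted so each cohort keeps at least
    ``max(2, ceil(min_fraction·n))`` patients. The reported p-value carries
    a mandatory selection-bias caveat: it is not adjusted for the search.
    """
    risks = patient_risks.sort_index()
    out = outcomes.loc[risks.index]
    n = len(risks)
    uniq = np.unique(risks.to_numpy())
    if len(uniq) < 2:
        raise ValueError("all patient risks equal: no valid cutpoint")
    min_n = max(2, int(np.ceil(min_fraction * n)))
    candidates = (uniq[:-1] + uniq[1:]) / 2
    best = None
    for thr in candidates:
        high = risks > thr
        if high.sum() < min_n or (~high).sum() < min_n:
            continue
        res = logrank_test(
            out.loc[~high, "time"], out.loc[~high, "event"],
            out.loc[high, "time"], out.loc[high, "event"],
        )
        if best is None or res.statistic > best[1].statistic:
            best = (thr, res)
    if best is None:
        raise ValueError("no cutpoint leaves both cohorts large enough")
    thr, res = best
    labels = pd.Series(
        np.where(risks > thr, "high", "low"), index=risks.index, name="cohort"
    )
    return CohortSplit(labels, float(thr), res.statistic, res.p_value)


def cohort_feature_tests(
    features: pd.DataFrame, labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided Mann–Whitney U test per feature between two cohorts.

    ``labels`` assigns each feature row to one of exactly two groups (e.g.
    low/high risk, or HPV status). Bonferroni correction multiplies each raw
    p by the number of features (capped at 1). Constant features record
    p = 1. Returns rows (feature, U, p_raw, p_bonferroni, significant)
    sorted by raw p.
    """
    from scipy.stats import mannwhitneyu

    labels = labels.loc[features.index]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 cohorts, got {len(groups)}")
    a_idx = labels == groups[0]
    rows = []
    m = features.shape[1]
    for col in features.columns:
        a = features.loc[a_idx, col].to_numpy()
        b = features.loc[~a_idx, col].to_numpy()
        if np.ptp(features[col].to_numpy()) == 0:
            rows.append((col, np.nan, 1.0))
            continue
        res = mannwhitneyu(a, b, alternative="two-sided")
        rows.append((col, float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["feature", "U", "p_raw"])
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * m)
    out["significant"] = out["p_bonferroni"] < alpha
    return out.sort_values("p_raw", ignore_index=True)
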