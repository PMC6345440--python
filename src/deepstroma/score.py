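"""The hazard-ratio-weighted deep stroma score and its survival analyses.

Construction, on a training cohort with pooled activation vectors and a
survival endpoint:

1. per tissue class c, a univariable Cox proportional-hazards fit of the
   continuous activation gives a hazard ratio HR_c per unit activation;
2. per class, an optimal cutoff tau_c is chosen by maximizing the Youden
   index (sensitivity + specificity - 1) of "activation > tau" against
   the endpoint's event indicator, ties broken toward the median;
3. classes with HR_c > 1 are selected, and a patient's score is
   S = sum over selected c of HR_c * 1[a_c > tau_c];
4. the training-cohort median m of S splits patients into high (S > m)
   and low risk; m is frozen and reused unchanged on validation cohorts.

The high/low label then enters multivariable Cox models adjusted for
UICC stage (continuous 1-4), sex and age in decades.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import ACTIVATION_COLUMNS
from .tissue import CLASS_CODES, N_CLASSES

logger = logging.getLogger(__name__)

#: Per-class univariable hazard ratios for shorter overall survival and
#: Youden-optimal activation cutoffs published for the original
#: 500-patient training cohort, in the fixed class order
#: (ADI, BACK, DEB, LYM, MUC, MUS, NORM, STR, TUM), together with the
#: training-cohort median score used for the high/low split.
PUBLISHED_HRS = (1.150, 0.015, 5.967, 1.226, 0.488, 3.761, 0.909, 1.154, 0.475)
PUBLISHED_CUTOFFS = (0.00056, 0.00227, 0.03151, 0.00121, 0.01123, 0.02359,
                     0.06405, 0.00122, 0.99961)
PUBLISHED_MEDIAN = 8.347


class ScoreModelError(ValueError):
    pass


@dataclass
class ScoreModel:
    """Frozen definition of a deep stroma score.

    Holds the per-class hazard ratios and cutoffs, the HR > 1 class
    selection, and the training-cohort median used to dichotomize.
    """

    hr: tuple[float, ...]
    cutoff: tuple[float, ...]
    median: float
    class_order: tuple[str, ...] = CLASS_CODES

    def __post_init__(self):
        self.hr = tuple(float(v) for v in self.hr)
        self.cutoff = tuple(float(v) for v in self.cutoff)
        if tuple(self.class_order) != CLASS_CODES:
            raise ScoreModelError("class order must match the package order")
        if len(self.hr) != N_CLASSES or len(self.cutoff) != N_CLASSES:
            raise ScoreModelError("need one HR and one cutoff per class")
        if not self.selected:
            raise ScoreModelError("no class with HR > 1")

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(c for c, h in zip(CLASS_CODES, self.hr) if h > 1.0)

    @property
    def selected_mask(self) -> np.ndarray:
        return np.array([h > 1.0 for h in self.hr])

    # -- scoring -----------------------------------------------------------

    def score(self, activations) -> np.ndarray:
        """S = sum over HR>1 classes of HR_c * 1[a_c > tau_c].

        Accepts one activation vector (length 9) or a matrix (n, 9);
        returns a scalar-shaped array or a length-n array.
        """
        a = np.atleast_2d(np.asarray(activations, dtype=float))
        if a.shape[1] != N_CLASSES:
            raise ValueError("activation vectors must have 9 components")
        above = a > np.asarray(self.cutoff)
        weights = np.asarray(self.hr) * self.selected_mask
        s = above @ weights
        return s if np.asarray(activations).ndim == 2 else float(s[0])

    def dichotomize(self, scores) -> np.ndarray:
        """High-risk label: 1 iff score > frozen training median."""
        return (np.asarray(scores, dtype=float) > self.median).astype(int)

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "class_order": list(self.class_order),
            "hr": list(self.hr),
            "cutoff": list(self.cutoff),
            "selected": list(self.selected),
            "median": self.median,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScoreModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(hr=tuple(d["hr"]), cutoff=tuple(d["cutoff"]),
                   median=d["median"], class_order=tuple(d["class_order"]))


def published_score_model() -> ScoreModel:
    """The published-2019 preset: printed HRs, cutoffs and median."""
    return ScoreModel(hr=PUBLISHED_HRS, cutoff=PUBLISHED_CUTOFFS,
                      median=PUBLISHED_MEDIAN)


# ---------------------------------------------------------------------------
# cutpoint selection


def youden_cutoff(values, binary_labels) -> float:
    """Youden-optimal cutoff for "value > tau" predicting the label.

    Candidate cutoffs are midpoints between consecutive sorted unique
    values.  Among maximizers of J = sensitivity + specificity - 1,
    the candidate closest to the median of ``values`` wins; residual
    ties go to the smaller cutoff.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D")
    if np.unique(y).size < 2:
        raise ValueError("both label classes must be present")
    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValueError("need >= 2 distinct values")

    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    pos = y == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    # J(tau) via vectorized comparison: predictions positive iff v > tau
    above = v[None, :] > candidates[:, None]
    sens = (above & pos[None, :]).sum(axis=1) / n_pos
    spec = (~above & ~pos[None, :]).sum(axis=1) / n_neg
    J = sens + spec - 1.0

    best = np.flatnonzero(np.isclose(J, J.max(), rtol=0, atol=1e-12))
    med = np.median(v)
    dist = np.abs(candidates[best] - med)
    close = best[np.isclose(dist, dist.min(), rtol=0, atol=1e-12)]
    return float(candidates[close].min())


# ---------------------------------------------------------------------------
# proportional-hazards fits (lifelines, Efron ties)


def _check_survival(times, events, min_events: int = 1):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    if e.sum() < min_events:
        raise ValueError(f"needs >= {min_events} events, got {int(e.sum())}")
    return t, e


def univariable_hr(activations, times, events) -> float:
    """Hazard ratio per unit activation from a single-covariate Cox fit."""
    x = np.asarray(activations, dtype=float)
    t, e = _check_survival(times, events, min_events=1)
    if np.ptp(x) == 0:
        raise ValueError("non-identifiable: constant covariate")
    df = pd.DataFrame({"x": x, "time": t, "event": e})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(np.exp(cph.params_["x"]))


@dataclass
class CoxResult:
    """One covariate's estimate from a proportional-hazards fit."""

    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int

    def __post_init__(self):
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("CI must bracket the HR")


def multivariable_cox(cohort: pd.DataFrame, group, endpoint: str = "OS"
                      ) -> dict[str, CoxResult]:
    """Cox fit of {group, stage, sex, age/decade} on an endpoint.

    ``group`` is the binary high/low label (array-like aligned to the
    cohort rows).  Returns one `CoxResult` per covariate.
    """
    t, e = _check_survival(cohort[f"time_{endpoint}"], cohort[f"event_{endpoint}"],
                           min_events=10)
    df = pd.DataFrame({
        "group": np.asarray(group, dtype=float),
        "stage": cohort["stage"].astype(float).to_numpy(),
        "sex": cohort["sex"].astype(float).to_numpy(),
        "age_decades": cohort["age"].astype(float).to_numpy() / 10.0,
        "time": t,
        "event": e,
    })
    for col in ("group", "stage", "sex", "age_decades"):
        if df[col].nunique() < 2:
            raise ValueError(f"non-identifiable: constant covariate {col!r}")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence / separation
        raise RuntimeError(f"Cox fit failed for endpoint {endpoint}: {exc}") from exc
    summary = cph.summary
    out = {}
    for cov in ("group", "stage", "sex", "age_decades"):
        row = summary.loc[cov]
        out[cov] = CoxResult(
            covariate=cov,
            hr=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
            n=len(df),
            n_events=int(df["event"].sum()),
        )
    return out


def per_stage_models(cohort: pd.DataFrame, group, endpoint: str = "OS",
                     min_events: int = 10) -> dict[int, dict[str, CoxResult] | str]:
    """Multivariable fit within each UICC stage stratum.

    The stage covariate is dropped inside a stratum.  Stages with fewer
    than ``min_events`` events are reported as "insufficient events".
    """
    group = np.asarray(group)
    out: dict[int, dict[str, CoxResult] | str] = {}
    for stage in (1, 2, 3, 4):
        m = (cohort["stage"].to_numpy() == stage)
        sub = cohort.loc[m]
        if m.sum() == 0 or int(sub[f"event_{endpoint}"].sum()) < min_events:
            out[stage] = "insufficient events"
            continue
        df = pd.DataFrame({
            "group": group[m].astype(float),
            "sex": sub["sex"].astype(float).to_numpy(),
            "age_decades": sub["age"].astype(float).to_numpy() / 10.0,
            "time": sub[f"time_{endpoint}"].astype(float).to_numpy(),
            "event": sub[f"event_{endpoint}"].astype(int).to_numpy(),
        })
        if any(df[c].nunique() < 2 for c in ("group", "sex", "age_decades")):
            out[stage] = "insufficient events"
            continue
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
        except Exception:
            out[stage] = "insufficient events"
            continue
        res = {}
        for cov in ("group", "sex", "age_decades"):
            row = cph.summary.loc[cov]
            res[cov] = CoxResult(
                covariate=cov, hr=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p=float(row["p"]), n=len(df), n_events=int(df["event"].sum()),
            )
        out[stage] = res
    return out


# ---------------------------------------------------------------------------
# score construction


def build_score_model(cohort: pd.DataFrame, endpoint: str = "OS") -> ScoreModel:
    """Fit a deep stroma score on a training cohort.

    The cohort frame needs pooled activation columns a_ADI..a_TUM plus
    time_<endpoint>/event_<endpoint>.  Rows with missing endpoint data
    are excluded (never imputed).
    """
    needed = [f"time_{endpoint}", f"event_{endpoint}"]
    for col in needed:
        if col not in cohort:
            raise ValueError(f"cohort lacks column {col!r}")
    sub = cohort.dropna(subset=needed)
    n_dropped = len(cohort) - len(sub)
    if n_dropped:
        logger.info("excluded %d subjects with missing %s data", n_dropped, endpoint)
    times = sub[f"time_{endpoint}"].to_numpy(float)
    events = sub[f"event_{endpoint}"].to_numpy(int)

    hrs, cutoffs = [], []
    for col in ACTIVATION_COLUMNS:
        a = sub[col].to_numpy(float)
        hrs.append(univariable_hr(a, times, events))
        cutoffs.append(youden_cutoff(a, events))
    if not any(h > 1.0 for h in hrs):
        raise ScoreModelError("no class with HR > 1")

    proto = ScoreModel(hr=tuple(hrs), cutoff=tuple(cutoffs), median=0.0)
    scores = proto.score(sub[list(ACTIVATION_COLUMNS)].to_numpy(float))
    return ScoreModel(hr=tuple(hrs), cutoff=tuple(cutoffs),
                      median=float(np.median(scores)))


def compute_score(sm: ScoreModel, activations) -> np.ndarray | float:
    """Deep stroma score(s) for activation vector(s) under a frozen model."""
    return sm.score(activations)


def dichotomize(sm: ScoreModel, scores) -> np.ndarray:
    """High/low labels at the frozen training-cohort median."""
    return sm.dichotomize(scores)


class DeepStromaScorer(BaseEstimator, TransformerMixin):
    """Scikit-learn style estimator for the deep stroma score.

    ``fit(cohort)`` builds the score model on a cohort frame (pooled
    activations + endpoint columns); ``transform`` returns scores for a
    cohort or an activation matrix; ``predict`` returns frozen-median
    high/low labels.

    Attributes (after ``fit``)
    --------------------------
    model_ : the frozen `ScoreModel`
    hr_, cutoff_, selected_, median_ : its components
    """

    def __init__(self, endpoint: str = "OS"):
        self.endpoint = endpoint

    def fit(self, X: pd.DataFrame, y=None):
        self.model_ = build_score_model(X, endpoint=self.endpoint)
        self.hr_ = np.asarray(self.model_.hr)
        self.cutoff_ = np.asarray(self.model_.cutoff)
        self.selected_ = self.model_.selected
        self.median_ = self.model_.median
        return self

    def _activations(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[list(ACTIVATION_COLUMNS)].to_numpy(float)
        return np.atleast_2d(np.asarray(X, dtype=float))

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.score(self._activations(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.dichotomize(self.transform(X))


# ---------------------------------------------------------------------------
# comparator scores


def caf_score(expression: pd.DataFrame, gene_list) -> pd.Series:
    """Cancer-associated-fibroblast score: per-patient mean expression.

    ``expression`` is genes x patients; the score is the mean over the
    intersection of ``gene_list`` with the matrix rows.  Missing genes
    are logged; an empty intersection is an error.
    """
    genes = [g for g in gene_list if g in expression.index]
    missing = sorted(set(gene_list) - set(genes))
    if not list(gene_list):
        raise ValueError("gene list is empty")
    if not genes:
        raise ValueError("no signature gene present in the expression matrix")
    if missing:
        logger.warning("CAF signature genes missing from matrix: %s", missing)
    return expression.loc[genes].mean(axis=0)


def compare_scores(cohort: pd.DataFrame, sm: ScoreModel, endpoint: str = "OS"
                   ) -> dict:
    """Benchmark the deep stroma score against comparator scores.

    The deep stroma score is binarized at the frozen median; CAF score
    and pathologist stromal percentage (when present) are binarized at
    their own Youden-optimal cutoff against the endpoint's event
    indicator.  Each binary score enters the multivariable Cox model,
    and Pearson correlations between scores/activations are reported.
    Missing comparator columns skip that comparison with a log record.
    """
    from scipy.stats import pearsonr

    events = cohort[f"event_{endpoint}"].to_numpy(int)
    acts = cohort[list(ACTIVATION_COLUMNS)].to_numpy(float)
    deep = sm.score(acts)
    report: dict = {"endpoint": endpoint, "models": {}, "correlations": {}}

    report["models"]["deep_stroma"] = multivariable_cox(
        cohort, sm.dichotomize(deep), endpoint
    )

    comparators = {"caf": "caf_score", "pathologist": "path_stroma_pct"}
    values = {"deep_stroma": deep, "str_activation": acts[:, CLASS_CODES.index("STR")],
              "tum_activation": acts[:, CLASS_CODES.index("TUM")]}
    for name, col in comparators.items():
        if col not in cohort or cohort[col].isna().all():
            logger.info("comparator %s absent; skipping", name)
            continue
        v = cohort[col].to_numpy(float)
        tau = youden_cutoff(v, events)
        report["models"][name] = multivariable_cox(cohort, (v > tau).astype(int),
                                                   endpoint)
        values[name] = v

    pairs = [
        ("deep_stroma", "caf"),
        ("deep_stroma", "pathologist"),
        ("str_activation", "caf"),
        ("pathologist", "caf"),
    ]
    if "tumor_purity" in cohort and not cohort["tumor_purity"].isna().all():
        values["tumor_purity"] = cohort["tumor_purity"].to_numpy(float)
        pairs.append(("tum_activation", "tumor_purity"))
    for a, b in pairs:
        if a in values and b in values:
            r, p = pearsonr(values[a], values[b])
            report["correlations"][f"{a}_vs_{b}"] = {"r": float(r), "p": float(p)}
    return report
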