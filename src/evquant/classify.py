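"""Control-based cutoffs, SCLC subtype calls, diagnostic classifiers, statistics.

Cutoff derivation from the high-risk-smoker (HRS) control group:

* ``whisker_max`` — highest control TFI after excluding Tukey box-plot
  outliers (fences at Q1 − 1.5·IQR and Q3 + 1.5·IQR, type-7 quartiles);
  used for the three subtype transcription factors.
* ``spec100`` — maximum control TFI, the smallest threshold with zero
  control positives under the strict ``value > cutoff`` rule (100%
  specificity by construction); used for the two DLL3 markers.

Subtype call: per transcription factor m, the ratio r_m = TFI_m / cutoff_m;
a sample is positive for subtype A/N/P when the matching ratio exceeds 1,
its primary label is the largest-ratio positive subtype (ties broken in the
fixed order A > N > P), and samples positive for none are SCLC-I.

Diagnostic calls: the dual DLL3 rule labels each sample H or L per marker
(H ⇔ TFI strictly above the cutoff) and calls it positive unless L/L.
Combined scores over any marker set are either the threshold-free
``max_log_ratio`` (max over markers of log2(TFI/cutoff)) or a
maximum-likelihood logistic model on log10 TFIs.

Statistics: empirical ROC/AUC via the tie-corrected rank (Mann–Whitney)
statistic, the Mann–Whitney U test with exact small-sample enumeration, and
2×2 confusion metrics.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TukeyFences",
    "CutoffSet",
    "SubtypeCall",
    "DualCall",
    "ROCResult",
    "MannWhitneyResult",
    "ClassifyConfig",
    "CohortReport",
    "tukey_fences",
    "derive_cutoff_whisker",
    "derive_cutoff_spec100",
    "assign_subtype",
    "dual_marker_call",
    "combined_score",
    "roc_auc",
    "mann_whitney",
    "confusion_metrics",
    "classify_cohort",
    "TF_SUBTYPE_MARKERS",
    "DLL3_MARKERS",
]

#: Subtype → defining transcription-factor marker column.
TF_SUBTYPE_MARKERS: dict[str, str] = {
    "A": "ASCL1",
    "N": "NEUROD1",
    "P": "POU2F3",
}

#: (Exo-mRNA, tEV-mProtein) marker columns for the dual DLL3 rule.
DLL3_MARKERS: tuple[str, str] = ("DLL3_exo_mRNA", "DLL3_tEV_mProtein")

_SUBTYPE_ORDER = ("A", "N", "P")


# ---------------------------------------------------------------------------
# Cutoffs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TukeyFences:
    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float
    inliers: tuple[float, ...]


def tukey_fences(values: Sequence[float], method: str = "linear") -> TukeyFences:
    """Quartiles, 1.5·IQR fences, and the non-outlier subset.

    Quartiles use linear interpolation (NumPy ``method='linear'``, the
    type-7 convention) by default; other NumPy quantile conventions are
    selectable.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for Tukey fences")
    q1, q3 = (float(q) for q in np.percentile(v, [25, 75], method=method))
    iqr = q3 - q1
    lower = q1 - 1.5 * iqr
    upper = q3 + 1.5 * iqr
    inliers = tuple(float(x) for x in v[(v >= lower) & (v <= upper)])
    return TukeyFences(q1, q3, iqr, lower, upper, inliers)


def derive_cutoff_whisker(controls: Sequence[float], method: str = "linear") -> float:
    """Highest control value after excluding Tukey box-plot outliers."""
    fences = tukey_fences(controls, method=method)
    return max(fences.inliers)


def derive_cutoff_spec100(controls: Sequence[float]) -> float:
    """Maximum control value: with the strict ``value > cutoff`` positivity
    rule this is the smallest threshold with zero control positives
    (specificity exactly 100% on the deriving controls)."""
    v = np.asarray(controls, dtype=float)
    if v.size == 0:
        raise ValueError("controls must be non-empty")
    return float(v.max())


@dataclass(frozen=True)
class CutoffSet:
    """Per-marker decision thresholds with derivation metadata."""

    cutoffs: Mapping[str, float]
    method: Mapping[str, str]
    control_group: str = "HRS"
    meta: Mapping[str, dict] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, c in self.cutoffs.items():
            if c <= 0:
                raise ValueError(f"cutoff for {m} must be positive, got {c}")
            if m not in self.method:
                raise ValueError(f"no derivation method recorded for {m}")

    def __getitem__(self, marker: str) -> float:
        return float(self.cutoffs[marker])

    def __contains__(self, marker: str) -> bool:
        return marker in self.cutoffs


def derive_cutoffs(
    cohort: pd.DataFrame,
    whisker_markers: Sequence[str],
    spec100_markers: Sequence[str],
    control_group: str = "HRS",
    quartile_method: str = "linear",
) -> CutoffSet:
    """Derive the full cutoff set from the control group of a cohort table."""
    controls = cohort[cohort["group"] == control_group]
    if controls.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    cutoffs: dict[str, float] = {}
    methods: dict[str, str] = {}
    meta: dict[str, dict] = {}
    for m in whisker_markers:
        if m not in cohort.columns:
            raise ValueError(f"missing marker column {m!r}")
        fences = tukey_fences(controls[m].to_numpy(), method=quartile_method)
        cutoffs[m] = max(fences.inliers)
        methods[m] = "whisker_max"
        meta[m] = {
            "q1": fences.q1,
            "q3": fences.q3,
            "lower_fence": fences.lower,
            "upper_fence": fences.upper,
            "n_controls": int(len(controls)),
        }
    for m in spec100_markers:
        if m not in cohort.columns:
            raise ValueError(f"missing marker column {m!r}")
        cutoffs[m] = derive_cutoff_spec100(controls[m].to_numpy())
        methods[m] = "spec100"
        meta[m] = {"control_max": cutoffs[m], "n_controls": int(len(controls))}
    return CutoffSet(cutoffs=cutoffs, method=methods, control_group=control_group, meta=meta)


# ---------------------------------------------------------------------------
# Per-sample calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    ratios: Mapping[str, float]  # subtype letter -> TFI / cutoff
    positive: frozenset[str]
    primary: str  # A, N, P or I

    def __post_init__(self) -> None:
        for s, r in self.ratios.items():
            if (r > 1) != (s in self.positive):
                raise ValueError("positive set inconsistent with ratios")
        if (self.primary == "I") != (len(self.positive) == 0):
            raise ValueError("primary I iff positive set empty")


def assign_subtype(
    row: Mapping[str, float],
    cutoffs: CutoffSet,
    tf_markers: Mapping[str, str] = TF_SUBTYPE_MARKERS,
) -> SubtypeCall:
    """Call the molecular subtype of one sample from its TFI/cutoff ratios.

    Positive for each of A/N/P when the matching ratio strictly exceeds 1;
    primary label is the largest-ratio positive subtype, ties broken by the
    fixed order A > N > P; SCLC-I when no ratio exceeds 1.
    """
    ratios: dict[str, float] = {}
    for subtype, marker in tf_markers.items():
        if marker not in row:
            raise ValueError(f"missing marker column {marker!r}")
        if marker not in cutoffs:
            raise ValueError(f"no cutoff for marker {marker!r}")
        ratios[subtype] = float(row[marker]) / cutoffs[marker]
    positive = frozenset(s for s, r in ratios.items() if r > 1)
    if positive:
        primary = max(
            positive, key=lambda s: (ratios[s], -_SUBTYPE_ORDER.index(s))
        )
    else:
        primary = "I"
    return SubtypeCall(
        sample_id=str(row.get("sample_id", "")),
        ratios=ratios,
        positive=positive,
        primary=primary,
    )


@dataclass(frozen=True)
class DualCall:
    sample_id: str
    category: str  # HH, HL, LH or LL (Exo-mRNA letter first)
    positive: bool

    def __post_init__(self) -> None:
        if self.category not in ("HH", "HL", "LH", "LL"):
            raise ValueError(f"invalid category {self.category!r}")
        if self.positive != (self.category != "LL"):
            raise ValueError("positive flag must equal category != LL")


def dual_marker_call(
    row: Mapping[str, float],
    cutoffs: CutoffSet,
    markers: tuple[str, str] = DLL3_MARKERS,
) -> DualCall:
    """Dual DLL3 Exo-mRNA / tEV-mProtein call.

    Each marker is H when its TFI strictly exceeds its cutoff; the category
    concatenates the two letters (mRNA first) and the sample is positive
    unless both are low (L/L).
    """
    letters = []
    for m in markers:
        if m not in row:
            raise ValueError(f"missing marker column {m!r}")
        if m not in cutoffs:
            raise ValueError(f"no cutoff for marker {m!r}")
        letters.append("H" if float(row[m]) > cutoffs[m] else "L")
    category = "".join(letters)
    return DualCall(
        sample_id=str(row.get("sample_id", "")),
        category=category,
        positive=category != "LL",
    )


# ---------------------------------------------------------------------------
# Combined classifiers
# ---------------------------------------------------------------------------


def _max_log_ratio(cohort: pd.DataFrame, markers: Sequence[str], cutoffs: CutoffSet) -> pd.Series:
    mat = np.column_stack(
        [np.log2(cohort[m].to_numpy(dtype=float) / cutoffs[m]) for m in markers]
    )
    return pd.Series(mat.max(axis=1), index=cohort.index, name="score")


def combined_score(
    cohort: pd.DataFrame,
    markers: Sequence[str],
    cutoffs: CutoffSet,
    method: str = "max_log_ratio",
    control_group: str = "HRS",
) -> pd.Series:
    """Per-sample combined score over a marker set.

    ``max_log_ratio``: max over markers of log2(TFI/cutoff) — positive as
    soon as any marker exceeds its cutoff, mirroring the any-marker-high
    logic of the dual rule.  ``logistic``: maximum-likelihood logistic
    regression of case/control status on log10 TFIs, score = linear
    predictor; on separation (infinite MLE) it falls back to
    ``max_log_ratio`` with a logged warning.
    """
    for m in markers:
        if m not in cohort.columns:
            raise ValueError(f"missing marker column {m!r}")
    if method == "max_log_ratio":
        return _max_log_ratio(cohort, markers, cutoffs)
    if method != "logistic":
        raise ValueError(f"unknown combination method {method!r}")
    y = (cohort["group"] != control_group).to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("logistic combination needs both classes present")
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    X = sm.add_constant(np.log10(cohort[list(markers)].to_numpy(dtype=float)))
    try:
        with warnings.catch_warnings(record=True) as caught, np.errstate(all="ignore"):
            warnings.simplefilter("always")
            fit = sm.Logit(y, X).fit(disp=0)
        if any(
            issubclass(w.category, (PerfectSeparationWarning, ConvergenceWarning))
            for w in caught
        ):
            raise PerfectSeparationError("separation or non-convergence in logistic fit")
        params = np.asarray(fit.params)
        if not np.all(np.isfinite(params)):
            raise PerfectSeparationError("non-finite coefficients")
        return pd.Series(X @ params, index=cohort.index, name="score")
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        logger.warning("logistic fit failed (%s); falling back to max_log_ratio", exc)
        return _max_log_ratio(cohort, markers, cutoffs)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve and tie-corrected AUC."""

    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: int
    n_controls: int


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Empirical ROC over all distinct thresholds plus the rank-based AUC.

    The AUC is the tie-corrected rank statistic U/(n_cases·n_controls) — the
    probability a random case outscores a random control, counting ties as
    1/2 — which equals the trapezoidal area under the empirical curve.
    Positivity at a threshold t is ``score >= t``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = float(np.sum(ranks[y == 1]) - n1 * (n1 + 1) / 2)
    auc = u / (n1 * n0)
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tps = np.cumsum(y_sorted == 1)[distinct]
    fps = np.cumsum(y_sorted == 0)[distinct]
    return ROCResult(
        thresholds=s_sorted[distinct],
        sensitivity=tps / n1,
        specificity=1.0 - fps / n0,
        auc=float(auc),
        n_cases=n1,
        n_controls=n0,
    )


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    auc: float  # U / (n_x * n_y)
    mode: str  # exact or normal


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # U = number of (x, y) pairs with x > y, ties counted 1/2.
    return float(np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :]))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    Exact p by full enumeration of the C(n_x+n_y, n_x) label assignments
    when the total sample size is at most 12 (ties handled exactly);
    otherwise a tie-corrected normal approximation without continuity
    correction.  The two-sided p is the permutation probability of a U at
    least as far from its null mean n_x·n_y/2 as observed.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    nx, ny = xa.size, ya.size
    n = nx + ny
    u_obs = _u_statistic(xa, ya)
    mu = nx * ny / 2.0
    if mode == "exact" or (mode == "auto" and n <= 12):
        pooled = np.concatenate([xa, ya])
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        idx = np.arange(n)
        for comb in itertools.combinations(idx, nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return MannWhitneyResult(u_obs, hits / total, u_obs / (nx * ny), "exact")
    # tie-corrected normal approximation
    pooled = np.concatenate([xa, ya])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values tied
        return MannWhitneyResult(u_obs, 1.0, u_obs / (nx * ny), "normal")
    z = (u_obs - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return MannWhitneyResult(u_obs, min(p, 1.0), u_obs / (nx * ny), "normal")


def confusion_metrics(
    calls: Sequence[int], labels: Sequence[int]
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) of binary calls vs truth."""
    c = np.asarray(calls).astype(bool)
    y = np.asarray(labels).astype(bool)
    if c.shape != y.shape:
        raise ValueError("calls and labels must have equal length")
    if y.all() or (~y).all():
        raise ValueError("both labels must be present")
    tp = int(np.sum(c & y))
    tn = int(np.sum(~c & ~y))
    fn = int(np.sum(~c & y))
    fp = int(np.sum(c & ~y))
    return (tp / (tp + fn), tn / (tn + fp), (tp + tn) / len(y))


# ---------------------------------------------------------------------------
# Whole-cohort report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifyConfig:
    """Marker sets and rules for the whole-cohort analysis."""

    control_group: str = "HRS"
    case_groups: tuple[str, ...] = ("LS", "ES")
    tf_markers: Mapping[str, str] = dc_field(default_factory=lambda: dict(TF_SUBTYPE_MARKERS))
    dll3_markers: tuple[str, str] = DLL3_MARKERS
    combined_markers: tuple[str, ...] = ("ASCL1", "POU2F3") + DLL3_MARKERS
    combined_method: str = "max_log_ratio"
    quartile_method: str = "linear"


@dataclass(frozen=True)
class CohortReport:
    """Everything the cohort analysis computes, deterministically."""

    cutoffs: CutoffSet
    subtype_calls: pd.DataFrame  # per SCLC sample: ratios, positive set, primary
    subtype_prevalence: pd.DataFrame  # primary-label frequencies among SCLC
    dual_calls: pd.DataFrame  # per sample: category, positive
    combined_scores: pd.Series
    ratio_matrix: pd.DataFrame  # SCLC samples × TF markers, TFI / cutoff
    roc: Mapping[str, ROCResult]  # "<set>|<case group>" -> ROC vs controls
    metrics: Mapping[str, tuple[float, float, float]]  # dual-rule sens/spec/acc


def _validate_cohort(cohort: pd.DataFrame, cfg: ClassifyConfig) -> None:
    if "group" not in cohort.columns:
        raise ValueError("cohort table needs a 'group' column")
    if cohort["group"].isna().any():
        raise ValueError("missing group labels")
    groups = set(cohort["group"])
    if cfg.control_group not in groups:
        raise ValueError(f"cohort has no {cfg.control_group!r} controls")
    if not any(g in groups for g in cfg.case_groups):
        raise ValueError(f"cohort has none of the case groups {cfg.case_groups}")
    needed = set(cfg.tf_markers.values()) | set(cfg.dll3_markers) | set(cfg.combined_markers)
    missing = sorted(m for m in needed if m not in cohort.columns)
    if missing:
        raise ValueError(f"missing marker column(s): {missing}")
    vals = cohort[sorted(needed)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals < 0):
        raise ValueError("TFI values must be finite and >= 0")


def classify_cohort(cohort: pd.DataFrame, cfg: ClassifyConfig = ClassifyConfig()) -> CohortReport:
    """Run the full cohort analysis.

    Whisker cutoffs from controls for the transcription factors, spec100
    cutoffs for the DLL3 pair, per-sample subtype and dual calls, combined
    scores, ROC/AUC of each single marker, the dual score and the combined
    set against controls (per case group and pooled), and dual-rule
    confusion metrics.  Fully deterministic given the table.
    """
    _validate_cohort(cohort, cfg)
    cohort = cohort.reset_index(drop=True)
    cutoffs = derive_cutoffs(
        cohort,
        whisker_markers=list(cfg.tf_markers.values()),
        spec100_markers=list(cfg.dll3_markers),
        control_group=cfg.control_group,
        quartile_method=cfg.quartile_method,
    )

    is_case = cohort["group"].isin(cfg.case_groups)
    sclc = cohort[is_case]

    sub_rows = []
    for _, row in sclc.iterrows():
        call = assign_subtype(row, cutoffs, cfg.tf_markers)
        sub_rows.append(
            {
                "sample_id": call.sample_id,
                "group": row["group"],
                **{f"ratio_{s}": call.ratios[s] for s in cfg.tf_markers},
                "positive": "".join(sorted(call.positive)),
                "primary": call.primary,
            }
        )
    subtype_calls = pd.DataFrame(sub_rows)
    if not subtype_calls.empty:
        freq = subtype_calls["primary"].value_counts(normalize=True)
        prevalence = pd.DataFrame(
            {
                "subtype": ["A", "N", "P", "I"],
                "fraction": [float(freq.get(s, 0.0)) for s in ("A", "N", "P", "I")],
            }
        )
    else:
        prevalence = pd.DataFrame({"subtype": ["A", "N", "P", "I"], "fraction": [0.0] * 4})

    dual_rows = []
    for _, row in cohort.iterrows():
        call = dual_marker_call(row, cutoffs, cfg.dll3_markers)
        dual_rows.append(
            {
                "sample_id": call.sample_id,
                "group": row["group"],
                "category": call.category,
                "positive": call.positive,
            }
        )
    dual_calls = pd.DataFrame(dual_rows)

    combined = combined_score(
        cohort,
        list(cfg.combined_markers),
        cutoffs,
        method=cfg.combined_method,
        control_group=cfg.control_group,
    )
    dual_score = combined_score(
        cohort, list(cfg.dll3_markers), cutoffs, method="max_log_ratio"
    )

    ratio_matrix = pd.DataFrame(
        {
            "sample_id": sclc["sample_id"].to_numpy(),
            **{
                m: (sclc[m] / cutoffs[m]).to_numpy()
                for m in cfg.tf_markers.values()
            },
        }
    )

    score_sets: dict[str, pd.Series] = {
        **{m: pd.Series(cohort[m].to_numpy(dtype=float), index=cohort.index) for m in
           sorted(set(cfg.tf_markers.values()) | set(cfg.dll3_markers))},
        "dual_DLL3": dual_score,
        "combined": combined,
    }
    roc: dict[str, ROCResult] = {}
    is_control = cohort["group"] == cfg.control_group
    case_subsets = {g: cohort["group"] == g for g in cfg.case_groups if (cohort["group"] == g).any()}
    case_subsets["all_SCLC"] = is_case
    for set_name, scores in score_sets.items():
        for case_name, case_mask in case_subsets.items():
            mask = is_control | case_mask
            labels = case_mask[mask].astype(int).to_numpy()
            roc[f"{set_name}|{case_name}"] = roc_auc(scores[mask].to_numpy(), labels)

    metrics: dict[str, tuple[float, float, float]] = {}
    dual_positive = dual_calls["positive"].to_numpy()
    for case_name, case_mask in case_subsets.items():
        mask = (is_control | case_mask).to_numpy()
        metrics[f"dual_DLL3|{case_name}"] = confusion_metrics(
            dual_positive[mask], case_mask.to_numpy()[mask].astype(int)
        )

    return CohortReport(
        cutoffs=cutoffs,
        subtype_calls=subtype_calls,
        subtype_prevalence=prevalence,
        dual_calls=dual_calls,
        combined_scores=combined,
        ratio_matrix=ratio_matrix,
        roc=roc,
        metrics=metrics,
    )
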