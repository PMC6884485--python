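"""Outcome statistics: cutpoint search, log-rank, Kaplan–Meier, Cox,
Mann–Whitney association and ICC/Wilcoxon agreement.

The centrepiece is the outcome-based dichotomization of a continuous score
(X-tile style): the two-group log-rank χ² is evaluated at every admissible
division of the cohort (midpoints between consecutive distinct scores whose
groups both hold at least ``min_group_fraction`` of the cases) and the
maximizing threshold is reported.  Because the maximal χ² is optimistically
biased, significance is assessed by Monte-Carlo cross-validation: on each
of ``n_splits`` random splits the cutpoint is derived on the training half
and the log-rank p is computed on the held-out half; the median held-out p
is the cross-validated significance.

The log-rank statistic is computed in-house with the standard
hypergeometric variance, vectorized over all candidate thresholds at once
(an O(n²) cumulative-sum table), which makes the full scan and its
cross-validation loops cheap.  Kaplan–Meier curves and Cox proportional
hazards fits delegate to lifelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SurvivalRecord",
    "CutpointResult",
    "logrank_chi2",
    "km_curve",
    "find_cutpoint",
    "crossvalidate_cutpoint",
    "cox_multivariable",
    "association_test",
    "agreement",
    "records_to_frame",
    "read_survival_csv",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05  # study-wide significance level


@dataclass
class SurvivalRecord:
    """One case: score, disease-specific follow-up and covariates.

    ``event`` is True when the disease-specific death was observed; cases
    dead of other causes or still alive are censored (event=False).
    """

    id: str
    score: float
    time_months: float
    event: bool
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError("time_months must be >= 0")


@dataclass
class CutpointResult:
    """Optimal outcome-based threshold and its χ² profile."""

    threshold: float
    chi2_max: float
    p_uncorrected: float
    candidate_profile: list[tuple[float, float]]
    min_group_fraction: float
    p_crossvalidated: float | None = None


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"id": r.id, "score": r.score, "time_months": r.time_months, "event": int(r.event)}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def read_survival_csv(path) -> list[SurvivalRecord]:
    """Read a survival table (columns: id, score, time_months, event, then
    covariates)."""
    df = pd.read_csv(path)
    required = {"id", "score", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival CSV is missing columns: {sorted(missing)}")
    cov_cols = [c for c in df.columns if c not in required]
    return [
        SurvivalRecord(
            id=str(row["id"]),
            score=float(row["score"]),
            time_months=float(row["time_months"]),
            event=bool(int(row["event"])),
            covariates={c: row[c] for c in cov_cols},
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# log-rank

def _logrank_terms(times, events, member):
    """(O, E, V) of the two-group log-rank for membership columns.

    ``member`` is (n, k) booleans: column k defines group 1 for candidate k.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    m = member[order]

    event_times = np.unique(t[e])
    j = len(event_times)
    # at-risk and event indicator tables per distinct event time
    at_risk = t[None, :] >= event_times[:, None]          # (j, n)
    dying = e[None, :] & (t[None, :] == event_times[:, None])
    n_j = at_risk.sum(axis=1).astype(float)
    d_j = dying.sum(axis=1).astype(float)
    n1 = at_risk.astype(float) @ m                        # (j, k)
    d1 = dying.astype(float) @ m
    frac = n1 / n_j[:, None]
    obs = d1.sum(axis=0)
    exp = (d_j[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d_j[:, None] * frac * (1.0 - frac) * ((n_j - d_j) / np.maximum(n_j - 1.0, 1.0))[:, None]
    var = var_terms.sum(axis=0)
    return obs, exp, var


def logrank_chi2(times, events, group_labels) -> tuple[float, float]:
    """Two-group log-rank test: (χ², p) with 1 degree of freedom.

    Uses the standard risk-set table with hypergeometric variance.  Raises
    when either group is empty or no event occurred.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(group_labels)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"exactly two non-empty groups required, found {len(uniq)}")
    if events.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    member = (groups == uniq[1]).reshape(-1, 1)
    obs, exp, var = _logrank_terms(times, events, member)
    if var[0] <= 0:
        return 0.0, 1.0
    chi2 = float((obs[0] - exp[0]) ** 2 / var[0])
    return chi2, float(sps.chi2.sf(chi2, df=1))


def _scan_cutpoints(times, events, scores, min_group_fraction):
    """All admissible midpoint cuts with their log-rank χ² (vectorized)."""
    n = len(scores)
    scores = np.asarray(scores, dtype=float)
    distinct = np.unique(scores)
    if len(distinct) < 2:
        return np.empty(0), np.empty(0)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n_high = (scores[None, :] > mids[:, None]).sum(axis=1)
    min_n = min_group_fraction * n
    ok = (n_high >= min_n) & ((n - n_high) >= min_n)
    mids = mids[ok]
    if len(mids) == 0:
        return np.empty(0), np.empty(0)
    member = scores[:, None] > mids[None, :]
    obs, exp, var = _logrank_terms(times, events, member)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(var > 0, (obs - exp) ** 2 / var, 0.0)
    return mids, chi2


def find_cutpoint(records, min_group_fraction: float = 0.1) -> CutpointResult:
    """Outcome-based optimal threshold: the admissible score division with
    the highest two-group log-rank χ² (ties broken toward the lower cut).

    Requires ≥ 20 records and ≥ 5 events.  The uncorrected p is the χ²(1)
    tail at the maximum and is optimistic; see
    :func:`crossvalidate_cutpoint`.
    """
    df = records_to_frame(records)
    if len(df) < 20:
        raise ValueError("cutpoint search requires at least 20 records")
    if df["event"].sum() < 5:
        raise ValueError("cutpoint search requires at least 5 events")
    mids, chi2 = _scan_cutpoints(
        df["time_months"].to_numpy(), df["event"].to_numpy(dtype=bool),
        df["score"].to_numpy(), min_group_fraction,
    )
    if len(mids) == 0:
        raise ValueError("no candidate division satisfies the group-size constraint")
    best = int(np.argmax(chi2))  # argmax returns the first (lowest-cut) maximum
    return CutpointResult(
        threshold=float(mids[best]),
        chi2_max=float(chi2[best]),
        p_uncorrected=float(sps.chi2.sf(chi2[best], df=1)),
        candidate_profile=[(float(m), float(c)) for m, c in zip(mids, chi2)],
        min_group_fraction=min_group_fraction,
    )


def crossvalidate_cutpoint(
    records,
    n_splits: int = 100,
    train_fraction: float = 0.5,
    seed: int = 0,
    min_group_fraction: float = 0.1,
) -> float:
    """Cross-validated significance of the outcome-based cutpoint.

    Each split derives the optimal cut on a random training fraction and
    evaluates the log-rank p on the held-out cases; the median held-out p
    across splits is returned.  Splits whose validation half lacks both
    groups or any event are skipped (logged); all-skipped is an error.
    """
    df = records_to_frame(records)
    n = len(df)
    if n < 20 or df["event"].sum() < 5:
        raise ValueError("cross-validation requires >= 20 records and >= 5 events")
    times = df["time_months"].to_numpy()
    events = df["event"].to_numpy(dtype=bool)
    scores = df["score"].to_numpy()
    rng = np.random.default_rng(seed)
    n_train = max(2, int(round(train_fraction * n)))
    ps = []
    skipped = 0
    for _ in range(n_splits):
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        mids, chi2 = _scan_cutpoints(times[tr], events[tr], scores[tr], min_group_fraction)
        if len(mids) == 0:
            skipped += 1
            continue
        cut = mids[int(np.argmax(chi2))]
        high = scores[va] > cut
        if high.all() or not high.any() or events[va].sum() == 0:
            skipped += 1
            continue
        _, p = logrank_chi2(times[va], events[va], high)
        ps.append(p)
    if skipped:
        logger.info("crossvalidate_cutpoint: skipped %d/%d degenerate splits", skipped, n_splits)
    if not ps:
        raise ValueError("every cross-validation split was degenerate")
    return float(np.median(ps))


# ---------------------------------------------------------------------------
# Kaplan–Meier and Cox

def km_curve(times, events) -> list[tuple[float, float]]:
    """Product-limit survival estimate as (time, S(time)) step pairs,
    starting at (0, 1); right-censoring handled."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    sf = kmf.survival_function_
    pairs = [(float(t), float(s)) for t, s in zip(sf.index, sf.iloc[:, 0])]
    if not pairs or pairs[0][0] != 0.0:
        pairs = [(0.0, 1.0)] + pairs
    return pairs


def cox_multivariable(records, covariate_spec) -> pd.DataFrame:
    """Multivariable Cox proportional-hazards fit (Efron tie handling).

    ``covariate_spec`` lists column names from the record covariates (plus
    optionally ``score`` or ``group``); categorical covariates are one-hot
    encoded with the first level as reference.  Returns a frame with
    covariate, HR, 95% CI bounds and Wald p, mirroring the usual
    HR / 95% CI / p reporting.
    """
    from lifelines import CoxPHFitter

    df = records_to_frame(records)
    if df["event"].sum() == 0:
        raise ValueError("Cox regression requires at least one event")
    cols = list(covariate_spec)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"unknown covariates: {missing}")
    design = df[cols].copy()
    cat_cols = [c for c in cols if design[c].dtype == object]
    if cat_cols:
        design = pd.get_dummies(design, columns=cat_cols, drop_first=True, dtype=float)
    for c in design.columns:
        if design[c].nunique() <= 1:
            raise ValueError(f"covariate '{c}' is constant")
    n_events = int(df["event"].sum())
    if n_events < 5 * design.shape[1]:
        warnings.warn(
            f"only {n_events} events for {design.shape[1]} covariates "
            "(fewer than 5 per covariate); estimates may be unstable",
            stacklevel=2,
        )
    fit_df = pd.concat(
        [df[["time_months", "event"]].astype(float), design.astype(float)], axis=1
    )
    cph = CoxPHFitter()
    try:
        # tight Newton tolerance: default stopping leaves ~1e-4 slack on coefs
        cph.fit(fit_df, duration_col="time_months", event_col="event",
                fit_options={"precision": 1e-9})
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    summary = cph.summary
    return pd.DataFrame(
        {
            "covariate": summary.index,
            "HR": summary["exp(coef)"].to_numpy(),
            "ci_low": summary["exp(coef) lower 95%"].to_numpy(),
            "ci_high": summary["exp(coef) upper 95%"].to_numpy(),
            "p": summary["p"].to_numpy(),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# association and agreement

def association_test(scores, factor) -> tuple[float, float]:
    """Mann–Whitney U between scores split by a binary factor.

    Exact null distribution for group sizes ≤ 20 without ties, otherwise the
    tie-corrected normal approximation.  All-tied input returns (U, nan).
    """
    scores = np.asarray(scores, dtype=float)
    factor = np.asarray(factor)
    uniq = np.unique(factor)
    if len(uniq) != 2:
        raise ValueError("factor must be binary with both levels present")
    a = scores[factor == uniq[0]]
    b = scores[factor == uniq[1]]
    if np.all(scores == scores[0]):
        # every observation tied: U is its null mean, p undefined
        return float(len(a) * len(b) / 2.0), float("nan")
    method = "exact" if max(len(a), len(b)) <= 20 and len(np.unique(scores)) == len(scores) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def agreement(scores_a, scores_b) -> tuple[float, float]:
    """Agreement between paired score series: (ICC(2,1) absolute agreement,
    Wilcoxon signed-rank p).

    Identical series have ICC = 1 and no nonzero paired differences, in
    which case the Wilcoxon p is the sentinel ``nan``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("agreement requires paired series of equal length >= 3")
    icc = _icc_2_1(a, b)
    diffs = b - a
    if np.all(diffs == 0):
        return icc, float("nan")
    res = sps.wilcoxon(a, b, alternative="two-sided")
    return icc, float(res.pvalue)


def _icc_2_1(a: np.ndarray, b: np.ndarray) -> float:
    """Two-way random effects, absolute agreement, single rater: ICC(2,1)."""
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = data - data.mean(axis=1, keepdims=True) - data.mean(axis=0, keepdims=True) + grand
    ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if denom == 0:
        return 1.0
    return float((ms_rows - ms_err) / denom)
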