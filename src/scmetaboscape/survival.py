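"""Signature-based survival stratification of a bulk cohort.

A bulk expression matrix is scored per sample with the GSVA machinery, an
optimal cutpoint on the score is found by maximally selected log-rank
statistics, and the two groups are compared with Kaplan-Meier curves,
log-rank tests and a multivariate Cox proportional-hazards model.

The maximally selected cutpoint inflates the naive log-rank p-value
(a maximum over many correlated statistics is not chi-square(1)); the report
therefore carries both the naive p and a permutation-based
selection-adjusted p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter

from .enrichment import gsva_scores
from .io import ConfigError, DataError, ExpressionMatrix, PathwayCollection
from .markers import Signature

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCohort:
    """Per-sample signature score, follow-up and covariates.

    ``data`` columns: ``time`` (> 0), ``event`` (0/1), ``score``, plus any
    covariates; indexed by sample id.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event", "score"):
            if col not in self.data.columns:
                raise DataError(f"cohort is missing required column {col!r}")
        if (self.data["time"] <= 0).any():
            raise DataError("follow-up times must be positive")
        if not set(self.data["event"].unique()) <= {0, 1}:
            raise DataError("event flags must be 0/1")
        if self.data["score"].isna().any():
            raise DataError("cohort has missing scores")

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event", "score")]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float            # standardized log-rank statistic at the cutpoint
    n_low: int
    n_high: int
    minprop: float
    candidates: pd.DataFrame    # candidate grid with statistics
    selection_adjusted_p: float | None = None
    naive_p: float | None = None


def score_bulk(
    expr: ExpressionMatrix,
    signature: Signature | list[str],
    kernel: str = "gaussian",
) -> pd.Series:
    """Per-sample GSVA score of one signature (samples as columns)."""
    genes = signature.genes if isinstance(signature, Signature) else list(signature)
    name = signature.name if isinstance(signature, Signature) else "signature"
    measured = [g for g in genes if g in set(expr.gene_ids)]
    if len(measured) < 3:
        raise DataError(
            f"signature {name!r}: only {len(measured)} genes measured (need >= 3)"
        )
    sets = PathwayCollection({name: measured})
    scores = gsva_scores(expr, sets, kernel=kernel)
    return scores.scores.loc[name]


def logrank_statistic(
    time: np.ndarray, event: np.ndarray, group_high: np.ndarray
) -> tuple[float, float, float]:
    """Two-group log-rank: returns (O-E of the high group, hypergeometric
    variance, standardized statistic (O-E)/sqrt(V))."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group_high = np.asarray(group_high, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    event_times = np.unique(time[event == 1])
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group_high).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group_high).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    z = o_minus_e / np.sqrt(var) if var > 0 else 0.0
    return float(o_minus_e), float(var), float(z)


def optimal_cutpoint(
    cohort: SurvivalCohort,
    minprop: float = 0.1,
    n_permutations: int = 0,
    seed: int = 0,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint on the score.

    Candidates are the observed score values leaving at least
    ``minprop * n`` samples on each side; the cutpoint maximizes the
    absolute standardized log-rank statistic (ties -> lower cutpoint).
    With ``n_permutations`` > 0 a selection-adjusted p-value is estimated by
    re-running the whole search on score-permuted cohorts.
    """
    if not 0.0 < minprop < 0.5:
        raise ConfigError("minprop must lie in (0, 0.5)")
    df = cohort.data
    n = len(df)
    time = df["time"].values
    event = df["event"].values
    score = df["score"].values

    # log-rank ingredients shared by every candidate: per unique event time,
    # total at-risk n_t and total deaths d_t
    event_times = np.unique(time[event == 1])
    n_t = (time[None, :] >= event_times[:, None]).sum(axis=1).astype(float)
    d_t = np.array([((time == t) & (event == 1)).sum() for t in event_times], dtype=float)
    risk_pos = np.searchsorted(event_times, time, side="right")  # cell at risk at event_times[:risk_pos]
    evt_pos = np.searchsorted(event_times, time)  # index of the cell's own event time

    def search(scores_vec: np.ndarray):
        """Sweep candidates in ascending score order, moving each cell from
        the high to the low group exactly once (incremental log-rank)."""
        svals = np.sort(np.unique(scores_vec))
        cell_order = np.argsort(scores_vec, kind="stable")
        n1_t = n_t.copy()          # at-risk in the high group
        d1_t = d_t.copy()          # deaths in the high group
        records = []
        best = None
        ptr = 0
        with np.errstate(invalid="ignore", divide="ignore"):
            for c in svals[:-1]:  # splitting at the max leaves an empty side
                while ptr < n and scores_vec[cell_order[ptr]] <= c:
                    i = cell_order[ptr]
                    n1_t[: risk_pos[i]] -= 1.0
                    if event[i]:
                        d1_t[evt_pos[i]] -= 1.0
                    ptr += 1
                n_high = n - ptr
                if min(n_high, ptr) < minprop * n:
                    continue
                frac = n1_t / n_t
                oe = float(np.sum(d1_t - d_t * frac))
                var = float(
                    np.sum(d_t * frac * (1 - frac) * (n_t - d_t) / np.maximum(n_t - 1, 1))
                )
                z = abs(oe) / np.sqrt(var) if var > 0 else 0.0
                records.append((c, z, ptr, n_high))
                if best is None or z > best[1] + 1e-15:
                    best = (c, z, ptr, n_high)
        return best, records

    best, records = search(score)
    if best is None:
        raise DataError("no valid cutpoint candidate under the minprop constraint")
    cut, stat, n_low, n_high = best
    naive_p = float(scipy.stats.chi2.sf(stat**2, df=1))
    adj_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm_best, _ = search(rng.permutation(score))
            if perm_best is not None and perm_best[1] >= stat:
                exceed += 1
        adj_p = (1.0 + exceed) / (1.0 + n_permutations)
    return CutpointResult(
        cutpoint=float(cut),
        statistic=float(stat),
        n_low=n_low,
        n_high=n_high,
        minprop=minprop,
        candidates=pd.DataFrame(records, columns=["cutpoint", "abs_z", "n_low", "n_high"]),
        selection_adjusted_p=adj_p,
        naive_p=naive_p,
    )


def km_logrank(
    cohort: SurvivalCohort, cutpoint: float
) -> dict:
    """Kaplan-Meier curves for the score-split groups plus the log-rank test.

    Returns a dict with per-group KM survival functions, O-E, variance,
    chi-square statistic, p, and an ``all_censored`` flag (statistic
    undefined when no events at all).
    """
    df = cohort.data
    high = df["score"].values > cutpoint
    if high.all() or not high.any():
        raise DataError("cutpoint leaves an empty group")
    curves = {}
    for name, mask in (("low", ~high), ("high", high)):
        if mask.sum() == 0:
            raise DataError(f"group {name} is empty")
        km = KaplanMeierFitter()
        km.fit(df["time"][mask], df["event"][mask], label=name)
        curves[name] = km.survival_function_
    o_minus_e, var, z = logrank_statistic(df["time"].values, df["event"].values, high)
    all_censored = df["event"].sum() == 0
    if all_censored:
        logger.warning("no events in the cohort; log-rank statistic undefined")
        chi2 = np.nan
        p = np.nan
    else:
        chi2 = z**2
        p = float(scipy.stats.chi2.sf(chi2, df=1))
    return {
        "curves": curves,
        "o_minus_e": o_minus_e,
        "variance": var,
        "chi2": chi2,
        "p": p,
        "all_censored": bool(all_censored),
        "n_low": int((~high).sum()),
        "n_high": int(high.sum()),
    }


def cox_multivariate(
    cohort: SurvivalCohort,
    covariates: list[str] | None = None,
    score_as: str = "continuous",
    cutpoint: float | None = None,
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    The signature score enters continuously (default) or as the binary
    cutpoint group (``score_as="group"``). Constant covariates are dropped
    with a warning; duplicated (collinear) columns raise. Returns a table
    with hazard ratios, Wald CIs and p-values per covariate.
    """
    covariates = list(covariates) if covariates is not None else cohort.covariate_names
    df = cohort.data.copy()
    if score_as == "continuous":
        df["score_term"] = df["score"]
    elif score_as == "group":
        if cutpoint is None:
            raise ConfigError("score_as='group' requires a cutpoint")
        df["score_term"] = (df["score"] > cutpoint).astype(float)
    else:
        raise ConfigError("score_as must be 'continuous' or 'group'")

    design_cols = ["score_term"]
    for c in covariates:
        if c not in df.columns:
            raise DataError(f"covariate {c!r} not in cohort")
        col = df[c]
        if not np.issubdtype(col.dtype, np.number):
            col = pd.Categorical(col).codes.astype(float)
            df[c] = col
        if np.std(col) == 0:
            logger.warning("covariate %s is constant; dropped", c)
            continue
        design_cols.append(c)
    design = df[["time", "event", *design_cols]]
    # explicit rank check so collinearity fails loudly, not with NaN output
    M = design[design_cols].values
    if np.linalg.matrix_rank(M - M.mean(axis=0)) < len(design_cols):
        raise DataError("design matrix is rank-deficient (collinear covariates)")
    n_events = int(df["event"].sum())
    if n_events < 10 * len(design_cols):
        logger.warning(
            "only %d events for %d covariates (< 10 per covariate); "
            "estimates may be unstable", n_events, len(design_cols),
        )
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="time", event_col="event")
    except Exception as err:  # lifelines raises ConvergenceError subclasses
        raise DataError(f"Cox model failed to converge: {err}") from err
    summary = cph.summary
    out = pd.DataFrame(
        {
            "coef": summary["coef"],
            "hazard_ratio": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    out.index.name = "term"
    return out
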