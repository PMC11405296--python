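"""Time-to-onset (TTO) extraction and Weibull failure-pattern modelling.

TTO is the number of whole days from the start of therapy with the suspect
drug to the adverse-event onset date.  The two-parameter Weibull distribution

    f(t) = (beta/alpha) * (t/alpha)**(beta-1) * exp(-(t/alpha)**beta),  t > 0

summarizes the hazard trend through its shape parameter beta: beta < 1 means
a declining hazard — events concentrate early after administration ("early
failure"); beta = 1 is a time-homogeneous (exponential) pattern; beta > 1 an
increasing hazard ("wear-out", e.g. late secondary malignancies).  The fit is
plain maximum likelihood on observed onsets (no censoring model), with Wald
95% confidence intervals built on the log of each parameter so the bounds stay
positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .cohort import DrugQuery
from .faers_io import SafetyReport

Z_95 = 1.959963984540054


@dataclass(frozen=True)
class TTORecord:
    report_id: str
    event: str
    tto_days: int | None
    validity: str  # valid / negative / missing_start / missing_event / imprecise_date

    def __post_init__(self):
        if (self.tto_days is not None) != (self.validity == "valid"):
            raise ValueError("tto_days must be present exactly when validity == valid")


@dataclass
class WeibullFit:
    n_used: int
    alpha: float | None
    alpha_ci: tuple[float, float] | None
    beta: float | None
    beta_ci: tuple[float, float] | None
    failure_type: str  # early / random / wear_out / indeterminate
    log_likelihood: float | None
    converged: bool
    message: str = ""


# ---------------------------------------------------------------------------
# TTO extraction


def compute_tto(
    cohort: Sequence[SafetyReport],
    drug_query: DrugQuery,
    include_imprecise: bool = False,
) -> list[TTORecord]:
    """One record per (report, reaction PT) with onset interval and validity.

    The onset interval is event_dt minus the earliest therapy-start date among
    drug entries matching the query.  Negative intervals and intervals built
    from partial (imputed) dates are flagged, not silently used; the latter can
    be admitted with ``include_imprecise``.
    """
    pats = [p.lower() for p in drug_query.name_patterns]
    records: list[TTORecord] = []
    for r in cohort:
        starts = [
            d.start_dt
            for d in r.drugs
            if d.role in drug_query.roles_included
            and d.start_dt is not None
            and any(p in " ".join(d.drug_name_raw.lower().split()) for p in pats)
        ]
        events = r.reactions or ("",)
        if not starts:
            for pt in events:
                records.append(TTORecord(r.primaryid, pt, None, "missing_start"))
            continue
        if r.event_dt is None:
            for pt in events:
                records.append(TTORecord(r.primaryid, pt, None, "missing_event"))
            continue
        start = min(starts, key=lambda p: p.date)
        imprecise = start.imprecise or r.event_dt.imprecise
        if imprecise and not include_imprecise:
            for pt in events:
                records.append(TTORecord(r.primaryid, pt, None, "imprecise_date"))
            continue
        days = (r.event_dt.date - start.date).days
        validity = "valid" if days >= 0 else "negative"
        for pt in events:
            records.append(
                TTORecord(r.primaryid, pt, days if days >= 0 else None, validity)
            )
    return records


def valid_days(records: Sequence[TTORecord]) -> np.ndarray:
    return np.array([r.tto_days for r in records if r.validity == "valid"], dtype=float)


def per_report_days(records: Sequence[TTORecord]) -> np.ndarray:
    """One onset value per report (a report's onset is shared by its PTs)."""
    by_report = {r.report_id: r.tto_days for r in records if r.validity == "valid"}
    return np.array(list(by_report.values()), dtype=float)


def onset_window_summary(
    records: Sequence[TTORecord] | Sequence[float], window_days: int = 30
) -> dict:
    """Median/mean/quartiles over valid records plus the share within the window.

    Accepts TTORecords or raw day values (useful for per-report summaries).
    """
    if len(records) and isinstance(records[0], TTORecord):
        days = valid_days(records)  # type: ignore[arg-type]
        counts = {v: sum(1 for r in records if r.validity == v)
                  for v in ("valid", "negative", "missing_start", "missing_event", "imprecise_date")}
    else:
        days = np.asarray(records, dtype=float)
        counts = {"valid": int(days.size)}
    if days.size == 0:
        return {"n_valid": 0, "validity_counts": counts, "median": None, "mean": None,
                "q1": None, "q3": None, "prop_within_window": None,
                "prop_day0": None, "window_days": window_days}
    return {
        "n_valid": int(days.size),
        "validity_counts": counts,
        "median": float(np.median(days)),
        "mean": float(np.mean(days)),
        "q1": float(np.percentile(days, 25)),
        "q3": float(np.percentile(days, 75)),
        "prop_within_window": float(np.mean(days <= window_days)),
        "prop_day0": float(np.mean(days == 0)),
        "window_days": window_days,
    }


# ---------------------------------------------------------------------------
# Weibull MLE


def weibull_loglik(t: np.ndarray, alpha: float, beta: float) -> float:
    n = t.size
    return float(
        n * math.log(beta)
        - n * beta * math.log(alpha)
        + (beta - 1) * np.log(t).sum()
        - ((t / alpha) ** beta).sum()
    )


def _shape_score(b: float, t: np.ndarray, mean_log: float) -> float:
    # profile score equation for the shape: 1/b + mean(ln t) - sum(t^b ln t)/sum(t^b)
    tb = t**b
    return 1.0 / b + mean_log - float((tb * np.log(t)).sum() / tb.sum())


def weibull_mle(
    tto: Sequence[float] | np.ndarray | Sequence[TTORecord],
    zero_handling: str = "shift",
    min_n: int = 10,
) -> WeibullFit:
    """Two-parameter Weibull MLE with Wald CIs from the observed information.

    ``tto`` may be raw day counts or TTORecords (only valid ones are used).
    Day-0 onsets lie outside the Weibull support; ``zero_handling`` is one of
    ``shift`` (0 -> 0.5 day, the default), ``drop``, or ``offset`` (+1 day to
    every observation).  The profile likelihood in the shape is maximized by
    root-finding on its score, which is monotone, so convergence is
    deterministic; CIs come from the numerically evaluated observed information
    on (log alpha, log beta).
    """
    if len(tto) and isinstance(tto[0], TTORecord):
        t = valid_days(tto)  # type: ignore[arg-type]
    else:
        t = np.asarray(tto, dtype=float)
    t = t[np.isfinite(t) & (t >= 0)]
    if zero_handling == "shift":
        t = np.where(t == 0, 0.5, t)
    elif zero_handling == "offset":
        t = t + 1.0
    elif zero_handling == "drop":
        t = t[t > 0]
    else:
        raise ValueError(f"unknown zero_handling {zero_handling!r}")

    def fail(msg: str) -> WeibullFit:
        return WeibullFit(int(t.size), None, None, None, None, "indeterminate",
                          None, False, msg)

    if t.size < min_n:
        return fail(f"fewer than {min_n} usable onset values")
    if np.all(t == t[0]):
        return fail("degenerate likelihood: all onset values equal")

    mean_log = float(np.log(t).mean())
    lo, hi = 1e-3, 1.0
    # bracket the root of the monotone-decreasing score
    while _shape_score(hi, t, mean_log) > 0 and hi < 1e4:
        hi *= 2.0
    if hi >= 1e4:
        return fail("shape score has no root below 1e4")
    try:
        beta = optimize.brentq(_shape_score, lo, hi, args=(t, mean_log), xtol=1e-12)
    except ValueError as exc:
        return fail(f"root finding failed: {exc}")
    alpha = float(((t**beta).mean()) ** (1.0 / beta))
    ll = weibull_loglik(t, alpha, beta)

    # observed information on (log alpha, log beta) by central differences
    la, lb = math.log(alpha), math.log(beta)

    def nll(theta):
        return -weibull_loglik(t, math.exp(theta[0]), math.exp(theta[1]))

    h = 1e-5
    hess = np.empty((2, 2))
    theta0 = np.array([la, lb])
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            hess[i, j] = (
                nll(theta0 + ei + ej) - nll(theta0 + ei - ej)
                - nll(theta0 - ei + ej) + nll(theta0 - ei - ej)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return fail("singular observed information")
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    if not np.all(np.isfinite(se)) or np.any(se == 0):
        return fail("non-finite standard errors")
    alpha_ci = (alpha * math.exp(-Z_95 * se[0]), alpha * math.exp(Z_95 * se[0]))
    beta_ci = (beta * math.exp(-Z_95 * se[1]), beta * math.exp(Z_95 * se[1]))
    fit = WeibullFit(int(t.size), alpha, alpha_ci, beta, beta_ci, "indeterminate",
                     ll, True)
    fit.failure_type = classify_failure_type(fit)
    return fit


def classify_failure_type(fit: WeibullFit) -> str:
    """Hazard-trend call from the shape CI: a total, deterministic rule.

    early if the CI lies below 1, wear_out if above, random if it straddles 1,
    indeterminate for failed fits.
    """
    if not fit.converged or fit.beta_ci is None:
        return "indeterminate"
    lo, hi = fit.beta_ci
    if hi < 1.0:
        return "early"
    if lo > 1.0:
        return "wear_out"
    return "random"
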