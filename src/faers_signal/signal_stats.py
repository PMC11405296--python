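"""Disproportionality statistics on spontaneous reports: ROR and the BCPNN IC.

For each (drug, event) pair a 2x2 table is formed over deduplicated reports

                    event   no event
    target drug       a        b
    other drugs       c        d

with reports (not reaction multiplicities) as the counting unit.  Two signal
statistics are computed:

* reporting odds ratio  ROR = (a*d)/(b*c)  with a 95% Wald CI on the log scale,
  se = sqrt(1/a + 1/b + 1/c + 1/d);
* information component IC = log2((a + 0.5) / (E + 0.5)) with expected count
  E = (a+b)(a+c)/N, the closed-form shrinkage estimator of the Bayesian
  confidence propagation neural network, and its lower credibility bound
  IC025 = IC - 3.3*(a+0.5)^(-1/2) - 2*(a+0.5)^(-3/2).

The conventional flags are ROR CI lower bound > 1 with >=3 cases, and
IC025 > 0.  No multiple-testing correction is applied: disproportionality
screening is hypothesis generation, and flagged pairs are candidates for
clinical review, not confirmed associations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .faers_io import SafetyReport

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int
    event: str = ""
    level: str = "PT"  # PT / SOC / HLGT
    stratum: str = "overall"

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SignalResult:
    event: str
    n_cases: int
    ror: float | None
    ror_ci_low: float | None
    ror_ci_high: float | None
    ic: float
    ic025: float
    level: str = "PT"
    stratum: str = "overall"
    ror_undefined_reason: str | None = None
    ror_signal: bool = False
    ic_signal: bool = False
    unexpected: bool | None = None


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds that turn statistics into flags; defaults are the standard ones."""

    min_cases: int = 3
    ror_ci_low_gt: float = 1.0
    ic025_gt: float = 0.0


# ---------------------------------------------------------------------------
# table construction


def event_index(
    reports: Sequence[SafetyReport], level: str = "PT"
) -> dict[str, set[str]]:
    """Map event term -> set of primaryids mentioning it.

    At PT level every distinct reaction term counts once per report.  At SOC
    level a report counts once per distinct mapped SOC (reports must have been
    through MedDRA attachment; unmapped PTs contribute nothing at SOC level).
    """
    idx: dict[str, set[str]] = {}
    for r in reports:
        if level == "PT":
            terms: Iterable[str] = r.reactions
        elif level in ("SOC", "HLGT"):
            terms = set((r.socs or {}).values())
        else:
            raise ValueError(f"unknown level {level!r}")
        for t in terms:
            idx.setdefault(t, set()).add(r.primaryid)
    return idx


def build_contingency(
    universe: Sequence[SafetyReport],
    cohort: Sequence[SafetyReport],
    event: str,
    level: str = "PT",
    stratum: str = "overall",
    universe_index: Mapping[str, set[str]] | None = None,
) -> ContingencyTable:
    """2x2 counts for one (drug, event) pair within one analysis stratum.

    ``universe`` is the full deduplicated report set restricted to the stratum;
    ``cohort`` the target-drug reports within it.  ``universe_index`` may carry
    a precomputed :func:`event_index` of the universe to amortize repeated calls.
    """
    idx = universe_index if universe_index is not None else event_index(universe, level)
    with_event = idx.get(event, set())
    cohort_ids = {r.primaryid for r in cohort}
    a = len(with_event & cohort_ids)
    b = len(cohort_ids) - a
    c = len(with_event) - a
    d = len(universe) - len(cohort_ids) - c
    return ContingencyTable(a, b, c, d, event=event, level=level, stratum=stratum)


# ---------------------------------------------------------------------------
# statistics


def compute_ror(
    t: ContingencyTable, continuity_correction: bool = False
) -> tuple[float | None, float | None, float | None, str | None]:
    """ROR with 95% Wald CI; a zero cell yields (None, None, None, reason).

    With ``continuity_correction`` the Haldane +0.5 is added to every cell
    instead; the default leaves zero-cell pairs undefined rather than invent
    signal strength (the IC covers the sparse-count regime).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if continuity_correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        zero = [cell for cell, v in zip("abcd", (a, b, c, d)) if v == 0]
        return None, None, None, f"zero cell: {','.join(zero)}"
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-Z_95 * se), ror * math.exp(Z_95 * se), None


def compute_ic(t: ContingencyTable) -> tuple[float, float]:
    """Shrunk information component and its 2.5% credibility bound.

    Defined for every table, including a = 0, which is what makes the IC the
    statistic of choice for rare events such as secondary malignancies.
    """
    n = t.n
    expected = (t.a + t.b) * (t.a + t.c) / n
    a5 = t.a + 0.5
    ic = math.log2(a5 / (expected + 0.5))
    ic025 = ic - 3.3 * a5 ** -0.5 - 2.0 * a5 ** -1.5
    return ic, ic025


def result_from_table(
    t: ContingencyTable, continuity_correction: bool = False
) -> SignalResult:
    ror, lo, hi, reason = compute_ror(t, continuity_correction)
    ic, ic025 = compute_ic(t)
    return SignalResult(
        event=t.event,
        n_cases=t.a,
        ror=ror,
        ror_ci_low=lo,
        ror_ci_high=hi,
        ic=ic,
        ic025=ic025,
        level=t.level,
        stratum=t.stratum,
        ror_undefined_reason=reason,
    )


def detect_signals(
    results: Sequence[SignalResult], criteria: SignalCriteria = SignalCriteria()
) -> list[SignalResult]:
    """Set the ror_signal / ic_signal flags according to the criteria."""
    out = []
    for r in results:
        ror_sig = (
            r.n_cases >= criteria.min_cases
            and r.ror_ci_low is not None
            and r.ror_ci_low > criteria.ror_ci_low_gt
        )
        ic_sig = r.ic025 > criteria.ic025_gt
        out.append(replace(r, ror_signal=ror_sig, ic_signal=ic_sig))
    return out


def rank_top(
    results: Sequence[SignalResult], k: int | None = 20, by: str = "ror"
) -> list[SignalResult]:
    """Top-k signal-positive results, descending by ``by`` (default ROR).

    Ties break by case count (larger first) then event name; undefined RORs
    sort last.  ``k`` beyond the list length returns everything.
    """
    positive = [r for r in results if r.ror_signal or (by != "ror" and r.ic_signal)]

    def key(r: SignalResult):
        v = getattr(r, by)
        return (-(v if v is not None else -math.inf), -r.n_cases, r.event)

    ranked = sorted(positive, key=key)
    return ranked if k is None else ranked[:k]


def flag_unexpected(
    results: Sequence[SignalResult], label_terms: Sequence[str]
) -> list[SignalResult]:
    """Mark signal-positive events absent from the product label's term list."""
    import logging

    if not label_terms:
        logging.getLogger(__name__).warning(
            "empty label term list: every signal will be marked unexpected"
        )
    labeled = {" ".join(t.lower().split()) for t in label_terms}
    out = []
    for r in results:
        if r.ror_signal or r.ic_signal:
            unexpected = " ".join(r.event.lower().split()) not in labeled
        else:
            unexpected = False
        out.append(replace(r, unexpected=unexpected))
    return out


# ---------------------------------------------------------------------------
# whole-screen driver


def screen(
    universe: Sequence[SafetyReport],
    cohort: Sequence[SafetyReport],
    level: str = "PT",
    stratum: str = "overall",
    criteria: SignalCriteria = SignalCriteria(),
    continuity_correction: bool = False,
) -> list[SignalResult]:
    """ROR/IC results for every event term reported at least once in the cohort."""
    idx = event_index(universe, level)
    cohort_idx = event_index(cohort, level)
    results = []
    for event in sorted(cohort_idx):
        t = build_contingency(
            universe, cohort, event, level=level, stratum=stratum, universe_index=idx
        )
        results.append(result_from_table(t, continuity_correction))
    return detect_signals(results, criteria)


# ---------------------------------------------------------------------------
# published-row consistency check


def wald_width_feasible(n_cases: int, ci_low: float, ci_high: float) -> bool:
    """Check a printed ROR row for internal consistency with the Wald CI.

    The implied standard error ln(hi/lo)/(2*1.96) can never fall below
    sqrt(1/a), the floor contributed by the case-count cell alone, so a printed
    (n, CI) pair violating that bound cannot come from the Wald construction.
    """
    implied_se = math.log(ci_high / ci_low) / (2 * Z_95)
    return implied_se >= math.sqrt(1.0 / n_cases) - 1e-9


def results_to_rows(results: Sequence[SignalResult]) -> list[dict]:
    """Flatten results for TSV export (level, stratum, event, n, ror, ci, ic...)."""
    rows = []
    for r in results:
        rows.append(
            {
                "level": r.level,
                "stratum": r.stratum,
                "event": r.event,
                "n": r.n_cases,
                "ror": "" if r.ror is None else f"{r.ror:.4g}",
                "ror_ci_low": "" if r.ror_ci_low is None else f"{r.ror_ci_low:.4g}",
                "ror_ci_high": "" if r.ror_ci_high is None else f"{r.ror_ci_high:.4g}",
                "ic": f"{r.ic:.4f}",
                "ic025": f"{r.ic025:.4f}",
                "ror_signal": r.ror_signal,
                "ic_signal": r.ic_signal,
                "unexpected": "" if r.unexpected is None else r.unexpected,
                "ror_undefined_reason": r.ror_undefined_reason or "",
            }
        )
    return rows
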