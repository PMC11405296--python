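"""Stratified and subset safety analyses.

Covers the secondary analyses that accompany an overall disproportionality
screen of a CAR-T cohort: sex and age subgroup screens, within-cohort
female-vs-male reporting ratios, the death-outcome subset, and a grouped IC
screen for secondary malignancies (sparse events, hence IC rather than ROR)
with their time-to-onset profile.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .cohort import DrugQuery, DemographicSummary, summarize_demographics
from .faers_io import SafetyReport
from .signal_stats import (
    ContingencyTable,
    SignalCriteria,
    SignalResult,
    Z_95,
    compute_ic,
    result_from_table,
    screen,
)
from .tto_weibull import TTORecord, compute_tto, onset_window_summary


@dataclass(frozen=True)
class StratumSpec:
    """Named subgroup defined by a total predicate over reports.

    Reports with an unknown stratifying variable fall outside every stratum of
    that variable but stay in the overall analysis.
    """

    name: str
    predicate: Callable[[SafetyReport], bool]


def default_strata() -> list[StratumSpec]:
    """Sex and adult age-band strata; under-18s are omitted (too few reports)."""
    return [
        StratumSpec("female", lambda r: r.sex == "F"),
        StratumSpec("male", lambda r: r.sex == "M"),
        StratumSpec("age_18_64", lambda r: r.age_years is not None and 18 <= r.age_years < 65),
        StratumSpec("age_65_plus", lambda r: r.age_years is not None and r.age_years >= 65),
        StratumSpec("male_18_64", lambda r: r.sex == "M" and r.age_years is not None and 18 <= r.age_years < 65),
        StratumSpec("female_18_64", lambda r: r.sex == "F" and r.age_years is not None and 18 <= r.age_years < 65),
        StratumSpec("male_65_plus", lambda r: r.sex == "M" and r.age_years is not None and r.age_years >= 65),
        StratumSpec("female_65_plus", lambda r: r.sex == "F" and r.age_years is not None and r.age_years >= 65),
    ]


def subgroup_signals(
    universe: Sequence[SafetyReport],
    cohort: Sequence[SafetyReport],
    strata: Sequence[StratumSpec] | None = None,
    level: str = "PT",
    criteria: SignalCriteria = SignalCriteria(),
) -> dict[str, list[SignalResult]]:
    """Full ROR/IC screen within each stratum's restriction of the universe."""
    strata = list(strata) if strata is not None else default_strata()
    cohort_ids = {r.primaryid for r in cohort}
    out: dict[str, list[SignalResult]] = {}
    for spec in strata:
        uni_s = [r for r in universe if spec.predicate(r)]
        coh_s = [r for r in uni_s if r.primaryid in cohort_ids]
        if not coh_s:
            out[spec.name] = []
            continue
        out[spec.name] = screen(uni_s, coh_s, level=level, stratum=spec.name, criteria=criteria)
    return out


def sex_difference_ror(
    cohort: Sequence[SafetyReport], event: str
) -> tuple[float | None, tuple[float, float] | None, str | None]:
    """Female-vs-male reporting odds ratio for one event within the cohort.

    The 2x2 table crosses sex (F/M rows; unknown-sex reports excluded) with
    event mention.  ROR > 1 means the event is relatively more reported in
    female recipients.  Returns (ror, (ci_low, ci_high), undefined_reason).
    """
    f_yes = f_no = m_yes = m_no = 0
    for r in cohort:
        has = event in r.reactions
        if r.sex == "F":
            f_yes, f_no = f_yes + has, f_no + (not has)
        elif r.sex == "M":
            m_yes, m_no = m_yes + has, m_no + (not has)
    if (f_yes + f_no) == 0 or (m_yes + m_no) == 0:
        return None, None, "a sex stratum is empty"
    if min(f_yes, f_no, m_yes, m_no) == 0:
        zero = [n for n, v in (("f_yes", f_yes), ("f_no", f_no), ("m_yes", m_yes), ("m_no", m_no)) if v == 0]
        return None, None, f"zero cell: {','.join(zero)}"
    ror = (f_yes * m_no) / (f_no * m_yes)
    se = math.sqrt(1 / f_yes + 1 / f_no + 1 / m_yes + 1 / m_no)
    return ror, (ror * math.exp(-Z_95 * se), ror * math.exp(Z_95 * se)), None


def sex_difference_table(
    cohort: Sequence[SafetyReport], min_cases: int = 3
) -> list[dict]:
    """F-vs-M ROR for every PT with at least ``min_cases`` cohort reports."""
    counts: dict[str, int] = {}
    for r in cohort:
        for pt in r.reactions:
            counts[pt] = counts.get(pt, 0) + 1
    rows = []
    for pt in sorted(counts):
        if counts[pt] < min_cases:
            continue
        ror, ci, reason = sex_difference_ror(cohort, pt)
        rows.append(
            {"event": pt, "n": counts[pt],
             "ror_f_vs_m": ror, "ci_low": ci[0] if ci else None,
             "ci_high": ci[1] if ci else None, "undefined_reason": reason}
        )
    return rows


def death_outcome_signals(
    universe: Sequence[SafetyReport],
    cohort: Sequence[SafetyReport],
    level: str = "PT",
    criteria: SignalCriteria = SignalCriteria(),
) -> tuple[list[SignalResult], DemographicSummary | None]:
    """Disproportionality within death-outcome reports plus their demographics.

    Both the universe and the cohort are restricted to reports whose outcome
    codes include DE, so the comparator is "other drugs, fatal outcome".
    """
    uni_d = [r for r in universe if "DE" in r.outcomes]
    cohort_ids = {r.primaryid for r in cohort}
    coh_d = [r for r in uni_d if r.primaryid in cohort_ids]
    if not coh_d:
        return [], None
    results = screen(uni_d, coh_d, level=level, stratum="death", criteria=criteria)
    return results, summarize_demographics(coh_d)


# ---------------------------------------------------------------------------
# secondary malignancies


@dataclass
class MalignancyTermSet:
    """PT membership of malignancy high-level groups, user-editable.

    Groups follow the HLGT-style families relevant to post-CAR-T secondary
    malignancies (leukemias, plasma cell neoplasms, lymphomas, skin neoplasms,
    gastrointestinal neoplasms, miscellaneous site-unspecified).  Full PT
    membership must be supplied by the user (MedDRA is licensed); the shipped
    seed file lists the group names with starter terms.
    """

    groups: dict[str, list[str]] = field(default_factory=dict)
    grouping_level: str = "HLGT"

    def __post_init__(self):
        if not self.groups:
            raise ValueError("MalignancyTermSet requires at least one group")
        for g, pts in self.groups.items():
            if len(set(map(str.lower, pts))) != len(pts):
                raise ValueError(f"duplicate PTs in group {g!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MalignancyTermSet":
        groups: dict[str, list[str]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                groups.setdefault(row["group"], []).append(row["pt"])
        return cls(groups)

    def all_pts(self) -> set[str]:
        return {pt.lower() for pts in self.groups.values() for pt in pts}


def malignancy_screen(
    universe: Sequence[SafetyReport],
    cohort: Sequence[SafetyReport],
    terms: MalignancyTermSet,
    drug_query: DrugQuery | None = None,
) -> list[dict]:
    """Grouped IC screen over malignancy term groups plus TTO summaries.

    Per group, `a` counts cohort reports mentioning any member PT (a report
    counts once per group); IC/IC025 are computed from the grouped 2x2 table.
    Zero-case groups are still reported (the IC is defined at a = 0).  When a
    drug query is given, onset statistics over the group's events are added.
    """
    cohort_ids = {r.primaryid for r in cohort}
    tto_by_report: dict[str, dict[str, int]] = {}
    if drug_query is not None:
        for rec in compute_tto(cohort, drug_query):
            if rec.validity == "valid":
                tto_by_report.setdefault(rec.report_id, {})[rec.event.lower()] = rec.tto_days

    rows = []
    for group in sorted(terms.groups):
        pts = {p.lower() for p in terms.groups[group]}

        def mentions(r: SafetyReport) -> bool:
            return any(pt.lower() in pts for pt in r.reactions)

        with_event = {r.primaryid for r in universe if mentions(r)}
        a = len(with_event & cohort_ids)
        b = len(cohort_ids) - a
        c = len(with_event) - a
        d = len(universe) - len(cohort_ids) - c
        ic, ic025 = compute_ic(ContingencyTable(a, b, c, d, event=group, level="HLGT"))
        ttos = [
            days
            for pid, by_pt in tto_by_report.items()
            for pt, days in by_pt.items()
            if pt in pts
        ]
        rows.append(
            {
                "group": group,
                "n": a,
                "ic": ic,
                "ic025": ic025,
                "ic_signal": ic025 > 0,
                "tto_n": len(ttos),
                "tto_mean": sum(ttos) / len(ttos) if ttos else None,
                "tto_median": _median(ttos) if ttos else None,
            }
        )
    return rows


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0
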