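"""Target-drug cohort selection, MedDRA annotation and Table-1-style demographics.

The cohort for each CAR-T product is every deduplicated report that lists the
product as primary or secondary suspect.  Drug-name matching is deliberately
pattern-driven (brand name, generic name, development codes) because verbatim
FAERS drug strings are noisy; the shipped defaults for idecabtagene vicleucel
and ciltacabtagene autoleucel can be overridden from config.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .faers_io import SafetyReport

logger = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class DrugQuery:
    """Name patterns and suspect roles that define one product's cohort."""

    label: str
    name_patterns: tuple[str, ...]
    roles_included: frozenset[str] = frozenset({"PS", "SS"})

    def __post_init__(self):
        if not self.name_patterns:
            raise ValueError("DrugQuery requires at least one name pattern")
        if not self.roles_included:
            raise ValueError("DrugQuery requires at least one role")

    def matches(self, report: SafetyReport) -> bool:
        pats = [p.lower() for p in self.name_patterns]
        for d in report.drugs:
            if d.role in self.roles_included:
                name = " ".join(d.drug_name_raw.lower().split())
                if any(p in name for p in pats):
                    return True
        return False


#: default match lists for the two marketed anti-BCMA CAR-T products
DEFAULT_DRUG_QUERIES = (
    DrugQuery("ide-cel", ("abecma", "idecabtagene", "ide-cel", "bb2121", "bb-2121")),
    DrugQuery("cilta-cel", ("carvykti", "ciltacabtagene", "cilta-cel", "jnj-68284528", "lcar-b38m")),
)


def select_cohort(reports: Sequence[SafetyReport], query: DrugQuery) -> list[SafetyReport]:
    """Reports with >=1 drug entry matching the query (substring, case-insensitive)."""
    cohort = [r for r in reports if query.matches(r)]
    if not cohort:
        logger.warning("drug query %r matched no reports", query.label)
    return cohort


# ---------------------------------------------------------------------------
# MedDRA


@dataclass
class MedDRAMap:
    """User-supplied PT -> SOC (and optionally PT -> HLGT) lookup.

    MedDRA is licensed, so no dictionary ships with the package; lookups are
    case-insensitive after whitespace normalization and unmapped PTs are
    reported, never dropped.
    """

    pt_to_soc: dict[str, str] = field(default_factory=dict)
    pt_to_hlgt: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.pt_to_soc = {self._norm(k): v for k, v in self.pt_to_soc.items()}
        self.pt_to_hlgt = {self._norm(k): v for k, v in self.pt_to_hlgt.items()}

    @staticmethod
    def _norm(pt: str) -> str:
        return " ".join(pt.lower().split())

    def soc(self, pt: str) -> str | None:
        return self.pt_to_soc.get(self._norm(pt))

    def hlgt(self, pt: str) -> str | None:
        return self.pt_to_hlgt.get(self._norm(pt))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MedDRAMap":
        """Load a TSV with columns pt, soc and optionally hlgt."""
        soc, hlgt = {}, {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                soc[row["pt"]] = row["soc"]
                if row.get("hlgt"):
                    hlgt[row["pt"]] = row["hlgt"]
        return cls(soc, hlgt)


def attach_meddra(
    cohort: Sequence[SafetyReport], meddra: MedDRAMap
) -> tuple[list[SafetyReport], float]:
    """Annotate every reaction PT with its SOC; returns (cohort, unmapped fraction)."""
    n_pts = 0
    n_unmapped = 0
    out = []
    for r in cohort:
        socs = {}
        for pt in r.reactions:
            n_pts += 1
            s = meddra.soc(pt)
            if s is None:
                n_unmapped += 1
            else:
                socs[pt] = s
        out.append(replace(r, socs=socs))
    frac = n_unmapped / n_pts if n_pts else 0.0
    if frac > 0.5:
        logger.warning(
            "%.0f%% of PTs unmapped — check the MedDRA table version", 100 * frac
        )
    return out, frac


# ---------------------------------------------------------------------------
# demographics (Table-1 shape)


def round_pct(count: int, denom: int, ndigits: int = 1) -> float:
    """Percentage rounded half-up to one decimal, the convention of printed tables."""
    if denom == 0:
        return 0.0
    pct = Decimal(100 * count) / Decimal(denom)
    q = Decimal(1).scaleb(-ndigits)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


AGE_BANDS = ("<18", "18-64", ">=65", "unknown")
WEIGHT_BANDS = ("<50", "50-100", ">100", "unknown")


def age_band(age_years: float | None) -> str:
    if age_years is None:
        return "unknown"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64"
    return ">=65"


def weight_band(weight_kg: float | None) -> str:
    if weight_kg is None:
        return "unknown"
    if weight_kg < 50:
        return "<50"
    if weight_kg <= 100:
        return "50-100"
    return ">100"


@dataclass
class DemographicSummary:
    """Counts and printed-style percentages per categorical block.

    ``blocks`` maps block name (sex, weight_kg, age_group, reporter, outcome,
    report_year, country) to an ordered {category: (count, pct)} dict.  Within
    each block except ``outcome`` the counts sum to the cohort size; a report
    can carry several outcome codes, so the outcome block is tallied per code
    with a separate none-reported bucket.
    """

    n: int
    blocks: dict[str, dict[str, tuple[int, float]]]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["block", "category", "count", "pct"])
            w.writerow(["overall", "N", self.n, 100.0])
            for block, cats in self.blocks.items():
                for cat, (c, p) in cats.items():
                    w.writerow([block, cat, c, p])


_OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other",
}


def summarize_demographics(cohort: Sequence[SafetyReport]) -> DemographicSummary:
    """Tabulate the cohort the way published FAERS case series print Table 1."""
    n = len(cohort)

    def block(values: Iterable[str], order: Sequence[str]) -> dict[str, tuple[int, float]]:
        counts: dict[str, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        ordered = list(order) + sorted(set(counts) - set(order))
        return {cat: (counts.get(cat, 0), round_pct(counts.get(cat, 0), n)) for cat in ordered}

    sex = block((r.sex if r.sex in ("F", "M") else "unknown" for r in cohort), ("F", "M", "unknown"))
    weight = block((weight_band(r.weight_kg) for r in cohort), WEIGHT_BANDS)
    age = block((age_band(r.age_years) for r in cohort), AGE_BANDS)
    reporter = block(
        (r.reporter for r in cohort), ("healthcare_professional", "consumer", "unknown")
    )
    years = block(
        (str(r.report_year()) if r.report_year() else "unknown" for r in cohort), ()
    )
    country = block(
        ("United States" if r.country.upper() in ("US", "USA", "UNITED STATES") else
         ("unknown" if r.country == "unknown" else "other") for r in cohort),
        ("United States", "other", "unknown"),
    )
    outcome: dict[str, tuple[int, float]] = {}
    for code, label in _OUTCOME_LABELS.items():
        c = sum(1 for r in cohort if code in r.outcomes)
        if c or code in ("DE", "LT", "HO", "DS", "OT"):
            outcome[label] = (c, round_pct(c, n))
    none = sum(1 for r in cohort if not r.outcomes)
    outcome["unknown"] = (none, round_pct(none, n))

    return DemographicSummary(
        n=n,
        blocks={
            "sex": sex,
            "weight_kg": weight,
            "age_group": age,
            "reporter": reporter,
            "outcome": outcome,
            "report_year": years,
            "country": country,
        },
    )
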