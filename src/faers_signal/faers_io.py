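"""Reading FAERS quarterly ASCII tables and case-level deduplication.

FAERS quarters are published as seven "$"-delimited text tables (DEMO, DRUG,
REAC, OUTC, THER, RPSR, INDI) keyed by PRIMARYID.  A single case (CASEID) may
appear several times across quarters as follow-up versions; the FDA-recommended
cleaning keeps, per case, the version with the most recent FDA receipt date
(FDA_DT), breaking ties by the numerically larger PRIMARYID.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

MANDATORY_TABLES = ("DEMO", "DRUG", "REAC")
KNOWN_TABLES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "RPSR", "INDI")

OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

#: one alias map covers the column-name dialects seen in post-2012 files
_COLUMN_ALIASES = {
    "primary_id": "primaryid",
    "case_id": "caseid",
    "isr": "primaryid",  # legacy key; legacy files themselves are unsupported
    "case": "caseid",
    "gndr_cod": "sex",
    "sex": "sex",
    "pt": "pt",
    "drugname": "drugname",
    "role_cod": "role_cod",
    "outc_cod": "outc_cod",
    "start_dt": "start_dt",
    "event_dt": "event_dt",
    "fda_dt": "fda_dt",
    "age": "age",
    "age_cod": "age_cod",
    "wt": "wt",
    "wt_cod": "wt_cod",
    "occp_cod": "occp_cod",
    "reporter_country": "reporter_country",
    "dsg_drug_seq": "drug_seq",
    "drug_seq": "drug_seq",
}


def _norm_col(name: str) -> str:
    key = name.strip().lower()
    return _COLUMN_ALIASES.get(key, key)


# ---------------------------------------------------------------------------
# dates


@dataclass(frozen=True)
class PartialDate:
    """A FAERS date that may be given to year, month, or day precision.

    Partial dates are imputed to the midpoint of the stated interval (YYYY ->
    July 1, YYYYMM -> the 15th) and flagged ``imprecise`` so interval
    statistics can exclude them.
    """

    date: dt.date
    imprecise: bool = False

    def __str__(self) -> str:  # round-trips through the TSV output
        return self.date.strftime("%Y%m%d") + ("~" if self.imprecise else "")


def parse_faers_date(raw: str | None) -> PartialDate | None:
    """Parse a YYYY, YYYYMM or YYYYMMDD date field; blank/invalid -> None."""
    if raw is None:
        return None
    s = str(raw).strip()
    imprecise = s.endswith("~")  # our own round-trip marker
    s = s.rstrip("~")
    if not s or not s.isdigit():
        return None
    try:
        if len(s) == 4:
            return PartialDate(dt.date(int(s), 7, 1), imprecise=True)
        if len(s) == 6:
            return PartialDate(dt.date(int(s[:4]), int(s[4:6]), 15), imprecise=True)
        if len(s) == 8:
            return PartialDate(
                dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])), imprecise=imprecise
            )
    except ValueError:
        return None
    return None


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class DrugEntry:
    drug_name_raw: str
    role: str  # PS / SS / C / I
    start_dt: PartialDate | None = None


@dataclass
class SafetyReport:
    """One FAERS case version assembled across the seven tables."""

    primaryid: str
    caseid: str
    fda_dt: PartialDate | None = None
    sex: str = "unknown"  # F / M / unknown
    age_years: float | None = None
    weight_kg: float | None = None
    reporter: str = "unknown"  # healthcare_professional / consumer / unknown
    country: str = "unknown"
    event_dt: PartialDate | None = None
    outcomes: frozenset[str] = frozenset()
    drugs: tuple[DrugEntry, ...] = ()
    reactions: tuple[str, ...] = ()
    socs: Mapping[str, str] | None = None  # PT -> SOC once MedDRA is attached

    def report_year(self) -> int | None:
        return self.fda_dt.date.year if self.fda_dt else None


@dataclass
class RawRecordSet:
    table_name: str
    rows: list[dict[str, str]]
    quarter_label: str = ""
    n_malformed: int = 0


@dataclass
class DedupResult:
    reports: list[SafetyReport]
    removed_count: int
    removed_primaryids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parsing


def _read_dollar_file(path: Path, table: str, quarter_label: str) -> RawRecordSet:
    rows: list[dict[str, str]] = []
    n_malformed = 0
    with open(path, "r", encoding="latin-1", newline="") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ValueError(f"{table}: unparseable header in {path}")
        header = [_norm_col(c) for c in header_line.rstrip("\r\n").split("$")]
        if not any(h == "primaryid" for h in header):
            raise ValueError(f"{table}: header of {path} has no PRIMARYID column")
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\r\n").split("$")
            if len(fields) != width:
                if len(fields) == width + 1 and fields[-1] == "":
                    # trailing "$": keep, with the empty final field dropped
                    fields = fields[:width]
                    logger.warning(
                        "%s line %d: trailing delimiter, empty final field kept",
                        table,
                        lineno,
                    )
                elif len(fields) < width:
                    fields = fields + [""] * (width - len(fields))
                    n_malformed += 1
                    logger.warning("%s line %d: short row padded", table, lineno)
                else:
                    fields = fields[:width]
                    n_malformed += 1
                    logger.warning("%s line %d: long row truncated", table, lineno)
            rows.append(dict(zip(header, fields)))
    return RawRecordSet(table, rows, quarter_label, n_malformed)


def parse_quarter(
    paths: Mapping[str, str | Path], quarter_label: str = ""
) -> dict[str, RawRecordSet]:
    """Parse one quarter's "$"-delimited tables into raw record sets.

    ``paths`` maps table names (DEMO, DRUG, ...) to file paths.  DEMO, DRUG and
    REAC are mandatory; the remaining tables are optional and their absence
    simply propagates as unknown fields downstream (e.g. a missing THER table
    yields 100% missing therapy-start dates in the onset analysis).
    """
    normalized = {k.upper(): Path(v) for k, v in paths.items()}
    for table in MANDATORY_TABLES:
        if table not in normalized:
            raise FileNotFoundError(f"mandatory FAERS table missing: {table}")
        if not normalized[table].exists():
            raise FileNotFoundError(
                f"mandatory FAERS table {table}: file not found {normalized[table]}"
            )
    out: dict[str, RawRecordSet] = {}
    for table, path in normalized.items():
        if table not in KNOWN_TABLES:
            logger.warning("ignoring unknown table %s", table)
            continue
        if not path.exists():
            logger.warning("optional table %s missing at %s", table, path)
            continue
        out[table] = _read_dollar_file(path, table, quarter_label)
    return out


# ---------------------------------------------------------------------------
# assembly

_SEX_MAP = {"F": "F", "M": "M"}
_REPORTER_MAP = {
    "MD": "healthcare_professional",
    "PH": "healthcare_professional",
    "HP": "healthcare_professional",
    "OT": "healthcare_professional",
    "RN": "healthcare_professional",
    "CN": "consumer",
    "LW": "consumer",
}

# age-unit codes convertible to years; DEC = decades
_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.18, "DY": 1 / 365.25, "HR": 1 / 8766.0}
_WT_FACTORS = {"KG": 1.0, "KGS": 1.0, "LBS": 0.453592, "LB": 0.453592, "GMS": 0.001}


def _to_float(s: str) -> float | None:
    try:
        v = float(s)
    except (TypeError, ValueError):
        return None
    return v if v >= 0 else None


def _age_years(row: Mapping[str, str]) -> float | None:
    v = _to_float(row.get("age", ""))
    if v is None:
        return None
    factor = _AGE_FACTORS.get(row.get("age_cod", "YR").strip().upper() or "YR")
    return v * factor if factor is not None else None


def _weight_kg(row: Mapping[str, str]) -> float | None:
    v = _to_float(row.get("wt", ""))
    if v is None:
        return None
    factor = _WT_FACTORS.get(row.get("wt_cod", "KG").strip().upper() or "KG")
    return v * factor if factor is not None else None


def assemble_reports(raw: Mapping[str, RawRecordSet]) -> tuple[list[SafetyReport], dict]:
    """Join the per-table rows into one :class:`SafetyReport` per DEMO row.

    Returns the reports and a small stats dict (orphan counts per table —
    DRUG/REAC/... rows whose PRIMARYID has no DEMO row are excluded, counted,
    and logged, never silently dropped).
    """
    demo = raw.get("DEMO")
    if demo is None:
        raise ValueError("DEMO table required to assemble reports")

    drugs_by_id: dict[str, list[DrugEntry]] = {}
    start_by_id_seq: dict[tuple[str, str], PartialDate | None] = {}
    reacs_by_id: dict[str, list[str]] = {}
    outc_by_id: dict[str, set[str]] = {}

    known_ids = {row.get("primaryid", "") for row in demo.rows}
    orphans = {t: 0 for t in KNOWN_TABLES if t != "DEMO"}

    for row in raw.get("THER", RawRecordSet("THER", [])).rows:
        pid = row.get("primaryid", "")
        if pid not in known_ids:
            orphans["THER"] += 1
            continue
        start_by_id_seq[(pid, row.get("drug_seq", ""))] = parse_faers_date(
            row.get("start_dt", "")
        )

    for row in raw.get("DRUG", RawRecordSet("DRUG", [])).rows:
        pid = row.get("primaryid", "")
        if pid not in known_ids:
            orphans["DRUG"] += 1
            continue
        role = row.get("role_cod", "").strip().upper()
        entry = DrugEntry(
            drug_name_raw=row.get("drugname", "").strip(),
            role=role if role in ROLE_CODES else "C",
            start_dt=start_by_id_seq.get((pid, row.get("drug_seq", ""))),
        )
        drugs_by_id.setdefault(pid, []).append(entry)

    for row in raw.get("REAC", RawRecordSet("REAC", [])).rows:
        pid = row.get("primaryid", "")
        if pid not in known_ids:
            orphans["REAC"] += 1
            continue
        pt = row.get("pt", "").strip()
        if pt:
            reacs_by_id.setdefault(pid, []).append(pt)

    for row in raw.get("OUTC", RawRecordSet("OUTC", [])).rows:
        pid = row.get("primaryid", "")
        if pid not in known_ids:
            orphans["OUTC"] += 1
            continue
        code = row.get("outc_cod", "").strip().upper()
        if code in OUTCOME_CODES:
            outc_by_id.setdefault(pid, set()).add(code)

    reports: list[SafetyReport] = []
    for row in demo.rows:
        pid = row.get("primaryid", "")
        reports.append(
            SafetyReport(
                primaryid=pid,
                caseid=row.get("caseid", "") or pid,
                fda_dt=parse_faers_date(row.get("fda_dt", "")),
                sex=_SEX_MAP.get(row.get("sex", "").strip().upper(), "unknown"),
                age_years=_age_years(row),
                weight_kg=_weight_kg(row),
                reporter=_REPORTER_MAP.get(
                    row.get("occp_cod", "").strip().upper(), "unknown"
                ),
                country=(row.get("reporter_country", "").strip() or "unknown"),
                event_dt=parse_faers_date(row.get("event_dt", "")),
                outcomes=frozenset(outc_by_id.get(pid, set())),
                drugs=tuple(drugs_by_id.get(pid, [])),
                reactions=tuple(dict.fromkeys(reacs_by_id.get(pid, []))),
            )
        )
    stats = {"orphans": orphans, "n_reports": len(reports)}
    for t, n in orphans.items():
        if n:
            logger.warning("%d orphan %s rows excluded (PRIMARYID not in DEMO)", n, t)
    return reports, stats


# ---------------------------------------------------------------------------
# deduplication


def _primaryid_key(pid: str):
    # numeric comparison when possible, lexicographic fallback keeps the order total
    try:
        return (1, int(pid), "")
    except ValueError:
        return (0, 0, pid)


def _dedup_sort_key(r: SafetyReport):
    # unknown FDA_DT sorts earliest so any dated version of the case wins
    date = r.fda_dt.date if r.fda_dt else dt.date.min
    return (date, _primaryid_key(r.primaryid))


def deduplicate(reports: Sequence[SafetyReport]) -> DedupResult:
    """Keep one report per CASEID: latest FDA_DT, ties to the higher PRIMARYID."""
    best: dict[str, SafetyReport] = {}
    for r in reports:
        cur = best.get(r.caseid)
        if cur is None or _dedup_sort_key(r) > _dedup_sort_key(cur):
            best[r.caseid] = r
    kept_ids = {r.primaryid for r in best.values()}
    removed = [r.primaryid for r in reports if r.primaryid not in kept_ids]
    kept = sorted(best.values(), key=lambda r: _primaryid_key(r.primaryid))
    return DedupResult(kept, len(reports) - len(kept), removed)


# ---------------------------------------------------------------------------
# round-trip serialization of a deduplicated set


def write_reports(reports: Iterable[SafetyReport], out_dir: str | Path, manifest: dict | None = None) -> None:
    """Write a report collection as one TSV per logical table plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _d(x: PartialDate | None) -> str:
        return str(x) if x else ""

    with open(out / "reports.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["primaryid", "caseid", "fda_dt", "sex", "age_years", "weight_kg",
             "reporter", "country", "event_dt", "outcomes"]
        )
        for r in reports:
            w.writerow(
                [r.primaryid, r.caseid, _d(r.fda_dt), r.sex,
                 "" if r.age_years is None else repr(r.age_years),
                 "" if r.weight_kg is None else repr(r.weight_kg),
                 r.reporter, r.country, _d(r.event_dt),
                 ",".join(sorted(r.outcomes))]
            )
    with open(out / "drugs.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["primaryid", "drug_name_raw", "role", "start_dt"])
        for r in reports:
            for d in r.drugs:
                w.writerow([r.primaryid, d.drug_name_raw, d.role, _d(d.start_dt)])
    with open(out / "reactions.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["primaryid", "pt"])
        for r in reports:
            for pt in r.reactions:
                w.writerow([r.primaryid, pt])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest or {}, fh, indent=2, sort_keys=True)


def read_reports(in_dir: str | Path) -> list[SafetyReport]:
    """Inverse of :func:`write_reports`."""
    out = Path(in_dir)
    drugs: dict[str, list[DrugEntry]] = {}
    with open(out / "drugs.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            drugs.setdefault(row["primaryid"], []).append(
                DrugEntry(row["drug_name_raw"], row["role"], parse_faers_date(row["start_dt"]))
            )
    reacs: dict[str, list[str]] = {}
    with open(out / "reactions.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            reacs.setdefault(row["primaryid"], []).append(row["pt"])
    reports = []
    with open(out / "reports.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pid = row["primaryid"]
            reports.append(
                SafetyReport(
                    primaryid=pid,
                    caseid=row["caseid"],
                    fda_dt=parse_faers_date(row["fda_dt"]),
                    sex=row["sex"],
                    age_years=float(row["age_years"]) if row["age_years"] else None,
                    weight_kg=float(row["weight_kg"]) if row["weight_kg"] else None,
                    reporter=row["reporter"],
                    country=row["country"],
                    event_dt=parse_faers_date(row["event_dt"]),
                    outcomes=frozenset(x for x in row["outcomes"].split(",") if x),
                    drugs=tuple(drugs.get(pid, [])),
                    reactions=tuple(reacs.get(pid, [])),
                )
            )
    return reports
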