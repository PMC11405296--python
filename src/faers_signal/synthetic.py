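"""Synthetic FAERS-like data with known ground truth.

The generator emits quarterly-style "$"-delimited DEMO/DRUG/REAC/OUTC/THER
tables (the same dialect :mod:`faers_signal.faers_io` parses) from an explicit
generative model, so every pipeline stage can be exercised against closed-form
expectations:

* each report carries one suspect drug — a target product with a configured
  share of reports, otherwise a uniformly chosen background drug;
* background reactions are ``max(1, Poisson(lambda))`` distinct PTs drawn
  uniformly from the background vocabulary, so any particular background PT
  appears on a report with probability p0 = (lambda + exp(-lambda)) / n_pts;
* an implanted (drug, PT) signal adds its PT to eligible target-drug reports
  with probability ``relative_reporting_rate * p0`` (other reports carry it at
  the base rate p0), optionally restricted to a demographic stratum, so the
  expected reporting odds ratio is available in closed form;
* onset dates follow a Weibull time-to-onset: event date = therapy start plus
  a draw from the implant's (shape, scale) when the report carries an
  implanted PT, else from the background early-onset default;
* a configured fraction of cases is emitted twice with the same CASEID but a
  perturbed FDA_DT / higher PRIMARYID, giving the deduplication rule known
  duplicate chains to resolve.

Demographic marginals default to the profile typical of CAR-T case series
(predominantly male, mostly 65+ or 18-64, largely US, ~10% fatal outcome).
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .faers_io import RawRecordSet, SafetyReport, assemble_reports

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TargetDrugSpec:
    name: str
    share: float  # fraction of reports naming this drug as the suspect


@dataclass(frozen=True)
class ImplantSpec:
    """One engineered drug-event association."""

    drug: str
    pt: str
    relative_reporting_rate: float  # >= 1; 1 is indistinguishable from null
    stratum: Mapping[str, str] | None = None  # e.g. {"sex": "F"}, {"outcome": "DE"}
    tto_shape: float | None = None  # Weibull shape for this event's onset
    tto_scale: float | None = None  # Weibull scale, days


#: categorical marginals emulating a CAR-T case-series Table 1 profile
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"F": 0.373, "M": 0.524, "unknown": 0.103},
    "age_band": {"<18": 0.0, "18-64": 0.343, ">=65": 0.468, "unknown": 0.189},
    "weight_band": {"<50": 0.015, "50-100": 0.565, ">100": 0.074, "unknown": 0.346},
    "reporter": {"healthcare_professional": 0.713, "consumer": 0.124, "unknown": 0.163},
    "country": {"US": 0.784, "other": 0.215, "unknown": 0.001},
    "outcome": {"DE": 0.105, "LT": 0.061, "HO": 0.280, "DS": 0.001, "OT": 0.371, "none": 0.182},
}

_IMPLANT_SOC = {
    "cytokine release syndrome": "Immune system disorders",
    "immune effector cell-associated neurotoxicity syndrome": "Nervous system disorders",
    "neurotoxicity": "Nervous system disorders",
    "febrile bone marrow aplasia": "Blood and lymphatic system disorders",
    "myelodysplastic syndrome": "Neoplasms benign, malignant and unspecified",
    "t-cell lymphoma": "Neoplasms benign, malignant and unspecified",
    "plasma cell myeloma": "Neoplasms benign, malignant and unspecified",
}


def default_implants() -> list[ImplantSpec]:
    """Hallmark CAR-T toxicity signals plus one late secondary malignancy each."""
    return [
        ImplantSpec("ABECMA", "Cytokine release syndrome", 50.0, tto_shape=0.43, tto_scale=12.67),
        ImplantSpec("ABECMA", "Immune effector cell-associated neurotoxicity syndrome", 30.0, tto_shape=0.43, tto_scale=12.67),
        ImplantSpec("ABECMA", "Myelodysplastic syndrome", 8.0, tto_shape=2.0, tto_scale=400.0),
        ImplantSpec("CARVYKTI", "Cytokine release syndrome", 40.0, tto_shape=0.61, tto_scale=74.08),
        ImplantSpec("CARVYKTI", "Neurotoxicity", 25.0, tto_shape=0.61, tto_scale=74.08),
        ImplantSpec("CARVYKTI", "T-cell lymphoma", 8.0, tto_shape=2.0, tto_scale=400.0),
    ]


@dataclass
class SimulationConfig:
    n_reports: int = 5000
    n_background_drugs: int = 50
    n_background_pts: int = 200
    target_drugs: tuple[TargetDrugSpec, ...] = (
        TargetDrugSpec("ABECMA", 0.05),
        TargetDrugSpec("CARVYKTI", 0.05),
    )
    implants: tuple[ImplantSpec, ...] = field(default_factory=lambda: tuple(default_implants()))
    duplicate_fraction: float = 0.1
    mean_pts_per_report: float = 1.7  # Poisson mean before the min-1 floor
    demographics: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}
    )
    date_start: dt.date = dt.date(2019, 1, 1)
    date_end: dt.date = dt.date(2023, 12, 31)
    background_tto_shape: float = 0.43
    background_tto_scale: float = 12.67
    missing_event_dt_fraction: float = 0.05
    missing_start_dt_fraction: float = 0.05
    seed: int = 0

    # -- derived quantities of the generative model -------------------------

    @property
    def expected_pts_per_report(self) -> float:
        lam = self.mean_pts_per_report
        return lam + math.exp(-lam)

    @property
    def base_pt_prob(self) -> float:
        """p0: probability a given PT appears on an arbitrary report."""
        return self.expected_pts_per_report / self.n_background_pts

    def drug_share(self, drug: str) -> float:
        for t in self.target_drugs:
            if t.name == drug:
                return t.share
        bg = 1.0 - sum(t.share for t in self.target_drugs)
        return bg / self.n_background_drugs

    def stratum_prob(self, stratum: Mapping[str, str] | None) -> float:
        if not stratum:
            return 1.0
        p = 1.0
        for key, value in stratum.items():
            table = self.demographics[key if key != "outcome" else "outcome"]
            p *= table[value]
        return p

    def validate(self) -> None:
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        total_share = sum(t.share for t in self.target_drugs)
        if total_share >= 1:
            raise ValueError("target drug shares must sum to < 1")
        for name, table in self.demographics.items():
            if abs(sum(table.values()) - 1.0) > 1e-9:
                raise ValueError(f"demographics table {name!r} must sum to 1")
        drugs = {t.name for t in self.target_drugs}
        for imp in self.implants:
            if imp.drug not in drugs:
                raise ValueError(f"implant on unknown target drug {imp.drug!r}")
            if imp.relative_reporting_rate < 1:
                raise ValueError("relative_reporting_rate must be >= 1")
            if imp.relative_reporting_rate * self.base_pt_prob > 1:
                raise ValueError(
                    f"infeasible implant {imp.drug}/{imp.pt}: "
                    f"rate x base probability exceeds 1"
                )


# ---------------------------------------------------------------------------
# expected contingency (the calibration oracle)


@dataclass(frozen=True)
class ExpectedTable:
    a: float
    b: float
    c: float
    d: float

    @property
    def ror(self) -> float:
        return (self.a * self.d) / (self.b * self.c)


def _implant_lookup(config: SimulationConfig) -> dict[tuple[str, str], ImplantSpec]:
    return {(i.drug, i.pt): i for i in config.implants}


def _pt_prob_for_drug(config: SimulationConfig, drug: str, pt: str) -> float:
    """P(report mentions pt | report's suspect drug is drug) under the model."""
    p0 = config.base_pt_prob
    imp = _implant_lookup(config).get((drug, pt))
    if imp is None:
        return p0
    q = config.stratum_prob(imp.stratum)
    boosted = min(1.0, imp.relative_reporting_rate * p0)
    return q * boosted + (1 - q) * p0


def expected_contingency(config: SimulationConfig, drug: str, pt: str) -> ExpectedTable:
    """Closed-form expected (a, b, c, d) implied by the generative model."""
    known_pts = {i.pt for i in config.implants} | {
        f"BG_PT_{i:04d}" for i in range(config.n_background_pts)
    }
    known_drugs = {t.name for t in config.target_drugs} | {
        f"BG_DRUG_{i:03d}" for i in range(config.n_background_drugs)
    }
    if pt not in known_pts:
        raise ValueError(f"unknown PT {pt!r}")
    if drug not in known_drugs:
        raise ValueError(f"unknown drug {drug!r}")
    n = config.n_reports
    n_d = n * config.drug_share(drug)
    a = n_d * _pt_prob_for_drug(config, drug, pt)
    # other reports: split across the remaining target drugs and background
    c = 0.0
    n_other = 0.0
    for t in config.target_drugs:
        if t.name == drug:
            continue
        c += n * t.share * _pt_prob_for_drug(config, t.name, pt)
        n_other += n * t.share
    n_bg = n * (1.0 - sum(t.share for t in config.target_drugs))
    if drug.startswith("BG_DRUG_"):
        n_bg -= n_d
    c += n_bg * config.base_pt_prob
    n_other += n_bg
    return ExpectedTable(a, n_d - a, c, n_other - c)


# ---------------------------------------------------------------------------
# simulation


def _draw_categorical(rng, table: Mapping[str, float], size: int) -> np.ndarray:
    cats = list(table)
    probs = np.array([table[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    return np.array(cats, dtype=object)[rng.choice(len(cats), size=size, p=probs)]


def _fmt_date(d: dt.date) -> str:
    return d.strftime("%Y%m%d")


@dataclass
class SimulatedQuarter:
    """In-memory simulation output: raw tables, manifest, and the mini PT map."""

    tables: dict[str, RawRecordSet]
    manifest: dict
    pt_to_soc: dict[str, str]

    def assemble(self) -> list[SafetyReport]:
        reports, _ = assemble_reports(self.tables)
        return reports


def simulate(config: SimulationConfig, seed: int | None = None) -> SimulatedQuarter:
    """Run the generative model; deterministic for a fixed config and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_reports
    p0 = config.base_pt_prob

    # --- suspect drug per report
    drug_names = [t.name for t in config.target_drugs]
    shares = [t.share for t in config.target_drugs]
    bg_share = 1.0 - sum(shares)
    choice = rng.choice(len(drug_names) + 1, size=n, p=shares + [bg_share])
    bg_idx = rng.integers(0, config.n_background_drugs, size=n)
    drugs = np.array(
        [drug_names[c] if c < len(drug_names) else f"BG_DRUG_{bg_idx[i]:03d}"
         for i, c in enumerate(choice)], dtype=object)

    # --- demographics
    demo = {k: _draw_categorical(rng, v, n) for k, v in config.demographics.items()}
    age = np.where(
        demo["age_band"] == "18-64", rng.integers(18, 65, size=n),
        np.where(demo["age_band"] == ">=65", rng.integers(65, 91, size=n),
                 rng.integers(1, 18, size=n)))
    weight = np.where(
        demo["weight_band"] == "<50", rng.uniform(30, 50, size=n),
        np.where(demo["weight_band"] == "50-100", rng.uniform(50, 100, size=n),
                 rng.uniform(101, 150, size=n)))

    # --- background reactions: k distinct PTs uniform over the vocabulary
    k = np.maximum(1, rng.poisson(config.mean_pts_per_report, size=n))
    k = np.minimum(k, config.n_background_pts)
    scores = rng.random((n, config.n_background_pts))
    order = np.argsort(scores, axis=1)
    reactions: list[list[str]] = [
        [f"BG_PT_{j:04d}" for j in order[i, : k[i]]] for i in range(n)
    ]

    # --- implanted and base-rate occurrences of the special PTs
    implant_pts = sorted({i.pt for i in config.implants})
    lookup = _implant_lookup(config)

    def in_stratum(i: int, stratum: Mapping[str, str] | None) -> bool:
        if not stratum:
            return True
        for key, value in stratum.items():
            if demo[key][i] != value:
                return False
        return True

    u = rng.random((n, len(implant_pts)))
    implant_hit: list[dict[str, ImplantSpec]] = [dict() for _ in range(n)]
    for j, pt in enumerate(implant_pts):
        for i in range(n):
            imp = lookup.get((drugs[i], pt))
            if imp is not None and in_stratum(i, imp.stratum):
                p = min(1.0, imp.relative_reporting_rate * p0)
            else:
                imp = None
                p = p0
            if u[i, j] < p:
                reactions[i].append(pt)
                if imp is not None:
                    implant_hit[i][pt] = imp

    # --- dates: therapy start uniform in window, onset Weibull, receipt lagged
    window_days = (config.date_end - config.date_start).days
    start_offsets = rng.integers(0, window_days + 1, size=n)
    tto = rng.weibull(config.background_tto_shape, size=n) * config.background_tto_scale
    for i in range(n):
        if implant_hit[i]:
            imp = next(iter(implant_hit[i].values()))
            if imp.tto_shape is not None and imp.tto_scale is not None:
                tto[i] = rng.weibull(imp.tto_shape) * imp.tto_scale
    tto_days = np.floor(tto).astype(int)
    delay = rng.integers(1, 91, size=n)
    miss_event = rng.random(n) < config.missing_event_dt_fraction
    miss_start = rng.random(n) < config.missing_start_dt_fraction

    # --- assemble table rows
    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows = [], [], [], [], []
    base_pid = 1_000_000
    caseids, fda_dts = [], []
    reporter_code = {"healthcare_professional": "MD", "consumer": "CN", "unknown": ""}
    for i in range(n):
        pid = str(base_pid + i)
        caseid = str(2_000_000 + i)
        caseids.append(caseid)
        start = config.date_start + dt.timedelta(days=int(start_offsets[i]))
        event = start + dt.timedelta(days=int(tto_days[i]))
        fda = event + dt.timedelta(days=int(delay[i]))
        fda_dts.append(fda)
        demo_rows.append({
            "primaryid": pid, "caseid": caseid, "fda_dt": _fmt_date(fda),
            "event_dt": "" if miss_event[i] else _fmt_date(event),
            "sex": demo["sex"][i] if demo["sex"][i] in ("F", "M") else "",
            "age": "" if demo["age_band"][i] == "unknown" else str(int(age[i])),
            "age_cod": "" if demo["age_band"][i] == "unknown" else "YR",
            "wt": "" if demo["weight_band"][i] == "unknown" else f"{weight[i]:.1f}",
            "wt_cod": "" if demo["weight_band"][i] == "unknown" else "KG",
            "occp_cod": reporter_code[demo["reporter"][i]],
            "reporter_country": {"US": "US", "other": "DE", "unknown": ""}[demo["country"][i]],
        })
        role = "PS" if rng.random() < 0.85 else "SS"
        drug_rows.append({"primaryid": pid, "caseid": caseid, "drug_seq": "1",
                          "role_cod": role, "drugname": drugs[i]})
        for pt in reactions[i]:
            reac_rows.append({"primaryid": pid, "caseid": caseid, "pt": pt})
        if demo["outcome"][i] != "none":
            outc_rows.append({"primaryid": pid, "caseid": caseid,
                              "outc_cod": demo["outcome"][i]})
        if not miss_start[i]:
            ther_rows.append({"primaryid": pid, "caseid": caseid, "drug_seq": "1",
                              "start_dt": _fmt_date(start)})

    # --- duplicate chains: re-emit a fraction of cases as older/newer versions
    n_dup = int(round(config.duplicate_fraction * n))
    dup_indices = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    dup_shift = rng.integers(-30, 31, size=n_dup)
    chains: dict[str, dict] = {}
    next_pid = base_pid + n
    all_tables = (demo_rows, drug_rows, reac_rows, outc_rows, ther_rows)
    by_pid = [
        {} for _ in all_tables
    ]
    for rows, idx in zip(all_tables, by_pid):
        for row in rows:
            idx.setdefault(row["primaryid"], []).append(row)
    for j, i in enumerate(sorted(dup_indices)):
        orig_pid = str(base_pid + i)
        dup_pid = str(next_pid)
        next_pid += 1
        dup_fda = fda_dts[i] + dt.timedelta(days=int(dup_shift[j]))
        for rows, idx in zip(all_tables, by_pid):
            for row in idx.get(orig_pid, []):
                dup = dict(row)
                dup["primaryid"] = dup_pid
                if "fda_dt" in dup:
                    dup["fda_dt"] = _fmt_date(dup_fda)
                rows.append(dup)
        # the dedup rule: latest FDA_DT wins, ties to the higher PRIMARYID
        if dup_fda > fda_dts[i] or (dup_fda == fda_dts[i]):
            keep = dup_pid
        else:
            keep = orig_pid
        chains[caseids[i]] = {"primaryids": [orig_pid, dup_pid], "keep": keep}

    tables = {
        "DEMO": RawRecordSet("DEMO", demo_rows, "SYN"),
        "DRUG": RawRecordSet("DRUG", drug_rows, "SYN"),
        "REAC": RawRecordSet("REAC", reac_rows, "SYN"),
        "OUTC": RawRecordSet("OUTC", outc_rows, "SYN"),
        "THER": RawRecordSet("THER", ther_rows, "SYN"),
    }

    # --- mini PT -> SOC map (self-consistent stand-in for the licensed MedDRA)
    socs = [
        "Infections and infestations", "Blood and lymphatic system disorders",
        "Nervous system disorders", "Gastrointestinal disorders",
        "Cardiac disorders", "Immune system disorders",
        "Renal and urinary disorders", "Respiratory disorders",
        "Investigations", "General disorders",
    ]
    pt_to_soc = {f"BG_PT_{i:04d}": socs[i % len(socs)]
                 for i in range(config.n_background_pts)}
    for pt in implant_pts:
        pt_to_soc[pt] = _IMPLANT_SOC.get(pt.lower(), "Immune system disorders")

    manifest = {
        "seed": config.seed if seed is None else seed,
        "n_reports": n,
        "n_duplicates": n_dup,
        "duplicate_chains": chains,
        "base_pt_prob": p0,
        "implants": [
            {
                "drug": imp.drug,
                "pt": imp.pt,
                "relative_reporting_rate": imp.relative_reporting_rate,
                "stratum": dict(imp.stratum) if imp.stratum else None,
                "tto_shape": imp.tto_shape,
                "tto_scale": imp.tto_scale,
                "expected_a": expected_contingency(config, imp.drug, imp.pt).a,
                "expected_ror": expected_contingency(config, imp.drug, imp.pt).ror,
            }
            for imp in config.implants
        ],
    }
    return SimulatedQuarter(tables, manifest, pt_to_soc)


# ---------------------------------------------------------------------------
# file output


_TABLE_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age", "age_cod",
             "wt", "wt_cod", "occp_cod", "reporter_country"],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "drug_seq", "start_dt"],
}

_HEADER_NAMES = {"drug_seq": "DSG_DRUG_SEQ"}  # THER's historical column name


def write_quarter(sim: SimulatedQuarter, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated tables in the FAERS "$"-delimited dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for table, rec in sim.tables.items():
        cols = _TABLE_COLUMNS[table]
        path = out / f"{table}.txt"
        with open(path, "w", newline="") as fh:
            header = [
                _HEADER_NAMES[c].upper() if table == "THER" and c in _HEADER_NAMES
                else c.upper()
                for c in cols
            ]
            fh.write("$".join(header) + "\n")
            for row in rec.rows:
                fh.write("$".join(row.get(c, "") for c in cols) + "\n")
        paths[table] = path
    with open(out / "manifest.json", "w") as fh:
        json.dump(sim.manifest, fh, indent=2, sort_keys=True)
    with open(out / "pt_to_soc.tsv", "w") as fh:
        fh.write("pt\tsoc\n")
        for pt, soc in sorted(sim.pt_to_soc.items()):
            fh.write(f"{pt}\t{soc}\n")
    return paths
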