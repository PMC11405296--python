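"""End-to-end orchestration: raw (or simulated) quarters to the report bundle.

The bundle mirrors the artifact set of a published FAERS case-series safety
analysis: deduplication manifest, Table-1-style demographics, SOC- and
PT-level disproportionality tables with top-k ranking and unexpected-signal
flags, subgroup and sex-difference tables, the death-outcome subset, the
secondary-malignancy IC screen, and time-to-onset summaries with Weibull fits.
Every table carries the config hash and package version in a header comment,
and identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .cohort import (
    DEFAULT_DRUG_QUERIES,
    DrugQuery,
    MedDRAMap,
    attach_meddra,
    select_cohort,
    summarize_demographics,
)
from .faers_io import deduplicate, parse_quarter, assemble_reports
from .signal_stats import (
    SignalCriteria,
    flag_unexpected,
    rank_top,
    results_to_rows,
    screen,
)
from .special_analyses import (
    MalignancyTermSet,
    death_outcome_signals,
    malignancy_screen,
    sex_difference_table,
    subgroup_signals,
)
from .synthetic import SimulationConfig, simulate
from .tto_weibull import compute_tto, onset_window_summary, per_report_days, weibull_mle

logger = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "data"


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialized into the bundle for provenance."""

    output_dir: str = "faers_signal_out"
    input_dirs: tuple[str, ...] = ()  # quarters of FAERS ASCII files
    synthetic: bool = True  # generate input instead of reading quarters
    synthetic_config: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    meddra_map: str | None = None  # TSV pt/soc; synthetic runs use the mini map
    drug_queries: tuple[DrugQuery, ...] = DEFAULT_DRUG_QUERIES
    label_terms: Mapping[str, tuple[str, ...]] | None = None  # per drug label PTs
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    run_subgroups: bool = True
    run_sex_difference: bool = True
    run_death: bool = True
    run_malignancy: bool = True
    malignancy_terms: str | None = None  # TSV group/pt; default: shipped seed file
    tto_zero_handling: str = "shift"
    top_k: int = 20

    def config_hash(self) -> str:
        def _ser(obj: Any):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                # output_dir is where the bundle lands, not what it computes
                return {f.name: _ser(getattr(obj, f.name))
                        for f in dataclasses.fields(obj) if f.name != "output_dir"}
            if isinstance(obj, (tuple, list, set, frozenset)):
                return sorted(map(_ser, obj)) if isinstance(obj, (set, frozenset)) else [
                    _ser(x) for x in obj
                ]
            if isinstance(obj, Mapping):
                return {str(k): _ser(v) for k, v in obj.items()}
            return str(obj)

        blob = json.dumps(_ser(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key in ("output_dir", "seed", "meddra_map", "run_subgroups", "synthetic",
                    "run_sex_difference", "run_death", "run_malignancy",
                    "malignancy_terms", "tto_zero_handling", "top_k"):
            if key in raw:
                kwargs[key] = raw[key]
        if "input_dirs" in raw:
            kwargs["input_dirs"] = tuple(raw["input_dirs"])
            kwargs.setdefault("synthetic", False)
        if "synthetic_config" in raw:
            kwargs["synthetic_config"] = SimulationConfig(**raw["synthetic_config"])
        if "drug_queries" in raw:
            kwargs["drug_queries"] = tuple(
                DrugQuery(q["label"], tuple(q["name_patterns"]),
                          frozenset(q.get("roles_included", ("PS", "SS"))))
                for q in raw["drug_queries"]
            )
        if "criteria" in raw:
            kwargs["criteria"] = SignalCriteria(**raw["criteria"])
        if "label_terms" in raw:
            kwargs["label_terms"] = {k: tuple(v) for k, v in raw["label_terms"].items()}
        return cls(**kwargs)


def load_default_label_terms(drug_label: str) -> tuple[str, ...]:
    """Labelled-event PT list shipped for the two anti-BCMA products."""
    path = _DATA_DIR / f"label_terms_{drug_label}.tsv"
    if not path.exists():
        return ()
    with open(path) as fh:
        return tuple(line.strip() for line in fh.readlines()[1:] if line.strip())


class _TsvWriter:
    """TSV writer stamping provenance (# version / config hash) on every table."""

    def __init__(self, out_dir: Path, config_hash: str):
        self.out_dir = out_dir
        self.header = f"# faers-signal {__version__} config={config_hash}"

    def write(self, name: str, rows: Sequence[Mapping[str, Any]], columns: Sequence[str]) -> Path:
        path = self.out_dir / name
        with open(path, "w", newline="") as fh:
            fh.write(self.header + "\n")
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(columns)
            for row in rows:
                w.writerow([("" if row.get(c) is None else row.get(c, "")) for c in columns])
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the machine-readable run summary.

    A stage failure marks the bundle partial (per-stage status in the summary)
    instead of aborting the run.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    tsv = _TsvWriter(out_dir, chash)
    status: dict[str, str] = {}
    summary: dict[str, Any] = {
        "version": __version__, "config_hash": chash, "seed": config.seed,
        "stages": status,
    }
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    # --- stage: input
    if config.synthetic:
        sim = simulate(config.synthetic_config, seed=config.seed)
        reports, _ = assemble_reports(sim.tables)
        meddra = MedDRAMap(dict(sim.pt_to_soc))
        with open(out_dir / "simulation_manifest.json", "w") as fh:
            json.dump(sim.manifest, fh, indent=2, sort_keys=True)
        log(f"simulated {len(reports)} report versions (seed {config.seed})")
    else:
        reports = []
        for qdir in config.input_dirs:
            qpath = Path(qdir)
            paths = {p.stem.upper().rstrip("0123456789Q_"): p
                     for p in sorted(qpath.glob("*.txt"))}
            raw = parse_quarter(paths, quarter_label=qpath.name)
            qreports, stats = assemble_reports(raw)
            reports.extend(qreports)
            log(f"{qpath.name}: {len(qreports)} reports, orphans {stats['orphans']}")
        meddra = MedDRAMap.from_tsv(config.meddra_map) if config.meddra_map else MedDRAMap({"_": "_"})
    status["input"] = "ok"

    # --- stage: dedup (quarters pooled first; duplicates cross quarters)
    dedup = deduplicate(reports)
    universe, _ = attach_meddra(dedup.reports, meddra)
    with open(out_dir / "dedup_manifest.json", "w") as fh:
        json.dump({"n_in": len(reports), "n_out": len(dedup.reports),
                   "removed_count": dedup.removed_count,
                   "removed_primaryids": dedup.removed_primaryids}, fh, indent=2)
    log(f"dedup: {len(reports)} -> {len(dedup.reports)} ({dedup.removed_count} removed)")
    status["dedup"] = "ok"
    summary["n_reports_raw"] = len(reports)
    summary["n_reports_dedup"] = len(dedup.reports)

    mal_terms_path = config.malignancy_terms or str(_DATA_DIR / "malignancy_groups.tsv")
    sig_cols = ["level", "stratum", "event", "n", "ror", "ror_ci_low", "ror_ci_high",
                "ic", "ic025", "ror_signal", "ic_signal", "unexpected",
                "ror_undefined_reason"]

    summary["drugs"] = {}
    for query in config.drug_queries:
        dsum: dict[str, Any] = {}
        summary["drugs"][query.label] = dsum
        cohort = select_cohort(universe, query)
        dsum["n_cohort"] = len(cohort)
        log(f"{query.label}: cohort of {len(cohort)} reports")
        if not cohort:
            status[f"{query.label}"] = "empty cohort"
            continue
        prefix = query.label.replace("/", "_")

        try:
            demo = summarize_demographics(cohort)
            demo.to_tsv(out_dir / f"{prefix}__demographics.tsv")
            dsum["death_reports"] = demo.blocks["outcome"]["Death"][0]
            status[f"{prefix}:demographics"] = "ok"
        except Exception as exc:  # pragma: no cover - defensive
            status[f"{prefix}:demographics"] = f"error: {exc}"

        label_terms = (config.label_terms or {}).get(query.label)
        if label_terms is None:
            label_terms = load_default_label_terms(query.label)

        for level in ("PT", "SOC"):
            try:
                results = screen(universe, cohort, level=level, criteria=config.criteria)
                results = flag_unexpected(results, label_terms)
                tsv.write(f"{prefix}__{level.lower()}_signals.tsv",
                          results_to_rows(results), sig_cols)
                n_sig = sum(1 for r in results if r.ror_signal or r.ic_signal)
                dsum[f"n_{level.lower()}_signals"] = n_sig
                log(f"{query.label} {level}: {len(results)} events, {n_sig} signals")
                if level == "PT":
                    top = rank_top(results, config.top_k)
                    tsv.write(f"{prefix}__top{config.top_k}.tsv",
                              results_to_rows(top), sig_cols)
                    unexpected = [r for r in results if r.unexpected]
                    tsv.write(f"{prefix}__unexpected.tsv",
                              results_to_rows(unexpected), sig_cols)
                    dsum["n_unexpected"] = len(unexpected)
                status[f"{prefix}:{level}"] = "ok"
            except Exception as exc:
                status[f"{prefix}:{level}"] = f"error: {exc}"

        if config.run_subgroups:
            try:
                per_stratum = subgroup_signals(universe, cohort, criteria=config.criteria)
                for name, results in per_stratum.items():
                    tsv.write(f"{prefix}__{name}__signals.tsv",
                              results_to_rows(results), sig_cols)
                status[f"{prefix}:subgroups"] = "ok"
            except Exception as exc:
                status[f"{prefix}:subgroups"] = f"error: {exc}"
        else:
            status[f"{prefix}:subgroups"] = "skipped"

        if config.run_sex_difference:
            try:
                rows = sex_difference_table(cohort, min_cases=config.criteria.min_cases)
                tsv.write(f"{prefix}__sex_difference.tsv", rows,
                          ["event", "n", "ror_f_vs_m", "ci_low", "ci_high",
                           "undefined_reason"])
                status[f"{prefix}:sex_difference"] = "ok"
            except Exception as exc:
                status[f"{prefix}:sex_difference"] = f"error: {exc}"
        else:
            status[f"{prefix}:sex_difference"] = "skipped"

        if config.run_death:
            try:
                results, death_demo = death_outcome_signals(
                    universe, cohort, criteria=config.criteria)
                tsv.write(f"{prefix}__death_signals.tsv",
                          results_to_rows(results), sig_cols)
                if death_demo is not None:
                    death_demo.to_tsv(out_dir / f"{prefix}__death_demographics.tsv")
                status[f"{prefix}:death"] = "ok"
            except Exception as exc:
                status[f"{prefix}:death"] = f"error: {exc}"
        else:
            status[f"{prefix}:death"] = "skipped"

        if config.run_malignancy:
            try:
                terms = MalignancyTermSet.from_tsv(mal_terms_path)
                rows = malignancy_screen(universe, cohort, terms, drug_query=query)
                tsv.write(f"{prefix}__malignancy_screen.tsv", rows,
                          ["group", "n", "ic", "ic025", "ic_signal",
                           "tto_n", "tto_mean", "tto_median"])
                status[f"{prefix}:malignancy"] = "ok"
            except Exception as exc:
                status[f"{prefix}:malignancy"] = f"error: {exc}"
        else:
            status[f"{prefix}:malignancy"] = "skipped"

        try:
            ttos = compute_tto(cohort, query)
            tsv.write(f"{prefix}__tto.tsv",
                      [{"report_id": t.report_id, "event": t.event,
                        "tto_days": t.tto_days, "validity": t.validity} for t in ttos],
                      ["report_id", "event", "tto_days", "validity"])
            report_days = per_report_days(ttos)
            window = onset_window_summary(report_days)
            window["validity_counts"] = {
                v: sum(1 for t in ttos if t.validity == v)
                for v in ("valid", "negative", "missing_start", "missing_event",
                          "imprecise_date")}
            fit = weibull_mle(report_days, zero_handling=config.tto_zero_handling)
            dsum["tto"] = window
            dsum["weibull"] = {
                "n_used": fit.n_used, "alpha": fit.alpha, "alpha_ci": fit.alpha_ci,
                "beta": fit.beta, "beta_ci": fit.beta_ci,
                "failure_type": fit.failure_type, "log_likelihood": fit.log_likelihood,
                "converged": fit.converged, "message": fit.message,
            }
            with open(out_dir / f"{prefix}__tto_summary.json", "w") as fh:
                json.dump({"onset_window": window, "weibull": dsum["weibull"]},
                          fh, indent=2)
            # per-SOC onset table (box-plot-ready)
            soc_rows = []
            soc_by_report = {r.primaryid: (r.socs or {}) for r in cohort}
            for t in ttos:
                if t.validity == "valid":
                    soc = soc_by_report.get(t.report_id, {}).get(t.event)
                    if soc:
                        soc_rows.append({"soc": soc, "event": t.event,
                                         "tto_days": t.tto_days})
            tsv.write(f"{prefix}__tto_by_soc.tsv", soc_rows,
                      ["soc", "event", "tto_days"])
            status[f"{prefix}:tto"] = "ok"
        except Exception as exc:
            status[f"{prefix}:tto"] = f"error: {exc}"

    summary["partial"] = any(v.startswith("error") for v in status.values())
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary
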