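"""End-to-end analysis orchestration from a config file.

Stage order is fixed: p-value selection -> LD clumping -> confounder
screening -> harmonization -> estimation -> diagnostics.  Every threshold
is a config default, never hard-coded in a stage, and all stochastic steps
take explicit seeds so a run is reproducible byte-for-byte (timestamps are
quarantined in the ``runtime`` block).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import platform
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .diagnostics import (
    cochran_q,
    funnel_and_forest_data,
    leave_one_out,
    mr_presso,
)
from .estimators import egger, ivw, weighted_median
from .gwas_io import FIXTURE_NAMES, SummaryStatRecord, load_fixture, read_summary_stats
from .harmonize import HarmonizedSet, harmonize
from .instruments import (
    InstrumentSet,
    LDTable,
    clump,
    instrument_strength,
    read_annotations,
    screen_confounders,
    select_instruments,
    strength_summary,
)

__all__ = ["AnalysisConfig", "PipelineError", "run_analysis", "validate_report"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and provenance so far."""

    def __init__(self, stage: str, message: str, provenance: Sequence = ()):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.provenance = list(provenance)


@dataclass
class AnalysisConfig:
    """Validated run configuration (YAML key-value file)."""

    exposure: str = ""
    outcome: str = ""
    exposure_n: int | None = None
    outcome_n: int | None = None
    p_threshold: float = 5e-6
    ld_r2_threshold: float = 0.001
    clump_window_bp: float = 10_000_000
    ld_file: str | None = None
    ld_policy: str = "permissive"
    annotations_file: str | None = None
    blocklist: tuple[str, ...] = ()
    palindromic_eaf_window: float = 0.08
    model: str = "auto_by_q"  # auto_by_q | fixed | random
    q_alpha: float = 0.05
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    seed: int | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must lie in (0, 1]")
        if not (0.0 <= self.ld_r2_threshold <= 1.0):
            raise ValueError("ld_r2_threshold must lie in [0, 1]")
        if self.model not in ("auto_by_q", "fixed", "random"):
            raise ValueError(f"unknown model rule {self.model!r}")
        if not (0.0 <= self.palindromic_eaf_window < 0.5):
            raise ValueError("palindromic_eaf_window must lie in [0, 0.5)")
        if self.seed is None:
            raise ValueError("seed is required (stochastic stages are enabled)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "blocklist" in raw and raw["blocklist"] is not None:
            raw["blocklist"] = tuple(raw["blocklist"])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["blocklist"] = list(d["blocklist"])
        return d


def _resolve_records(spec: str) -> list[SummaryStatRecord]:
    if spec in FIXTURE_NAMES and spec != "study_meta":
        return list(load_fixture(spec))
    return read_summary_stats(spec)


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns the report as a JSON-serializable dict.

    When ``config.out_dir`` is set the report plus the TSV side tables
    (estimates, harmonization, leave-one-out, forest/funnel/scatter) are
    also written there.
    """
    exposure = _resolve_records(config.exposure)
    outcome = _resolve_records(config.outcome)

    # --- selection ---------------------------------------------------
    try:
        selected = select_instruments(exposure, config.p_threshold)
    except Exception as exc:
        raise PipelineError("selection", str(exc)) from exc

    # --- clumping ----------------------------------------------------
    try:
        if config.ld_file:
            ld = LDTable.from_tsv(config.ld_file, policy=config.ld_policy)
        else:
            ld = LDTable(policy="permissive")
        clumped = clump(selected, ld, config.ld_r2_threshold, config.clump_window_bp)
    except Exception as exc:
        raise PipelineError("clump", str(exc), selected.provenance) from exc

    # --- confounder screen -------------------------------------------
    try:
        annotations = (
            read_annotations(config.annotations_file) if config.annotations_file else []
        )
        screened = screen_confounders(clumped, annotations, list(config.blocklist))
        if screened.k == 0:
            raise PipelineError("confounder_screen", "no instruments survive screening",
                                screened.provenance)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("confounder_screen", str(exc), clumped.provenance) from exc

    # --- strength ----------------------------------------------------
    strength_rows = []
    if config.exposure_n:
        for rec in screened.records:
            s = instrument_strength(rec, config.exposure_n, k=screened.k)
            strength_rows.append(dataclasses.asdict(s))
    fmin, fmax, n_strong = strength_summary(screened)

    # --- harmonization -----------------------------------------------
    try:
        hset = harmonize(screened.records, outcome, config.palindromic_eaf_window)
        if hset.nsnp == 0:
            raise PipelineError("harmonize", "no SNPs retained after harmonization",
                                screened.provenance)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("harmonize", str(exc), screened.provenance) from exc

    # --- estimation --------------------------------------------------
    try:
        qtest = cochran_q(hset) if hset.nsnp >= 2 else None
        if config.model == "auto_by_q":
            model = "random" if (qtest and qtest.pvalue < config.q_alpha) else "fixed"
        else:
            model = config.model
        estimates = [ivw(hset, model="fixed"), ivw(hset, model="random")]
        main = ivw(hset, model=model)
        if hset.nsnp >= 3:
            estimates.append(egger(hset))
            estimates.append(
                weighted_median(hset, n_boot=config.n_boot, seed=config.seed)
            )
    except Exception as exc:
        raise PipelineError("estimation", str(exc), screened.provenance) from exc

    # --- diagnostics -------------------------------------------------
    egger_int = None
    presso = None
    loo = None
    if hset.nsnp >= 3:
        e = next(e for e in estimates if e.method == "egger_slope")
        egger_int = {
            "intercept": e.extra["intercept"],
            "se": e.extra["intercept_se"],
            "pvalue": e.extra["intercept_pvalue"],
        }
    if hset.nsnp >= 4:
        pres = mr_presso(
            hset,
            n_sim=config.presso_n_sim,
            seed=config.seed,
            outlier_alpha=config.presso_outlier_alpha,
        )
        presso = {
            "rss_obs": pres.rss_obs,
            "global_pvalue": pres.global_pvalue,
            "n_sim": pres.n_sim,
            "outliers": list(pres.outliers),
            "outlier_pvalues": pres.outlier_pvalues,
            "distortion_pvalue": pres.distortion_pvalue,
            "beta_raw": pres.beta_raw,
            "beta_corrected": pres.beta_corrected,
            "seed": pres.seed,
        }
    if hset.nsnp >= 2:
        loo_table = leave_one_out(hset, model=model)
        loo = {
            "rows": [dict(r) for r in loo_table.rows],
            "sign_consistency": loo_table.sign_consistency,
        }
    plot_data = funnel_and_forest_data(hset, methods=estimates)

    provenance = [dataclasses.asdict(ev) for ev in screened.provenance]
    report = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config": config.as_dict(),
        "provenance": provenance,
        "strength": {
            "per_snp": strength_rows,
            "f_min": fmin,
            "f_max": fmax,
            "n_f_gt_10": n_strong,
            "convention": "f_from_p",
        },
        "harmonization": {
            "n_retained": hset.nsnp,
            "n_dropped": len(hset.dropped),
            "actions": {p.snp_id: p.action for p in hset.pairs},
            "dropped": [dataclasses.asdict(d) for d in hset.dropped],
        },
        "estimates": [e.as_dict() for e in estimates],
        "main_model": model,
        "main_estimate": main.as_dict(),
        "heterogeneity": (
            {"q": qtest.q, "df": qtest.df, "pvalue": qtest.pvalue} if qtest else {}
        ),
        "egger_intercept": egger_int or {},
        "presso": presso,
        "leave_one_out": loo or {},
        "plot_data": plot_data,
        "runtime": {
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "host": platform.node(),
        },
    }
    validate_report(report)

    if config.out_dir:
        _write_outputs(report, hset, Path(config.out_dir))
    return report


def _write_outputs(report: dict, hset: HarmonizedSet, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
    )
    with open(out_dir / "estimates.tsv", "w", encoding="utf-8") as fh:
        cols = ["method", "nsnp", "beta", "se", "ci_low", "ci_high", "pvalue",
                "or_point", "or_ci_low", "or_ci_high"]
        fh.write("\t".join(cols) + "\n")
        for e in report["estimates"]:
            fh.write("\t".join(str(e[c]) for c in cols) + "\n")
    with open(out_dir / "harmonization.tsv", "w", encoding="utf-8") as fh:
        hset.report_tsv(fh)
    if report["leave_one_out"]:
        with open(out_dir / "leave_one_out.tsv", "w", encoding="utf-8") as fh:
            fh.write("excluded\tbeta\tse\tci_low\tci_high\n")
            for row in report["leave_one_out"]["rows"]:
                fh.write(
                    f"{row['excluded'] or 'FULL_SET'}\t{row['beta']}\t{row['se']}\t"
                    f"{row['ci_low']}\t{row['ci_high']}\n"
                )
    for name in ("forest", "funnel", "scatter"):
        rows = report["plot_data"][name]
        if not rows:
            continue
        keys = sorted({k for r in rows for k in r})
        with open(out_dir / f"{name}_data.tsv", "w", encoding="utf-8") as fh:
            fh.write("\t".join(keys) + "\n")
            for r in rows:
                fh.write("\t".join(str(r.get(k, "")) for k in keys) + "\n")


def _load_schema() -> dict:
    ref = resources.files("tsmr.schemas").joinpath("report_schema.json")
    return json.loads(ref.read_text(encoding="utf-8"))


def validate_report(report: Mapping[str, Any]) -> None:
    """Structural validation against the shipped JSON schema (the subset of
    JSON Schema the schema file actually uses: required + type)."""
    schema = _load_schema()
    missing = [k for k in schema["required"] if k not in report]
    if missing:
        raise ValueError(f"report missing required keys: {missing}")
    type_map = {
        "object": dict,
        "array": list,
        "string": str,
        "number": (int, float),
        "null": type(None),
    }
    for key, spec in schema["properties"].items():
        if key not in report:
            continue
        expected = spec["type"]
        expected_types = tuple(
            t for name in ([expected] if isinstance(expected, str) else expected)
            for t in (type_map[name] if isinstance(type_map[name], tuple) else (type_map[name],))
        )
        if not isinstance(report[key], expected_types):
            raise ValueError(
                f"report[{key!r}] has type {type(report[key]).__name__}, "
                f"expected {expected}"
            )
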