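"""End-to-end pipeline: morphometrics -> synchrony -> split-CC -> GLM.

Assembles every number a results section would cite into one JSON report:
the phi timeline, the before/after cross-correlation pair, the AICc model
table, the averaged coefficients, and the per-phase environmental slopes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import buffering_glm, crosscorr, morphometrics, sync_markov
from .errors import EggSyncError, SchemaError

log = logging.getLogger("eggsync")

ENV_CSV_COLUMNS = ["year", "wnao"]

#: Required top-level keys of the JSON run report and their types.
REPORT_SCHEMA: dict[str, type] = {
    "config": dict,
    "synchrony": dict,
    "cross_correlation": dict,
    "model_table": list,
    "averaged_coefficients": list,
    "phase_slopes": list,
}


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    eggs_csv: str
    env_csv: str
    out_dir: str = "results"
    study_window: tuple[int, int] = morphometrics.DEFAULT_STUDY_WINDOW
    closure_year: int = 2010
    n_sims: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    delta_aicc_threshold: float = 4.0
    standardize: bool = True

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "study_window" in raw:
            raw["study_window"] = tuple(raw["study_window"])
        return cls(**raw)


def read_env_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ENV_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df["year"] = df["year"].astype(int)
    return df[ENV_CSV_COLUMNS]


def validate_report(report: dict) -> None:
    """Raise SchemaError unless the report matches the declared schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise SchemaError(f"report is missing key '{key}'")
        if not isinstance(report[key], typ):
            raise SchemaError(
                f"report key '{key}' has type {type(report[key]).__name__}, "
                f"expected {typ.__name__}"
            )
    for key in ("H_null_mean", "years_synchronized", "transition_matrix"):
        if key not in report["synchrony"]:
            raise SchemaError(f"report['synchrony'] is missing '{key}'")
    for key in ("cc_before", "cc_after", "breakpoint_year"):
        if key not in report["cross_correlation"]:
            raise SchemaError(f"report['cross_correlation'] is missing '{key}'")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write tidy outputs plus the JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except EggSyncError as exc:
            raise EggSyncError(f"stage '{name}' failed: {exc}") from exc
        log.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
        return result

    eggs = _stage("read", lambda: morphometrics.read_eggs_csv(config.eggs_csv))
    env = _stage("env", lambda: read_env_csv(config.env_csv))
    series = _stage(
        "volumes",
        lambda: morphometrics.annual_series(eggs, study_window=config.study_window),
    )
    morphometrics.write_series_csv(series, out / "annual_series.csv")

    if set(series) != {"gull", "shearwater"}:
        raise EggSyncError(f"expected both study species, got {sorted(series)}")
    sync = _stage(
        "synchrony",
        lambda: sync_markov.run_synchrony(
            series["gull"], series["shearwater"],
            n_sims=config.n_sims, seed=config.seed,
        ),
    )
    sync.to_frame().to_csv(out / "synchrony.csv", index=False)

    cc = _stage(
        "crosscorr",
        lambda: crosscorr.split_cc(
            series["gull"], series["shearwater"], config.closure_year
        ),
    )

    frame = buffering_glm.build_model_frame(
        series, env, sync, config.closure_year, standardize=config.standardize
    )
    table = _stage("glm", lambda: buffering_glm.model_selection(frame))
    table.to_frame().to_csv(out / "model_table.csv", index=False)
    averaged = buffering_glm.model_average(table, config.delta_aicc_threshold)
    averaged.to_csv(out / "averaged_coefficients.csv", index=False)
    slopes = _stage("slopes", lambda: buffering_glm.phase_slopes(frame))
    slopes.to_csv(out / "phase_slopes.csv", index=False)

    report = {
        "config": {
            "study_window": list(config.study_window),
            "closure_year": config.closure_year,
            "n_sims": config.n_sims,
            "seed": config.seed,
            "alpha": config.alpha,
            "delta_aicc_threshold": config.delta_aicc_threshold,
            "standardize": config.standardize,
        },
        "synchrony": sync.report(config.alpha),
        "cross_correlation": cc.report(),
        "model_table": table.to_frame().to_dict(orient="records"),
        "averaged_coefficients": averaged.to_dict(orient="records"),
        "phase_slopes": slopes.to_dict(orient="records"),
    }
    validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
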