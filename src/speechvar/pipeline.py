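"""End-to-end orchestration: simulate or ingest -> measure -> analyze -> report.

A run is fully described by a :class:`RunConfig`; given the same config and
seed, every output file is byte-identical across runs (no wall-clock state
enters the report bundle; progress timestamps go to the log stream only).

Outputs written to the run directory:

``measures.csv``
    tidy measure table (participant x task x measure).
``group_summary.csv``
    Table-1-style grid: "mean (SD)" per group and the group-difference p,
    per measure x task, with blank cells where a measure is undefined.
``validity_grid.csv``
    Table-2-style CHR-only validity correlations, computed only for
    measures with a significant group difference.
``modality.csv``
    per-modality group models and the group x modality interaction.
``power.txt``
    Fisher-z power report.
``run_log.json``
    the full config, seed and every analysis parameter used.
``MANIFEST.txt``
    stages completed (written incrementally, so a failed run shows which
    stage died).
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SpeechVarError
from .measures import (
    ANALYSIS_MEASURES,
    MEASURE_TASKS,
    Measure,
    MeasureConfig,
    MeasureTable,
    compute_measure_table,
)
from .segments import Task
from .segments_io import read_segments_csv, write_segments_csv
from .stats_inference import (
    ALPHA,
    PowerSpec,
    fit_group_difference,
    modality_stratified_analysis,
    power_analysis,
    read_participants_csv,
    validity_grid,
)
from .synthetic_cohort import Cohort, SyntheticConfig, generate_cohort

TASK_ORDER = [Task.AMR, Task.SMR, Task.READ, Task.SPONT]


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    mode: str = "simulate"  # "simulate" | "ingest"
    out_dir: str = "speechvar_run"
    seed: int = 0
    # ingest-mode inputs
    segments_csv: Optional[str] = None
    participants_csv: Optional[str] = None
    # measure parameters
    min_silence_s: float = 0.150
    min_n: int = 5
    epsilon: float = 1e-3
    # analysis parameters
    alpha: float = ALPHA
    power_r: float = 0.37
    power_power: float = 0.80
    power_n: Optional[int] = None  # defaults to the CHR count
    # simulate-mode generator config
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    write_segments: bool = False

    def measure_config(self) -> MeasureConfig:
        return MeasureConfig(
            min_silence_s=self.min_silence_s, min_n=self.min_n, epsilon=self.epsilon
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)


def _log(message: str) -> None:
    stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    print(f"[{stamp}] {message}", file=sys.stderr)


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "MANIFEST.txt"
        self.stages: list[str] = []

    def done(self, stage: str) -> None:
        self.stages.append(stage)
        self.path.write_text("\n".join(self.stages) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------- #
# analysis result computation
# --------------------------------------------------------------------------- #
def group_summary(
    table: MeasureTable, participants: pd.DataFrame, alpha: float = ALPHA
) -> pd.DataFrame:
    """Tidy per measure x task group descriptives plus the group-model p."""
    rows = []
    for measure in ANALYSIS_MEASURES:
        for task in MEASURE_TASKS[measure]:
            raw = table.series(measure, task, scale="raw")
            if raw.empty:
                continue
            merged = participants.set_index("participant_id")[["group"]].join(
                raw.rename("raw"), how="inner"
            ).dropna()
            stats = {}
            for g in ("CHR", "HC"):
                vals = merged.loc[merged["group"] == g, "raw"].to_numpy(float)
                stats[g] = (
                    (float(np.mean(vals)), float(np.std(vals, ddof=1)), len(vals))
                    if len(vals) >= 2 else (np.nan, np.nan, len(vals))
                )
            try:
                fit = fit_group_difference(table, participants, measure, task)
                beta, se, tval, p, n = fit.beta, fit.se, fit.t, fit.p, fit.n
            except SpeechVarError:
                beta = se = tval = p = np.nan
                n = 0
            rows.append(
                (
                    measure.value, task.value,
                    stats["CHR"][0], stats["CHR"][1], stats["CHR"][2],
                    stats["HC"][0], stats["HC"][1], stats["HC"][2],
                    beta, se, tval, p, n,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "measure", "task", "chr_mean", "chr_sd", "chr_n",
            "hc_mean", "hc_sd", "hc_n", "beta", "se", "t", "p", "n_model",
        ],
    )


def render_group_table(summary: pd.DataFrame) -> str:
    """Format the group summary as a Table-1-style CSV string.

    One block of three rows (CHR, HC, p) per measure; one column per task;
    cells are ``mean (SD)`` at full precision, blank where the measure is
    not defined for the task.
    """
    tasks = [t.value for t in TASK_ORDER]
    lines = [",".join(["measure", "row"] + tasks)]
    for measure in ANALYSIS_MEASURES:
        sub = summary[summary["measure"] == measure.value].set_index("task")
        cells: dict[str, dict[str, str]] = {"CHR": {}, "HC": {}, "p": {}}
        for task in tasks:
            if task not in sub.index:
                cells["CHR"][task] = cells["HC"][task] = cells["p"][task] = ""
                continue
            row = sub.loc[task]
            for g, m, s in (("CHR", row["chr_mean"], row["chr_sd"]),
                            ("HC", row["hc_mean"], row["hc_sd"])):
                cells[g][task] = (
                    "" if pd.isna(m) else f"{float(m)!r} ({float(s)!r})"
                )
            cells["p"][task] = "" if pd.isna(row["p"]) else repr(float(row["p"]))
        if all(v == "" for v in cells["CHR"].values()):
            continue
        for rowname in ("CHR", "HC", "p"):
            lines.append(
                ",".join(
                    [measure.value, rowname]
                    + [f'"{cells[rowname][t]}"' if "," in cells[rowname][t] else cells[rowname][t] for t in tasks]
                )
            )
    return "\n".join(lines) + "\n"


def parse_group_table(text: str) -> pd.DataFrame:
    """Invert :func:`render_group_table` back to tidy numbers."""
    import io

    df = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    tasks = [c for c in df.columns if c not in ("measure", "row")]
    rows = []
    for measure, block in df.groupby("measure", sort=False):
        block = block.set_index("row")
        for task in tasks:
            chr_cell = block.loc["CHR", task]
            if not chr_cell:
                continue

            def split(cell: str) -> tuple[float, float]:
                m, s = cell.split(" (")
                return float(m), float(s.rstrip(")"))

            cm, cs = split(chr_cell)
            hm, hs = split(block.loc["HC", task])
            p = block.loc["p", task]
            rows.append((measure, task, cm, cs, hm, hs, float(p) if p else np.nan))
    return pd.DataFrame(
        rows,
        columns=["measure", "task", "chr_mean", "chr_sd", "hc_mean", "hc_sd", "p"],
    )


def modality_results(
    table: MeasureTable,
    participants: pd.DataFrame,
    summary: pd.DataFrame,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Stratified modality models for the measures with significant group effects."""
    rows = []
    import warnings as _w

    significant = summary[summary["p"] < alpha]
    for r in significant.itertuples(index=False):
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            res = modality_stratified_analysis(table, participants, r.measure, r.task)
        rec: dict = {"measure": r.measure, "task": r.task}
        for stratum in ("in_person", "remote"):
            fit = res.per_modality.get(stratum)
            rec[f"{stratum}_beta"] = fit.beta if fit else np.nan
            rec[f"{stratum}_p"] = fit.p if fit else np.nan
            rec[f"{stratum}_n"] = fit.n if fit else 0
        rec["interaction_beta"] = res.interaction.beta if res.interaction else np.nan
        rec["interaction_p"] = res.interaction.p if res.interaction else np.nan
        rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=[
            "measure", "task", "in_person_beta", "in_person_p", "in_person_n",
            "remote_beta", "remote_p", "remote_n", "interaction_beta", "interaction_p",
        ],
    )


def power_report(config: RunConfig, participants: pd.DataFrame) -> str:
    n = config.power_n
    if n is None:
        n = int((participants["group"] == "CHR").sum())
    required = power_analysis(
        PowerSpec(r=config.power_r, alpha=config.alpha, power=config.power_power),
        mode="required_n",
    )
    minimal = power_analysis(
        PowerSpec(alpha=config.alpha, power=config.power_power, n=max(n, 4)),
        mode="minimal_r",
    )
    return (
        "Fisher-z power analysis (two-sided test of a Pearson correlation)\n"
        f"alpha = {config.alpha}, power = {config.power_power}\n"
        f"required N to detect r = {config.power_r}: {required}\n"
        f"minimal detectable r at n = {n}: {minimal:.3f}\n"
    )


# --------------------------------------------------------------------------- #
# the pipeline
# --------------------------------------------------------------------------- #
@dataclass
class RunResult:
    out_dir: Path
    table: MeasureTable
    participants: pd.DataFrame
    summary: pd.DataFrame
    validity: pd.DataFrame
    modality: pd.DataFrame
    cohort: Optional[Cohort] = None


def run_pipeline(config: RunConfig) -> RunResult:
    """Run simulate/ingest -> measure -> analyze -> report; write the bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)

    # ---- stage: inputs ------------------------------------------------- #
    cohort = None
    if config.mode == "simulate":
        _log(f"simulate: generating cohort (seed={config.seed})")
        cohort = generate_cohort(config.synthetic, seed=config.seed)
        samples = cohort.samples
        participants = cohort.participants
        if config.write_segments:
            write_segments_csv(samples, out / "segments.csv")
            participants.to_csv(out / "participants.csv", index=False)
    elif config.mode == "ingest":
        if not config.segments_csv or not config.participants_csv:
            raise SpeechVarError("ingest mode requires segments_csv and participants_csv")
        _log(f"ingest: reading {config.segments_csv}")
        samples = read_segments_csv(config.segments_csv)
        participants = read_participants_csv(config.participants_csv)
    else:
        raise SpeechVarError(f"unknown mode {config.mode!r}")
    manifest.done("inputs")

    # ---- stage: measure ------------------------------------------------ #
    _log(f"measure: {len(samples)} samples")
    table = compute_measure_table(samples, config.measure_config())
    table.to_csv(out / "measures.csv")
    manifest.done("measure")

    # ---- stage: analyze ------------------------------------------------ #
    _log("analyze: group models, validity, modality, power")
    summary = group_summary(table, participants, config.alpha)
    validity = validity_grid(
        table, participants,
        tasks=[t.value for t in TASK_ORDER],
        measures=[m for m in ANALYSIS_MEASURES],
        alpha=config.alpha,
    )
    modality = modality_results(table, participants, summary, config.alpha)
    manifest.done("analyze")

    # ---- stage: report ------------------------------------------------- #
    float_fmt = lambda v: repr(float(v))  # noqa: E731 - lossless CSV floats
    (out / "group_summary.csv").write_text(render_group_table(summary), encoding="utf-8")
    validity.to_csv(out / "validity_grid.csv", index=False, float_format=float_fmt)
    modality.to_csv(out / "modality.csv", index=False, float_format=float_fmt)
    (out / "power.txt").write_text(power_report(config, participants), encoding="utf-8")
    run_log = {
        "config": config.to_dict(),
        "seed": config.seed,
        "alpha": config.alpha,
        "epsilon": config.epsilon,
        "min_silence_s": config.min_silence_s,
        "min_n": config.min_n,
        "n_samples": len(samples),
        "n_participants": len(participants),
    }
    (out / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    manifest.done("report")
    _log(f"done: bundle in {out}")
    return RunResult(
        out_dir=out, table=table, participants=participants,
        summary=summary, validity=validity, modality=modality, cohort=cohort,
    )
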