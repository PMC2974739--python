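"""The reproducible simulate → process → summarize run.

Stages, executed in fixed order on request:

* ``simulate``     — generate one trace bundle per receptor condition,
* ``process``      — per-cell measurements (amplitudes, block, measured
                     reversal potentials) from the bundles,
* ``permeability`` — junction correction, GHK conversion, per-condition
                     summary of reversal potentials and P_Ca/P_mono,
* ``block``        — per-condition amplitude and percent-block summary,
* ``report``       — plain-text summary and averaged-IV figure.

Every artifact is a tab-separated table with unit-bearing headers, stamped
with the configuration hash and seed; a run log records each stage's
inputs, parameters and row counts so any stage can be re-run from the log
alone.
"""

from __future__ import annotations

import datetime
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .io import read_trace_bundle, write_trace_bundle
from .permeability import (
    NoReversalError,
    build_permeability_table,
    compute_permeability_per_cell,
    correct_junction_potential,
    estimate_reversal_potential,
    group_statistics,
)
from .simulate import TraceRecording, generate_batch
from .traces import (
    peak_current,
    percent_block,
    ramp_to_iv,
    response_ratio,
    segment_window,
    subtract_background,
    average_ivs,
    normalize_iv,
)

__all__ = ["run_pipeline", "STAGES", "StageOrderError"]

STAGES = ("simulate", "process", "permeability", "block", "report")


class StageOrderError(RuntimeError):
    """A stage was requested before the stage that produces its inputs."""


def _log(outdir: Path, message: str) -> None:
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with open(outdir / "run.log", "a") as fh:
        fh.write(f"{stamp}\t{message}\n")


def _write_table(df: pd.DataFrame, path: Path, config: ExperimentConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()}\tseed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _plateau(trace: TraceRecording, window, fraction=0.25) -> float:
    t0 = window[1] - fraction * (window[1] - window[0])
    mask = (trace.time >= t0) & (trace.time < window[1])
    return float(trace.current[mask].mean())


def _application_measurements(trace: TraceRecording) -> dict[str, float]:
    """Amplitude and within-sweep percent block of one application sweep:
    wash / agonist / agonist+Mg / agonist / wash."""
    base = _plateau(trace, segment_window(trace, 0))
    d_ctrl = _plateau(trace, segment_window(trace, 1)) - base
    d_block = _plateau(trace, segment_window(trace, 2)) - base
    amp = peak_current(trace, segment_window(trace, 1), segment_window(trace, 0))
    sign = -1.0 if d_ctrl < 0 else 1.0
    out: dict[str, float] = {"amplitude_nA": amp}
    if d_ctrl != 0:
        out["percent_block"] = percent_block(sign * d_ctrl, sign * d_block)
    return out


def _ramp_erev(sweeps: dict[str, TraceRecording], agonist: str) -> float:
    """Measured (junction-uncorrected) reversal potential from one cell's
    biionic ramp triple for one agonist condition."""
    pre = ramp_to_iv(sweeps[f"ramp_{agonist}_ctrl_pre"])
    ago = ramp_to_iv(sweeps[f"ramp_{agonist}_agonist"])
    post = ramp_to_iv(sweeps[f"ramp_{agonist}_ctrl_post"])
    iv = subtract_background(ago, pre, post)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # multiple-crossing warnings on noise
        return estimate_reversal_potential(iv)


def stage_simulate(config: ExperimentConfig, outdir: Path) -> None:
    traces_dir = outdir / "traces"
    for k, condition in enumerate(config.conditions):
        design = config.design_for(condition)
        # distinct, reproducible sub-seed per condition
        batch = generate_batch(design, config.n_cells, config.seed * 1009 + k)
        sweeps = [tr for cell in batch.values() for tr in cell]
        bundle = traces_dir / condition.replace("/", "_")
        write_trace_bundle(sweeps, bundle)
        _log(outdir, f"simulate\tcondition={condition}\tn_cells={config.n_cells}"
                     f"\tsweeps={len(sweeps)}\tseed={config.seed}"
                     f"\tconfig={config.config_hash()}")


def stage_process(config: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    traces_dir = outdir / "traces"
    if not traces_dir.is_dir():
        raise StageOrderError("process requested but no traces/ directory; "
                              "run the simulate stage first")
    rows = []
    for condition in config.conditions:
        bundle = traces_dir / condition.replace("/", "_")
        traces = read_trace_bundle(bundle)
        by_cell: dict[str, dict[str, TraceRecording]] = {}
        for tr in traces:
            by_cell.setdefault(tr.metadata["cell_id"], {})[
                tr.metadata["protocol_name"]
            ] = tr

        for cell_id, sweeps in sorted(by_cell.items()):
            def add(quantity: str, value: float, units: str) -> None:
                rows.append(dict(condition=condition, cell_id=cell_id,
                                 quantity=quantity, value=value, units=units))

            amps = {}
            for agonist, name in (("Gly", "app_gly"), ("Glu/Gly", "app_glugly")):
                m = _application_measurements(sweeps[name])
                tag = "gly" if agonist == "Gly" else "glugly"
                amps[agonist] = m["amplitude_nA"]
                add(f"i_{tag}", m["amplitude_nA"], "nA")
                if "percent_block" in m:
                    add(f"block_{tag}", m["percent_block"], "%")
            if amps["Glu/Gly"] > 0:
                add("response_ratio", response_ratio(amps["Gly"], amps["Glu/Gly"]),
                    "")
            for agonist, tag in (("gly", "gly"), ("glugly", "glugly")):
                try:
                    erev = _ramp_erev(sweeps, agonist)
                except NoReversalError:
                    continue
                add(f"erev_measured_{tag}", erev, "mV")
    df = pd.DataFrame(rows)
    _write_table(df, outdir / "per_cell_measurements.tsv", config)
    _log(outdir, f"process\trows={len(df)}\tconfig={config.config_hash()}")
    return df


def _require_measurements(config: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    path = outdir / "per_cell_measurements.tsv"
    if not path.exists():
        raise StageOrderError(f"{path.name} missing; run the process stage first")
    return _read_table(path)


def stage_permeability(config: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    meas = _require_measurements(config, outdir)
    cal = config.calibration
    per_cell = []
    for (condition, cell_id), grp in meas.groupby(["condition", "cell_id"]):
        q = dict(zip(grp["quantity"], grp["value"]))
        for agonist, tag in (("Gly", "gly"), ("Glu/Gly", "glugly")):
            key = f"erev_measured_{tag}"
            if key not in q:
                continue
            corrected = correct_junction_potential(
                q[key], config.junction_potential_mv
            )
            ratio = compute_permeability_per_cell(
                corrected, cal, config.ca_o, config.constants
            )
            per_cell.append(dict(
                condition=condition, cell_id=cell_id, agonist=agonist,
                erev_measured_mv=q[key], erev_mv=corrected,
                junction_corrected=True, p_ratio=ratio,
            ))
    per_cell_df = pd.DataFrame(per_cell)
    _write_table(per_cell_df, outdir / "per_cell_permeability.tsv", config)

    results = build_permeability_table(
        per_cell_df, list(config.conditions), cal, config.ca_o
    )
    table = pd.DataFrame([vars(r) for r in results])
    _write_table(table, outdir / "permeability_table.tsv", config)
    _log(outdir, f"permeability\trows={len(table)}\tmono_i={cal.mono_i:.4g}mM"
                 f"\tca_o={config.ca_o}mM\tconfig={config.config_hash()}")
    return table


def stage_block(config: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    meas = _require_measurements(config, outdir)
    rows = []
    for condition in config.conditions:
        sub = meas[meas["condition"] == condition]
        row: dict[str, object] = {"condition": condition}
        for tag in ("gly", "glugly"):
            for quantity, prefix, unit in (
                (f"i_{tag}", f"i_{tag}", "nA"),
                (f"block_{tag}", f"block_{tag}", "%"),
            ):
                vals = sub.loc[sub["quantity"] == quantity, "value"]
                if len(vals) >= 2:
                    g = group_statistics(vals)
                    row[f"{prefix}_mean"] = g.mean
                    row[f"{prefix}_sem"] = g.sem
                    row[f"{prefix}_n"] = g.n
        rows.append(row)
    table = pd.DataFrame(rows)
    _write_table(table, outdir / "block_table.tsv", config)
    _log(outdir, f"block\trows={len(table)}\tconfig={config.config_hash()}")
    return table


def stage_report(config: ExperimentConfig, outdir: Path) -> Path:
    perm_path = outdir / "permeability_table.tsv"
    block_path = outdir / "block_table.tsv"
    if not (perm_path.exists() and block_path.exists()):
        raise StageOrderError("report requested before permeability/block stages")
    perm = _read_table(perm_path)
    block = _read_table(block_path)
    report = outdir / "report.txt"
    with open(report, "w") as fh:
        fh.write(f"Run {config.config_hash()} seed={config.seed} "
                 f"n_cells={config.n_cells}\n")
        fh.write(f"mono_i = {config.calibration.mono_i:.2f} mM, "
                 f"ca_o = {config.ca_o} mM, T = {config.constants.T} K, "
                 f"junction = {config.junction_potential_mv} mV\n\n")
        fh.write("Reversal potentials and P_Ca/P_mono (mean +/- SEM, n):\n")
        fh.write(perm.to_string(index=False))
        fh.write("\n\nAmplitudes and Mg2+ block (mean +/- SEM, n):\n")
        fh.write(block.to_string(index=False))
        fh.write("\n")
    _plot_ivs(config, outdir)
    _log(outdir, f"report\tfile={report.name}\tconfig={config.config_hash()}")
    return report


def _plot_ivs(config: ExperimentConfig, outdir: Path) -> None:
    traces_dir = outdir / "traces"
    if not traces_dir.is_dir():
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for condition in config.conditions:
        bundle = traces_dir / condition.replace("/", "_")
        traces = read_trace_bundle(bundle)
        by_cell: dict[str, dict[str, TraceRecording]] = {}
        for tr in traces:
            by_cell.setdefault(tr.metadata["cell_id"], {})[
                tr.metadata["protocol_name"]
            ] = tr
        ivs = []
        for sweeps in by_cell.values():
            try:
                pre = ramp_to_iv(sweeps["ramp_glugly_ctrl_pre"])
                ago = ramp_to_iv(sweeps["ramp_glugly_agonist"])
                post = ramp_to_iv(sweeps["ramp_glugly_ctrl_post"])
                ivs.append(normalize_iv(subtract_background(ago, pre, post)))
            except (KeyError, ZeroDivisionError):
                continue
        if ivs:
            mean_iv = average_ivs(ivs)
            ax.plot(mean_iv.voltage, mean_iv.current, label=condition)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("command potential (mV)")
    ax.set_ylabel("current (normalized to +20 mV)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "iv_curves.png", dpi=120)
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "process": stage_process,
    "permeability": stage_permeability,
    "block": stage_block,
    "report": stage_report,
}


def run_pipeline(config: ExperimentConfig, stages=STAGES, output_dir="results") -> int:
    """Execute the requested stages in canonical order; returns 0 on
    success.  Stage-order violations (e.g. ``report`` without tables) raise
    :class:`StageOrderError`."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage in stages:
            _STAGE_FUNCS[stage](config, outdir)
    return 0
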