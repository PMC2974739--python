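"""On-disk sweep format: columnar text plus a YAML metadata sidecar.

A trace bundle is a directory of sweeps; each sweep is a tab-separated file
with unit-bearing column headers (``time_s``, ``command_mV``, ``current_nA``)
and a ``<stem>.meta.yaml`` sidecar holding the acquisition metadata.  Units
are checked strictly on read: a file recorded in µA is converted to nA, an
unknown unit is a format error, and a missing sidecar or ragged column
count names the offending file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .simulate import TraceRecording

__all__ = ["FormatError", "write_trace_bundle", "read_trace_bundle"]

_TIME_UNITS = {"s": 1.0, "ms": 1e-3}
_VOLT_UNITS = {"mV": 1.0, "V": 1e3}
_CURR_UNITS = {"nA": 1.0, "uA": 1e3, "pA": 1e-3}


class FormatError(ValueError):
    """A sweep file or its sidecar violates the bundle format."""


def _sweep_stem(trace: TraceRecording, index: int) -> str:
    cell = trace.metadata.get("cell_id", "cell")
    name = trace.metadata.get("protocol_name") or trace.metadata.get("protocol", "sweep")
    safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in f"{cell}__{name}")
    return f"{safe}__{index:03d}"


def write_trace_bundle(traces, path) -> list[Path]:
    """Write sweeps into ``path`` (created if needed); returns written files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for k, tr in enumerate(traces):
        stem = _sweep_stem(tr, k)
        data_file = path / f"{stem}.tsv"
        cols = np.column_stack([tr.time, tr.command_voltage, tr.current])
        header = "time_s\tcommand_mV\tcurrent_nA"
        np.savetxt(data_file, cols, fmt="%.9g", delimiter="\t",
                   header=header, comments="")
        meta_file = path / f"{stem}.meta.yaml"
        meta = _plain(tr.metadata)
        with open(meta_file, "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
        written.extend([data_file, meta_file])
    return written


def _plain(obj):
    """Recursively coerce numpy scalars/arrays so YAML stays readable."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _parse_header(path: Path, header_line: str) -> tuple[float, float, float]:
    names = header_line.strip().split("\t")
    if len(names) != 3:
        raise FormatError(f"{path}: expected 3 columns, header has {len(names)}")
    scales = []
    for name, table, kind in zip(
        names, (_TIME_UNITS, _VOLT_UNITS, _CURR_UNITS),
        ("time", "command", "current"),
    ):
        if "_" not in name:
            raise FormatError(f"{path}: column {name!r} carries no unit suffix")
        unit = name.rsplit("_", 1)[1]
        if unit not in table:
            raise FormatError(f"{path}: unknown {kind} unit {unit!r} in {name!r}")
        scales.append(table[unit])
    return tuple(scales)  # type: ignore[return-value]


def read_trace_bundle(path) -> list[TraceRecording]:
    """Read every sweep in a bundle directory, converting units to the
    package conventions (s, mV, nA)."""
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"{path} is not a bundle directory")
    traces = []
    for data_file in sorted(path.glob("*.tsv")):
        meta_file = data_file.with_name(data_file.stem + ".meta.yaml")
        if not meta_file.exists():
            raise FormatError(f"{data_file}: missing sidecar {meta_file.name}")
        with open(data_file) as fh:
            header = fh.readline()
            t_scale, v_scale, i_scale = _parse_header(data_file, header)
            rows = []
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise FormatError(
                        f"{data_file}: line {lineno} has {len(parts)} fields, expected 3"
                    )
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise FormatError(
                        f"{data_file}: line {lineno}: {exc}"
                    ) from None
        if len(rows) < 2:
            raise FormatError(f"{data_file}: fewer than two samples")
        arr = np.asarray(rows, dtype=float)
        with open(meta_file) as fh:
            meta = yaml.safe_load(fh) or {}
        traces.append(
            TraceRecording(
                time=arr[:, 0] * t_scale,
                command_voltage=arr[:, 1] * v_scale,
                current=arr[:, 2] * i_scale,
                metadata=meta,
            )
        )
    if not traces:
        raise FormatError(f"{path}: bundle contains no sweep files")
    return traces
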