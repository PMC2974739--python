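"""Sweep-level processing: peaks, IV relations, normalization, percent block.

Turns raw sweeps into the intermediate quantities of the analysis: baseline-
subtracted response amplitudes, background-subtracted IV relations on a
regular voltage grid, +20 mV-normalized and averaged IV curves, percent Mg2+
block, agonist-response ratios, and the leak/induced-current decomposition
that explains apparent block exceeding 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .simulate import TraceRecording

__all__ = [
    "IVRelation",
    "BlockResult",
    "ramp_to_iv",
    "peak_current",
    "subtract_background",
    "normalize_iv",
    "average_ivs",
    "percent_block",
    "response_ratio",
    "apparent_block_decomposition",
    "segment_window",
]


@dataclass
class IVRelation:
    """Current-voltage relation on a strictly increasing voltage grid."""

    voltage: np.ndarray  # mV
    current: np.ndarray  # nA (dimensionless once normalized)
    n_averaged: int = 1
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.voltage.shape != self.current.shape:
            raise ValueError("voltage and current must have equal length")
        if self.voltage.size < 2:
            raise ValueError("an IV relation needs at least two points")
        if np.any(np.diff(self.voltage) <= 0):
            raise ValueError("voltage grid must be strictly increasing")

    def interpolate(self, v_mv: float) -> float:
        if not (self.voltage[0] <= v_mv <= self.voltage[-1]):
            raise ValueError(f"{v_mv} mV outside grid "
                             f"[{self.voltage[0]}, {self.voltage[-1]}]")
        return float(np.interp(v_mv, self.voltage, self.current))


@dataclass
class BlockResult:
    """Per-condition percent Mg2+ block of glycine- and glutamate/glycine-
    evoked currents, mean ± SEM with n.  Negative percentages denote
    potentiation; values above 100 arise when the blocker also suppresses
    leak current."""

    condition: str
    percent_block_gly: float | None = None
    sem_gly: float | None = None
    n_gly: int = 0
    percent_block_glugly: float | None = None
    sem_glugly: float | None = None
    n_glugly: int = 0

    def __post_init__(self) -> None:
        if self.n_gly < 0 or self.n_glugly < 0:
            raise ValueError("n must be >= 0")


def ramp_to_iv(trace: TraceRecording, grid_step_mv: float = 1.0) -> IVRelation:
    """Bin the samples of a ramp sweep onto a regular voltage grid.

    A 2-s ramp sampled at >= 1 kHz oversamples voltage heavily; within-bin
    averaging onto a fixed grid makes subtraction and averaging across
    sweeps well-defined.
    """
    v = np.asarray(trace.command_voltage, dtype=float)
    i = np.asarray(trace.current, dtype=float)
    lo = np.ceil(v.min() / grid_step_mv) * grid_step_mv
    hi = np.floor(v.max() / grid_step_mv) * grid_step_mv
    grid = np.arange(lo, hi + 0.5 * grid_step_mv, grid_step_mv)
    edges = np.concatenate([grid - 0.5 * grid_step_mv, [grid[-1] + 0.5 * grid_step_mv]])
    idx = np.digitize(v, edges) - 1
    ok = (idx >= 0) & (idx < grid.size)
    counts = np.bincount(idx[ok], minlength=grid.size)
    sums = np.bincount(idx[ok], weights=i[ok], minlength=grid.size)
    filled = counts > 0
    iv = IVRelation(
        grid[filled],
        sums[filled] / counts[filled],
        metadata=dict(trace.metadata),
    )
    return iv


def segment_window(
    trace: TraceRecording, segment_index: int
) -> tuple[float, float]:
    """Time window of one timeline segment of an application sweep."""
    timeline = trace.metadata.get("timeline")
    if timeline is None:
        raise ValueError("trace has no application timeline in its metadata")
    if not 0 <= segment_index < len(timeline):
        raise IndexError(f"segment {segment_index} out of range")
    start = sum(d for _, d in timeline[:segment_index])
    return start, start + timeline[segment_index][1]


def peak_current(
    trace: TraceRecording,
    window: tuple[float, float],
    baseline_window: tuple[float, float],
    mode: str = "plateau",
    plateau_fraction: float = 0.25,
) -> float:
    """Baseline-subtracted response amplitude of one application window, in
    positive nA.

    ``mode='plateau'`` (default) takes the mean over the last
    ``plateau_fraction`` of the window — appropriate for 20-s applications
    that reach steady state; ``mode='extremum'`` takes the sample of largest
    baseline deviation.  The amplitude is reported as a magnitude, matching
    the convention for inward currents at a negative holding potential.
    """
    t = trace.time
    if window[1] <= window[0] or baseline_window[1] <= baseline_window[0]:
        raise ValueError("windows must have positive length")
    if baseline_window[0] > window[0]:
        raise ValueError("baseline window must precede the response window")
    base_mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not base_mask.any():
        raise ValueError("baseline window contains no samples")
    baseline = float(trace.current[base_mask].mean())

    if mode == "plateau":
        t0 = window[1] - plateau_fraction * (window[1] - window[0])
        mask = (t >= t0) & (t < window[1])
        if not mask.any():
            raise ValueError("response window contains no samples")
        resp = float(trace.current[mask].mean())
        return abs(resp - baseline)
    if mode == "extremum":
        mask = (t >= window[0]) & (t < window[1])
        if not mask.any():
            raise ValueError("response window contains no samples")
        dev = trace.current[mask] - baseline
        return float(np.abs(dev).max())
    raise ValueError(f"unknown mode {mode!r}")


def _resample(iv: IVRelation, grid: np.ndarray) -> np.ndarray:
    if grid[0] < iv.voltage[0] - 1e-9 or grid[-1] > iv.voltage[-1] + 1e-9:
        raise ValueError("voltage ranges do not overlap over the target grid")
    return np.interp(grid, iv.voltage, iv.current)


def subtract_background(
    agonist_iv: IVRelation,
    control_before: IVRelation,
    control_after: IVRelation,
) -> IVRelation:
    """Background-correct an agonist-present IV by subtracting the average of
    the two bracketing control (agonist-free) IVs, pointwise on the agonist
    grid."""
    grid = agonist_iv.voltage
    ctrl = 0.5 * (_resample(control_before, grid) + _resample(control_after, grid))
    out = replace(agonist_iv, current=agonist_iv.current - ctrl)
    out.metadata = dict(agonist_iv.metadata, background_subtracted=True)
    return out


def normalize_iv(
    iv: IVRelation, reference_voltage_mv: float = 20.0, epsilon: float = 1e-9
) -> IVRelation:
    """Divide an IV by its (interpolated) current at the reference voltage,
    +20 mV by default, so curves from cells of different expression level
    can be averaged."""
    ref = iv.interpolate(reference_voltage_mv)
    if abs(ref) < epsilon:
        raise ZeroDivisionError(
            f"current at {reference_voltage_mv} mV is {ref}; normalization degenerate"
        )
    out = replace(iv, current=iv.current / ref, normalized=True)
    out.metadata = dict(iv.metadata, normalized_at_mv=reference_voltage_mv)
    return out


def average_ivs(ivs) -> IVRelation:
    """Pointwise mean of IV relations on the first input's grid."""
    ivs = list(ivs)
    if not ivs:
        raise ValueError("average_ivs needs at least one IV relation")
    grid = ivs[0].voltage
    stacked = np.vstack([_resample(iv, grid) for iv in ivs])
    return IVRelation(
        grid.copy(),
        stacked.mean(axis=0),
        n_averaged=len(ivs),
        normalized=all(iv.normalized for iv in ivs),
        metadata=dict(ivs[0].metadata),
    )


def percent_block(i_control: float, i_with_blocker: float) -> float:
    """Percent reduction of the response amplitude by a blocker.

    Both inputs are baseline-subtracted response magnitudes from the same
    sweep.  Negative values mean potentiation; values above 100 occur when
    the blocker also suppresses leak (see
    :func:`apparent_block_decomposition`)."""
    if i_control == 0:
        raise ZeroDivisionError("control current is zero; block undefined")
    return 100.0 * (i_control - i_with_blocker) / i_control


def response_ratio(i_gly: float, i_glugly: float) -> float:
    """Per-cell ratio of glycine- to glutamate/glycine-evoked amplitude.

    Group values must be the mean of per-cell ratios, not the ratio of mean
    amplitudes — the two differ under per-cell expression variability
    (Jensen gap)."""
    if i_glugly == 0:
        raise ZeroDivisionError("glutamate/glycine amplitude is zero")
    if i_glugly < 0:
        raise ValueError("amplitudes are magnitudes; i_glugly must be > 0")
    return i_gly / i_glugly


def apparent_block_decomposition(
    ic: float, lc: float, f_channel: float, f_leak: float
) -> float:
    """Apparent percent block when the blocker suppresses both the agonist-
    induced current (IC) and the standing leak current (LC).

    Returns ``100 * (f_channel * IC + f_leak * LC) / IC``.  When the
    induced current is small relative to leak, the leak term dominates and
    the apparent block exceeds 100% even though the channel itself is fully
    blocked at most."""
    if ic <= 0:
        raise ValueError(f"induced current must be > 0, got {ic}")
    if lc < 0:
        raise ValueError(f"leak current must be >= 0, got {lc}")
    if not (0.0 <= f_channel <= 1.0 and 0.0 <= f_leak <= 1.0):
        raise ValueError("blocked fractions must lie in [0, 1]")
    return 100.0 * (f_channel * ic + f_leak * lc) / ic
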