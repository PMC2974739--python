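"""Reversal potentials and Ca2+/monovalent permeability ratios.

The permeability pipeline: estimate the reversal potential of a background-
subtracted biionic IV, apply the junction-potential correction exactly once,
calibrate the intracellular monovalent concentration from a reference
channel (or a published operating point), convert each cell's corrected
reversal potential to P_Ca/P_mono, and aggregate per condition as
mean ± SEM with an unpaired Student's t test for group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .biophysics import BiionicContext, PhysicalConstants, ghk_permeability_ratio
from .traces import IVRelation

__all__ = [
    "PermeabilityResult",
    "CalibrationRecord",
    "GroupStats",
    "NoReversalError",
    "estimate_reversal_potential",
    "correct_junction_potential",
    "compute_permeability_per_cell",
    "group_statistics",
    "compare_groups",
    "build_permeability_table",
    "significance_tier",
]


class NoReversalError(ValueError):
    """The IV relation does not cross zero inside the search window."""


@dataclass(frozen=True)
class CalibrationRecord:
    """Per-batch calibration of the intracellular monovalent concentration,
    obtained from a reference channel of known P_Ca/P_mono."""

    batch_id: str
    erev_ref_mv: float
    p_ref: float
    mono_i: float

    def __post_init__(self) -> None:
        if not self.mono_i > 0:
            raise ValueError(f"mono_i must be > 0, got {self.mono_i}")


@dataclass
class PermeabilityResult:
    """One condition's row of the permeability summary: reversal potential
    and P_Ca/P_mono as mean ± SEM with n, for one agonist condition."""

    condition: str
    agonist: str  # 'Gly' or 'Glu/Gly'
    erev_mean: float
    erev_sem: float
    p_ratio_mean: float
    p_ratio_sem: float
    n: int
    ca_o: float
    mono_i_used: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.p_ratio_mean > 0:
            raise ValueError("p_ratio_mean must be > 0")


@dataclass(frozen=True)
class GroupStats:
    mean: float
    sem: float
    n: int


def estimate_reversal_potential(
    iv: IVRelation,
    window: tuple[float, float] = (-120.0, 0.0),
) -> float:
    """Reversal potential of an IV relation by linear interpolation.

    Finds zero crossings of the current inside the search window (default
    -120 to 0 mV, bracketing every plausible biionic reversal) and
    interpolates linearly between the bracketing grid points.  If several
    crossings exist — noise can produce spurious ones — the crossing closest
    to the window's current-magnitude minimum is returned and a warning is
    emitted.
    """
    mask = (iv.voltage >= window[0]) & (iv.voltage <= window[1])
    v = iv.voltage[mask]
    i = iv.current[mask]
    if v.size < 2:
        raise NoReversalError(
            f"search window {window} contains fewer than two grid points"
        )
    sign = np.sign(i)
    # treat exact zeros as crossings at the grid point itself
    crossings: list[float] = [float(v[k]) for k in np.flatnonzero(sign == 0)]
    idx = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    for k in idx:
        frac = i[k] / (i[k] - i[k + 1])
        crossings.append(float(v[k] + frac * (v[k + 1] - v[k])))
    if not crossings:
        raise NoReversalError(
            f"no zero crossing between {window[0]} and {window[1]} mV"
        )
    if len(crossings) > 1:
        v_min = float(v[np.argmin(np.abs(i))])
        crossings.sort(key=lambda c: abs(c - v_min))
        warnings.warn(
            f"{len(crossings)} zero crossings in window; returning the one "
            f"closest to the |I| minimum at {v_min:.1f} mV",
            stacklevel=2,
        )
    return crossings[0]


def correct_junction_potential(
    erev_measured_mv: float, junction_potential_mv: float = -4.5
) -> float:
    """Add the liquid-junction potential to a measured reversal potential.

    With the default of -4.5 mV the corrected value is 4.5 mV more negative
    than measured.  The pipeline applies this exactly once per cell and
    records a provenance flag; double correction is a bookkeeping error."""
    if not (np.isfinite(erev_measured_mv) and np.isfinite(junction_potential_mv)):
        raise ValueError("inputs must be finite")
    return erev_measured_mv + junction_potential_mv


def compute_permeability_per_cell(
    erev_corrected_mv: float,
    calibration: CalibrationRecord,
    ca_o: float,
    constants: PhysicalConstants | None = None,
) -> float:
    """P_Ca/P_mono for one cell from its junction-corrected reversal
    potential, using the batch's calibrated mono_i."""
    if constants is None:
        constants = PhysicalConstants()
    ctx = BiionicContext(mono_i=calibration.mono_i, ca_o=ca_o, constants=constants)
    return ghk_permeability_ratio(erev_corrected_mv, ctx)


def group_statistics(values) -> GroupStats:
    """Mean, SEM (sample SD / sqrt(n)) and n of one group of per-cell
    values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values for an SEM, got {arr.size}")
    return GroupStats(
        mean=float(arr.mean()),
        sem=float(arr.std(ddof=1) / np.sqrt(arr.size)),
        n=int(arr.size),
    )


def compare_groups(values_a, values_b, equal_var: bool = True):
    """Two-sided unpaired Student's t test between two groups of per-cell
    values (pooled variance by default; ``equal_var=False`` for Welch).

    Returns ``(stats_a, stats_b, t, p)``."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    sa, sb = group_statistics(a), group_statistics(b)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return sa, sb, float(t), float(p)


def significance_tier(p: float) -> str:
    """Significance marker at the conventional 0.05 / 0.01 / 0.005 tiers."""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def build_permeability_table(
    per_cell: pd.DataFrame,
    condition_order,
    calibration: CalibrationRecord,
    ca_o: float,
) -> list[PermeabilityResult]:
    """Aggregate per-cell (condition, agonist, erev, p_ratio) records into
    one summary row per condition and agonist.

    ``per_cell`` needs columns ``condition``, ``agonist``, ``erev_mv`` and
    ``p_ratio``.  Rows are emitted in the configured condition order;
    conditions present in the data but absent from the order are a
    configuration error.  An empty (condition, agonist) subgroup yields no
    row — missing, never zero."""
    required = {"condition", "agonist", "erev_mv", "p_ratio"}
    missing = required - set(per_cell.columns)
    if missing:
        raise ValueError(f"per-cell table lacks columns: {sorted(missing)}")
    unknown = set(per_cell["condition"]) - set(condition_order)
    if unknown:
        raise KeyError(f"conditions not in configured order: {sorted(unknown)}")
    results: list[PermeabilityResult] = []
    for condition in condition_order:
        sub_c = per_cell[per_cell["condition"] == condition]
        for agonist in ("Gly", "Glu/Gly"):
            sub = sub_c[sub_c["agonist"] == agonist]
            if sub.empty:
                continue
            erev = sub["erev_mv"].to_numpy(dtype=float)
            ratio = sub["p_ratio"].to_numpy(dtype=float)
            n = len(sub)
            sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            results.append(
                PermeabilityResult(
                    condition=condition,
                    agonist=agonist,
                    erev_mean=float(erev.mean()),
                    erev_sem=sem(erev),
                    p_ratio_mean=float(ratio.mean()),
                    p_ratio_sem=sem(ratio),
                    n=n,
                    ca_o=ca_o,
                    mono_i_used=calibration.mono_i,
                )
            )
    return results
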