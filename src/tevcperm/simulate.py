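"""Synthetic two-electrode voltage-clamp (TEVC) data generator.

Produces oocyte-like current sweeps from a fully known generative model so
that every downstream stage — background subtraction, reversal-potential
estimation, percent block — can be tested against ground truth.

The generative current at true membrane potential Vm is

    I(Vm) = g_leak * (Vm - E_leak)
          + gain * expression * efficacy(agonists) * b(Vm) * sum_s GHK_s(Vm)
          + noise,

where the GHK sum runs over a lumped monovalent pool (z = +1) and Ca2+
(z = +2) with relative permeabilities 1 and ``pca_over_pmono``, ``b`` is the
Woodhull unblocked fraction for the Mg2+ concentration of the bath, and
efficacy maps the solution's agonist set to a fraction of maximal
activation.  Leak in µS times mV gives nA directly; inward current is
negative.

Two protocols are modelled: voltage ramps (2 s, -150 to +50 mV by default)
and timed solution applications at a fixed holding potential with
first-order solution-exchange smoothing.  An electrode junction potential
can be emulated: the recorded command voltage then reads
``Vm - junction_potential``, so the measured reversal potential is offset
until the analysis pipeline applies the correction.

Randomness is hierarchical: one root seed per batch, one spawned stream per
cell and per sweep, so any single sweep is reproducible in isolation from
the seed recorded in its metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .biophysics import (
    ION_CHARGE,
    PhysicalConstants,
    SolutionSpec,
    WoodhullParams,
    ghk_current_density,
    woodhull_unblocked_fraction,
)

__all__ = [
    "ChannelModel",
    "OocyteModel",
    "Protocol",
    "TraceRecording",
    "ExperimentDesign",
    "channel_current",
    "analytic_reversal_potential",
    "simulate_ramp_sweep",
    "simulate_application_sweep",
    "generate_batch",
]


@dataclass(frozen=True)
class ChannelModel:
    """Generative description of one receptor population.

    ``pca_over_pmono`` is the ground-truth Ca2+/monovalent permeability
    ratio the pipeline should recover; ``max_conductance_scale`` converts
    GHK current density to nA; ``agonist_efficacy`` maps a canonical agonist
    key (sorted names joined by '+', e.g. ``'glutamate+glycine'``) to the
    fraction of maximal activation.
    """

    pca_over_pmono: float = 2.3
    max_conductance_scale: float = 1.0
    agonist_efficacy: Mapping[str, float] = field(
        default_factory=lambda: {"glycine": 0.06, "glutamate+glycine": 1.0}
    )
    relative_permeabilities: Mapping[str, float] = field(default_factory=dict)
    block: WoodhullParams | None = None
    desensitization_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.max_conductance_scale < 0:
            raise ValueError("max_conductance_scale must be >= 0")
        if self.pca_over_pmono < 0:
            raise ValueError("pca_over_pmono must be >= 0")
        for key, eff in self.agonist_efficacy.items():
            if not 0.0 <= eff <= 1.0:
                raise ValueError(f"efficacy for {key!r} outside [0, 1]: {eff}")
        if self.desensitization_rate < 0:
            raise ValueError("desensitization_rate must be >= 0")

    def efficacy(self, solution: SolutionSpec) -> float:
        return float(self.agonist_efficacy.get(solution.agonist_key, 0.0))


@dataclass(frozen=True)
class OocyteModel:
    """Cell-level properties: ohmic leak, cytosolic ion pools, expression
    level and recording noise."""

    leak_conductance: float = 1.0  # µS
    leak_reversal: float = -20.0  # mV
    internal_concentrations: Mapping[str, float] = field(
        default_factory=lambda: {"Mono": 89.4, "Ca": 0.0}
    )
    expression_scale: float = 1.0
    noise_sd: float = 5.0  # nA
    endogenous_contamination_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.leak_conductance < 0:
            raise ValueError("leak_conductance must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.endogenous_contamination_fraction <= 1.0:
            raise ValueError("endogenous_contamination_fraction outside [0, 1]")


@dataclass(frozen=True)
class Protocol:
    """Acquisition protocol: a voltage ramp or a timed application series."""

    kind: str = "ramp"
    name: str = ""
    hold_mv: float = -70.0
    ramp_span: tuple[float, float] = (-150.0, 50.0)
    ramp_duration_s: float = 2.0
    sample_rate_hz: float = 2000.0
    application_timeline: tuple[tuple[str, float], ...] = ()
    exchange_tau_s: float = 1.0
    junction_potential_mv: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ramp", "application"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.ramp_duration_s <= 0:
            raise ValueError("ramp_duration_s must be > 0")
        if self.sample_rate_hz < 100:
            raise ValueError("sample_rate_hz must be >= 100")
        for label, dur in self.application_timeline:
            if dur <= 0:
                raise ValueError(f"timeline segment {label!r} has duration {dur}")


@dataclass
class TraceRecording:
    """One sweep: sampled time, recorded command voltage and current, plus
    acquisition metadata (cell id, protocol, solutions, seed, units)."""

    time: np.ndarray  # s
    command_voltage: np.ndarray  # mV (recorded axis, junction uncorrected)
    current: np.ndarray  # nA
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.command_voltage) == len(self.current)):
            raise ValueError("sample vectors must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def _ion_pools(
    solution: SolutionSpec, internal: Mapping[str, float],
    rel_perm: Mapping[str, float],
) -> tuple[float, float, float, float]:
    """Lump permeant monovalents into one pool; return
    (mono_in, mono_out, ca_in, ca_out) with per-species permeability weights
    applied to the external monovalents."""
    mono_out = 0.0
    ca_out = 0.0
    for sp, conc in solution.ion_concentrations.items():
        z = ION_CHARGE.get(sp)
        if z == 1:
            mono_out += rel_perm.get(sp, 1.0) * conc
        elif z == 2 and sp == "Ca":
            ca_out += conc
    mono_in = sum(
        rel_perm.get(sp, 1.0) * c
        for sp, c in internal.items()
        if ION_CHARGE.get(sp) == 1
    )
    ca_in = float(internal.get("Ca", 0.0))
    return mono_in, mono_out, ca_in, ca_out


def channel_current(
    v_mv,
    channel: ChannelModel,
    solution: SolutionSpec,
    oocyte: OocyteModel,
    constants: PhysicalConstants | None = None,
    apply_block: bool = True,
):
    """Gated channel current (nA, per unit efficacy and expression) at true
    membrane potential ``v_mv``; raises if the bath carries no permeant ion
    while the channel has nonzero gain."""
    if constants is None:
        constants = PhysicalConstants()
    mono_in, mono_out, ca_in, ca_out = _ion_pools(
        solution, oocyte.internal_concentrations, channel.relative_permeabilities
    )
    if channel.max_conductance_scale > 0 and (mono_out + ca_out + mono_in + ca_in) == 0:
        raise ValueError(
            f"solution {solution.label!r} and cytosol carry no permeant ion"
        )
    i = ghk_current_density(v_mv, 1, mono_in, mono_out, 1.0, constants)
    if channel.pca_over_pmono > 0 and (ca_in > 0 or ca_out > 0):
        i = i + ghk_current_density(
            v_mv, 2, ca_in, ca_out, channel.pca_over_pmono, constants
        )
    i = channel.max_conductance_scale * i
    if apply_block and channel.block is not None:
        mg = float(solution.blockers.get("Mg", 0.0))
        params = replace(channel.block, blocker_conc=mg)
        i = i * woodhull_unblocked_fraction(v_mv, params, constants)
    return i


def analytic_reversal_potential(
    channel: ChannelModel,
    solution: SolutionSpec,
    oocyte: OocyteModel,
    constants: PhysicalConstants | None = None,
    bracket: tuple[float, float] = (-200.0, 200.0),
) -> float:
    """Ground-truth reversal potential: the root of the summed GHK current,
    found by bisection (block cancels at the zero and is ignored)."""
    lo, hi = bracket
    f = lambda v: float(
        channel_current(v, channel, solution, oocyte, constants, apply_block=False)
    )
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise ValueError("no reversal inside bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def _rng_from_seed(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_ramp_sweep(
    channel: ChannelModel,
    oocyte: OocyteModel,
    protocol: Protocol,
    solution: SolutionSpec,
    seed: int,
    constants: PhysicalConstants | None = None,
) -> TraceRecording:
    """Simulate one voltage-ramp sweep in a fixed bath solution.

    The recorded command voltage ramps linearly over ``ramp_span`` within
    ``ramp_duration_s``; the true membrane potential is the command plus the
    protocol's junction potential.  Identical seeds give bit-identical
    traces.
    """
    if protocol.kind != "ramp":
        raise ValueError(f"expected a ramp protocol, got {protocol.kind!r}")
    n = int(round(protocol.ramp_duration_s * protocol.sample_rate_hz))
    t = np.arange(n) / protocol.sample_rate_hz
    v_cmd = np.linspace(protocol.ramp_span[0], protocol.ramp_span[1], n)
    vm = v_cmd + protocol.junction_potential_mv
    if channel.max_conductance_scale > 0:
        mono_in, mono_out, ca_in, ca_out = _ion_pools(
            solution, oocyte.internal_concentrations,
            channel.relative_permeabilities,
        )
        if (mono_in + mono_out + ca_in + ca_out) == 0:
            raise ValueError(
                f"solution {solution.label!r} and cytosol carry no permeant ion"
            )
    i = oocyte.leak_conductance * (vm - oocyte.leak_reversal)
    eff = channel.efficacy(solution)
    if channel.max_conductance_scale > 0 and eff > 0:
        i = i + (
            eff
            * oocyte.expression_scale
            * channel_current(vm, channel, solution, oocyte, constants)
        )
    if oocyte.noise_sd > 0:
        i = i + _rng_from_seed(seed).normal(0.0, oocyte.noise_sd, size=n)
    else:
        i = np.asarray(i, dtype=float) + np.zeros(n)
    meta = {
        "protocol": "ramp",
        "protocol_name": protocol.name,
        "solutions": [solution.label],
        "seed": int(seed),
        "sample_rate_hz": protocol.sample_rate_hz,
        "junction_potential_mv": protocol.junction_potential_mv,
        "hold_mv": protocol.hold_mv,
        "units": {"time": "s", "command_voltage": "mV", "current": "nA"},
    }
    return TraceRecording(t, v_cmd, np.asarray(i, dtype=float), meta)


def simulate_application_sweep(
    channel: ChannelModel,
    oocyte: OocyteModel,
    protocol: Protocol,
    solutions: Mapping[str, SolutionSpec],
    seed: int,
    constants: PhysicalConstants | None = None,
) -> TraceRecording:
    """Simulate a timed solution-application sweep at the holding potential.

    Each timeline segment has a stationary target current (leak + gated,
    blocked channel current at the hold); the recorded current relaxes
    toward it with the protocol's solution-exchange time constant.
    Desensitization, if enabled on the channel, is an exponential sag of the
    channel component while agonist is continuously present.
    """
    if protocol.kind != "application":
        raise ValueError(f"expected an application protocol, got {protocol.kind!r}")
    if not protocol.application_timeline:
        raise ValueError("application protocol has an empty timeline")
    for label, _ in protocol.application_timeline:
        if label not in solutions:
            raise KeyError(f"timeline references undefined solution {label!r}")

    fs = protocol.sample_rate_hz
    vm = protocol.hold_mv + protocol.junction_potential_mv
    total = sum(d for _, d in protocol.application_timeline)
    n = int(round(total * fs))
    t = np.arange(n) / fs

    target = np.empty(n)
    leak = oocyte.leak_conductance * (vm - oocyte.leak_reversal)
    pos = 0
    agonist_elapsed = 0.0
    for label, dur in protocol.application_timeline:
        sol = solutions[label]
        m = int(round(dur * fs))
        m = min(m, n - pos)
        eff = channel.efficacy(sol)
        seg = np.full(m, leak)
        if channel.max_conductance_scale > 0 and eff > 0:
            i_chan = float(channel_current(vm, channel, sol, oocyte, constants))
            amp = eff * oocyte.expression_scale * i_chan
            if channel.desensitization_rate > 0:
                t_seg = agonist_elapsed + np.arange(m) / fs
                seg = seg + amp * np.exp(-channel.desensitization_rate * t_seg)
            else:
                seg = seg + amp
            agonist_elapsed += dur
        else:
            agonist_elapsed = 0.0
        target[pos : pos + m] = seg
        pos += m
    target[pos:] = target[pos - 1] if pos else leak

    # causal first-order solution-exchange filter, exact for piecewise-
    # constant targets; initial state = first target (bath equilibrated)
    alpha = 1.0 - math.exp(-1.0 / (fs * protocol.exchange_tau_s))
    from scipy.signal import lfilter

    i, _ = lfilter([alpha], [1.0, alpha - 1.0], target,
                   zi=np.array([(1.0 - alpha) * target[0]]))
    if oocyte.noise_sd > 0:
        i = i + _rng_from_seed(seed).normal(0.0, oocyte.noise_sd, size=n)

    v_cmd = np.full(n, protocol.hold_mv)
    meta = {
        "protocol": "application",
        "protocol_name": protocol.name,
        "solutions": [label for label, _ in protocol.application_timeline],
        "timeline": [[label, float(d)] for label, d in protocol.application_timeline],
        "seed": int(seed),
        "sample_rate_hz": fs,
        "junction_potential_mv": protocol.junction_potential_mv,
        "hold_mv": protocol.hold_mv,
        "units": {"time": "s", "command_voltage": "mV", "current": "nA"},
    }
    return TraceRecording(t, v_cmd, i, meta)


@dataclass(frozen=True)
class ExperimentDesign:
    """One condition's experiment description: which channel and cell model,
    which solutions exist, and which sweeps every cell records."""

    channel: ChannelModel
    oocyte: OocyteModel
    solutions: Mapping[str, SolutionSpec]
    ramp_sweeps: Sequence[tuple[Protocol, str]] = ()  # (protocol, solution label)
    application_sweeps: Sequence[Protocol] = ()
    expression_cv: float = 0.5
    condition: str = ""


def generate_batch(
    design: ExperimentDesign,
    n_cells: int,
    seed: int,
    constants: PhysicalConstants | None = None,
) -> dict[str, list[TraceRecording]]:
    """Simulate ``n_cells`` oocytes, each recording every sweep in the
    design.

    Per-cell expression scales are log-normal with unit mean and the
    configured coefficient of variation.  Seeding is hierarchical
    (root -> cell -> sweep) and every sweep's own integer seed is stored in
    its metadata, so a single sweep can be regenerated in isolation.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    root = np.random.SeedSequence(seed)
    cell_seqs = root.spawn(n_cells)
    batch: dict[str, list[TraceRecording]] = {}
    for ci, cseq in enumerate(cell_seqs):
        cell_id = f"{design.condition or 'cell'}-{ci:03d}"
        rng = np.random.default_rng(cseq)
        cv = design.expression_cv
        if cv > 0:
            sigma2 = math.log1p(cv * cv)
            scale = float(
                rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2))
            )
        else:
            scale = 1.0
        oocyte = replace(design.oocyte, expression_scale=scale)
        sweeps: list[TraceRecording] = []
        n_sweeps = len(design.ramp_sweeps) + len(design.application_sweeps)
        sweep_seeds = [
            int(s.generate_state(1)[0] % (2**31)) for s in cseq.spawn(n_sweeps)
        ]
        k = 0
        for protocol, sol_label in design.ramp_sweeps:
            tr = simulate_ramp_sweep(
                design.channel, oocyte, protocol,
                design.solutions[sol_label], sweep_seeds[k], constants,
            )
            tr.metadata.update(cell_id=cell_id, condition=design.condition,
                               expression_scale=scale)
            sweeps.append(tr)
            k += 1
        for protocol in design.application_sweeps:
            tr = simulate_application_sweep(
                design.channel, oocyte, protocol, design.solutions,
                sweep_seeds[k], constants,
            )
            tr.metadata.update(cell_id=cell_id, condition=design.condition,
                               expression_scale=scale)
            sweeps.append(tr)
            k += 1
        batch[cell_id] = sweeps
    return batch
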