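"""Experiment configuration: solutions, protocols, conditions, calibration.

A single YAML file (or the bundled default) describes everything a run
needs: solution recipes, the ramp and application protocols, one generative
channel model per receptor condition, the oocyte model, physical constants,
the calibration source for the intracellular monovalent concentration, and
seeds.  ``ExperimentConfig.from_dict`` validates that every protocol's
solution labels resolve and that exactly one calibration source is given.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .biophysics import PhysicalConstants, SolutionSpec, WoodhullParams, calibrate_mono_i
from .permeability import CalibrationRecord
from .simulate import ChannelModel, ExperimentDesign, OocyteModel, Protocol

__all__ = ["ExperimentConfig", "ConfigError", "default_config_dict", "load_config"]


class ConfigError(ValueError):
    """The experiment configuration is inconsistent."""


#: normal frog Ringer and the biionic Ca2+ Ringers, with agonist and blocker
#: variants built on top of them
def default_config_dict() -> dict:
    """The bundled default experiment: three receptor conditions whose
    generative parameters mirror characteristic wild-type and pore-mutant
    phenotypes, recorded with both protocols in NFR and 4 mM CaR."""
    nfr_ions = {"Na": 115.0, "K": 2.5, "Ca": 1.8}
    car4_ions = {"NMDG": 108.6, "Ca": 4.0}
    car8_ions = {"NMDG": 114.2, "Ca": 8.0}
    gly = {"glycine": 10.0}
    glugly = {"glutamate": 100.0, "glycine": 10.0}
    return {
        "temperature_K": 293.15,
        "junction_potential_mv": -4.5,
        "seed": 1,
        "n_cells": 5,
        "calibration": {
            # reference operating point: biionic reversal potential and known
            # P_Ca/P_mono of a calibration channel in 4 mM CaR
            "reference": {"erev_mv": -29.3, "p_ref": 2.3, "ca_o": 4.0},
        },
        "solutions": {
            "NFR": {"ions": nfr_ions, "pH": 7.2},
            "NFR+Gly": {"ions": nfr_ions, "pH": 7.2, "agonists": gly},
            "NFR+Glu/Gly": {"ions": nfr_ions, "pH": 7.2, "agonists": glugly},
            "NFR+Gly+Mg": {"ions": nfr_ions, "pH": 7.2, "agonists": gly,
                           "blockers": {"Mg": 0.5}},
            "NFR+Glu/Gly+Mg": {"ions": nfr_ions, "pH": 7.2, "agonists": glugly,
                               "blockers": {"Mg": 0.5}},
            "4CaR": {"ions": car4_ions, "pH": 7.2},
            "4CaR+Gly": {"ions": car4_ions, "pH": 7.2, "agonists": gly},
            "4CaR+Glu/Gly": {"ions": car4_ions, "pH": 7.2, "agonists": glugly},
            "8CaR": {"ions": car8_ions, "pH": 7.2},
        },
        "protocols": {
            "ramp": {"span_mv": [-150.0, 50.0], "duration_s": 2.0,
                     "sample_rate_hz": 1000.0},
            "application": {
                "hold_mv": -70.0, "sample_rate_hz": 500.0,
                "exchange_tau_s": 1.0,
                # wash, 20 s agonist, 20 s agonist + 0.5 mM Mg2+, agonist, wash
                "segments_s": [5.0, 20.0, 20.0, 10.0, 5.0],
            },
        },
        "oocyte": {
            "leak_uS": 1.0, "leak_reversal_mv": -20.0, "noise_sd_nA": 5.0,
            "mono_i_mM": 89.37, "expression_cv": 0.5,
        },
        "conditions": {
            # conventional NMDAR: glutamate/glycine-gated, Ca2+ permeable,
            # strongly Mg2+ blocked
            "NR1-3a/NR2B": {
                "pca_over_pmono": 2.3, "gain_nA": 50.0,
                "efficacy": {"glycine": 0.06, "glutamate+glycine": 1.0},
                "block": {"kd0_mM": 1.09, "zdelta": 1.0},
            },
            # NR1 N-site glycine mutant: halved Ca2+ permeability, weakened
            # block
            "NR1-3a(GS)/NR2B": {
                "pca_over_pmono": 1.1, "gain_nA": 120.0,
                "efficacy": {"glycine": 0.05, "glutamate+glycine": 1.0},
                "block": {"kd0_mM": 6.3, "zdelta": 1.0},
            },
            # excitatory glycine receptor: fully glycine-gated, barely Ca2+
            # permeable, unblocked
            "NR1-3a/NR3B": {
                "pca_over_pmono": 0.4, "gain_nA": 4.0,
                "efficacy": {"glycine": 1.0, "glutamate+glycine": 1.0},
                "block": None,
            },
        },
    }


def _solution_from_dict(label: str, d: Mapping) -> SolutionSpec:
    return SolutionSpec(
        label=label,
        ion_concentrations=dict(d.get("ions", {})),
        pH=float(d.get("pH", 7.2)),
        agonists=dict(d.get("agonists", {})),
        blockers=dict(d.get("blockers", {})),
    )


@dataclass
class ExperimentConfig:
    """Validated experiment description, ready for the pipeline."""

    constants: PhysicalConstants
    junction_potential_mv: float
    seed: int
    n_cells: int
    solutions: dict[str, SolutionSpec]
    conditions: dict[str, ChannelModel]
    oocyte: OocyteModel
    expression_cv: float
    ramp_protocol: Protocol
    application_segments: list[float]
    application_protocol_template: Protocol
    calibration: CalibrationRecord
    ca_o: float
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        constants = PhysicalConstants(T=float(d.get("temperature_K", 293.15)))
        jp = float(d.get("junction_potential_mv", -4.5))

        solutions = {
            label: _solution_from_dict(label, sd)
            for label, sd in d.get("solutions", {}).items()
        }
        if not solutions:
            raise ConfigError("no solutions defined")

        cal = d.get("calibration", {})
        has_explicit = "mono_i_mM" in cal
        has_ref = "reference" in cal
        if has_explicit == has_ref:
            raise ConfigError(
                "calibration needs exactly one of 'mono_i_mM' or 'reference'"
            )
        if has_explicit:
            mono_i = float(cal["mono_i_mM"])
            record = CalibrationRecord("config", float("nan"), float("nan"), mono_i)
        else:
            ref = cal["reference"]
            mono_i = calibrate_mono_i(
                float(ref["erev_mv"]), float(ref["p_ref"]), float(ref["ca_o"]),
                constants,
            )
            record = CalibrationRecord(
                "reference", float(ref["erev_mv"]), float(ref["p_ref"]), mono_i
            )

        oo = d.get("oocyte", {})
        oocyte = OocyteModel(
            leak_conductance=float(oo.get("leak_uS", 1.0)),
            leak_reversal=float(oo.get("leak_reversal_mv", -20.0)),
            internal_concentrations={"Mono": float(oo.get("mono_i_mM", mono_i)),
                                     "Ca": 0.0},
            noise_sd=float(oo.get("noise_sd_nA", 5.0)),
        )

        conditions: dict[str, ChannelModel] = {}
        for label, cd in d.get("conditions", {}).items():
            block = cd.get("block")
            conditions[label] = ChannelModel(
                pca_over_pmono=float(cd["pca_over_pmono"]),
                max_conductance_scale=float(cd.get("gain_nA", 1.0)),
                agonist_efficacy=dict(cd.get("efficacy", {})),
                block=(
                    WoodhullParams(
                        kd0=float(block["kd0_mM"]),
                        zdelta=float(block["zdelta"]),
                        blocker_conc=0.0,
                    )
                    if block
                    else None
                ),
            )
        if not conditions:
            raise ConfigError("no receptor conditions defined")

        pr = d.get("protocols", {}).get("ramp", {})
        ramp = Protocol(
            kind="ramp",
            name="ramp",
            ramp_span=tuple(pr.get("span_mv", (-150.0, 50.0))),
            ramp_duration_s=float(pr.get("duration_s", 2.0)),
            sample_rate_hz=float(pr.get("sample_rate_hz", 1000.0)),
            junction_potential_mv=jp,
        )
        pa = d.get("protocols", {}).get("application", {})
        segments = [float(x) for x in pa.get("segments_s", [5, 20, 20, 10, 5])]
        if len(segments) != 5:
            raise ConfigError("application protocol needs 5 segment durations")
        app_template = Protocol(
            kind="application",
            name="application",
            hold_mv=float(pa.get("hold_mv", -70.0)),
            sample_rate_hz=float(pa.get("sample_rate_hz", 500.0)),
            exchange_tau_s=float(pa.get("exchange_tau_s", 1.0)),
            application_timeline=(("NFR", 1.0),),  # replaced per agonist
            junction_potential_mv=jp,
        )

        cfg = cls(
            constants=constants,
            junction_potential_mv=jp,
            seed=int(d.get("seed", 0)),
            n_cells=int(d.get("n_cells", 5)),
            solutions=solutions,
            conditions=conditions,
            oocyte=oocyte,
            expression_cv=float(oo.get("expression_cv", 0.5)),
            ramp_protocol=ramp,
            application_segments=segments,
            application_protocol_template=app_template,
            calibration=record,
            ca_o=float(solutions["4CaR"].ion_concentrations["Ca"])
            if "4CaR" in solutions else 4.0,
            raw=dict(d),
        )
        cfg._validate()
        return cfg

    def _validate(self) -> None:
        for label in ("NFR", "NFR+Gly", "NFR+Glu/Gly", "NFR+Gly+Mg",
                      "NFR+Glu/Gly+Mg", "4CaR", "4CaR+Gly", "4CaR+Glu/Gly"):
            if label not in self.solutions:
                raise ConfigError(f"required solution {label!r} is not defined")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")

    def application_protocol(self, agonist: str) -> Protocol:
        """Timed application sweep for one agonist condition ('Gly' or
        'Glu/Gly'): wash, agonist, agonist + Mg2+, agonist, wash."""
        if agonist not in ("Gly", "Glu/Gly"):
            raise ConfigError(f"unknown agonist condition {agonist!r}")
        s = self.application_segments
        base = f"NFR+{agonist}"
        timeline = (
            ("NFR", s[0]), (base, s[1]), (f"{base}+Mg", s[2]),
            (base, s[3]), ("NFR", s[4]),
        )
        from dataclasses import replace

        return replace(
            self.application_protocol_template,
            name=f"app_{'gly' if agonist == 'Gly' else 'glugly'}",
            application_timeline=timeline,
        )

    def design_for(self, condition: str) -> ExperimentDesign:
        """Full per-cell sweep plan for one condition: biionic ramps
        (control, agonist, control — for both agonist sets) plus the two
        application sweeps."""
        if condition not in self.conditions:
            raise ConfigError(f"unknown condition {condition!r}")
        from dataclasses import replace

        ramps = []
        for agonist, sol in (("gly", "4CaR+Gly"), ("glugly", "4CaR+Glu/Gly")):
            for tag, lab in (("ctrl_pre", "4CaR"), ("agonist", sol),
                             ("ctrl_post", "4CaR")):
                ramps.append(
                    (replace(self.ramp_protocol, name=f"ramp_{agonist}_{tag}"), lab)
                )
        apps = [self.application_protocol("Gly"),
                self.application_protocol("Glu/Gly")]
        return ExperimentDesign(
            channel=self.conditions[condition],
            oocyte=self.oocyte,
            solutions=self.solutions,
            ramp_sweeps=ramps,
            application_sweeps=apps,
            expression_cv=self.expression_cv,
            condition=condition,
        )

    def config_hash(self) -> str:
        """Stable short hash of the raw configuration, stamped on artifacts."""
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path=None) -> ExperimentConfig:
    """Load a YAML experiment configuration, or the bundled default."""
    if path is None:
        return ExperimentConfig.from_dict(default_config_dict())
    with open(Path(path)) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh))
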