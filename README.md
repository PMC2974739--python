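# tevcperm

Quantitative analysis of two-electrode voltage-clamp (TEVC) recordings from
*Xenopus* oocytes expressing wild-type and pore-mutant NMDA-receptor
diheteromers: Ca²⁺/monovalent permeability ratios from biionic reversal
potentials via a calibrated Goldman–Hodgkin–Katz (GHK) equation, and percent
voltage-dependent Mg²⁺ block from timed agonist/blocker applications.
Because no raw recordings are deposited for this class of experiment, the
package ships a synthetic TEVC generator with fully known ground truth, so
every processing stage — background subtraction, reversal-potential
estimation, junction correction, GHK conversion, block quantification — is
validated by parameter recovery.

## The model

With Ca²⁺ as the only putatively permeant extracellular cation (monovalents
replaced by impermeant NMDG) and the cytosol treated as a single lumped
monovalent pool, the GHK current equations for Ca²⁺ (z = +2) and the
monovalent (z = +1) sum to zero at the reversal potential E_rev, giving

P_Ca / P_mono = [Mono⁺]ᵢ · e^u · (e^u + 1) / (4 · [Ca²⁺]ₒ),  u = E_rev·F/(R·T)

with F = 9.65·10⁴ C·mol⁻¹, R = 8.314 J·mol⁻¹·K⁻¹ and T = 293.15 K by
default. [Mono⁺]ᵢ is calibrated per batch by inverting the same relation at
a reference channel of known P_Ca/P_mono; measured reversal potentials are
corrected for the −4.5 mV liquid-junction potential exactly once before
conversion. Voltage-dependent Mg²⁺ block is generated by a one-site
Woodhull model, f_unblocked(V) = Kd₀·e^(zδ·VF/RT) / (Kd₀·e^(zδ·VF/RT) + [Mg²⁺]),
and quantified within a single application sweep as
100·(I_control − I_Mg)/I_control. Apparent block above 100% is explained by
the leak/induced-current (LC/IC) decomposition
100·(f_channel·IC + f_leak·LC)/IC.

## Worked example

```python
from tevcperm import calibrate_mono_i, ghk_permeability_ratio
from tevcperm.biophysics import BiionicContext, PhysicalConstants

room = PhysicalConstants()  # T = 293.15 K
mono_i = calibrate_mono_i(erev_ref_mv=-29.3, p_ref=2.3, ca_o=4.0, constants=room)
print(f"[Mono+]i = {mono_i:.2f} mM")
ctx = BiionicContext(mono_i=mono_i, ca_o=4.0, constants=room)
for erev in (-44.7, -68.4, -23.1):
    print(f"Erev {erev} mV -> P_Ca/P_mono = {ghk_permeability_ratio(erev, ctx):.2f}")
```

prints

```
[Mono+]i = 89.38 mM
Erev -44.7 mV -> P_Ca/P_mono = 1.11
Erev -68.4 mV -> P_Ca/P_mono = 0.40
Erev -23.1 mV -> P_Ca/P_mono = 3.13
```

i.e. the calibration inverts the wild-type NR1-3a/NR2B glutamate/glycine
operating point to an intracellular monovalent concentration of ~89.4 mM,
and forward evaluation converts other measured reversal potentials to their
permeability ratios (1.1 for the NR1 N-site glycine mutant, 0.4 for the
Ca²⁺-impermeable wild-type glycine receptor, 3.1 for glycine-evoked
wild-type NMDAR currents).

## Analysis scripts

The numbered drivers under `analysis/` run the full synthetic study and
write their tables to `results/` (sweep bundles go to `scratch/`):

1. `01_simulate_cohort.py` — 5 oocytes × 3 receptor conditions, ramps and
   agonist/Mg²⁺ applications;
2. `02_process_traces.py` — per-cell amplitudes, percent block, response
   ratios and measured reversal potentials;
3. `03_permeability_tables.py` — junction correction, calibration, GHK
   conversion, per-condition summary (recovers the generative ratios
   2.3 / 1.1 / 0.4);
4. `04_block_analysis.py` — per-condition block summary and the LC/IC
   decomposition of apparent block > 100%;
5. `05_recompute_published_ratios.py` — forward-GHK recomputation of every
   published (E_rev, ratio) pair under one shared calibration, flagging the
   rows that do not regenerate.

The same pipeline is available as a CLI
(`tevcperm run --seed 1 --out results/run`) with subcommands `simulate`,
`process-iv`, `permeability`, `block` and `report`.

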