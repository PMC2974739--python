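# Methods

## Scope and data model

The package reconstructs, from voltage-clamp sweeps, the two quantitative
endpoints that characterize NMDA-receptor pore phenotypes in oocyte
expression work: the Ca²⁺/monovalent permeability ratio under biionic
conditions, and percent voltage-dependent Mg²⁺ block. A sweep
(`TraceRecording`) is sampled time, recorded command voltage and current
plus acquisition metadata; ramp sweeps become `IVRelation` objects on a
regular voltage grid; application sweeps yield baseline-subtracted plateau
amplitudes. Units are fixed at every interface: mV, nA, mM, seconds;
inward current is negative; depolarization is positive.

## Biionic GHK permeability ratio

Under a bath in which Ca²⁺ is the only putatively permeant extracellular
cation (monovalents replaced by NMDG) and assuming the cytosol contains
only monovalent cations of equal permeability, lumped at concentration
[Mono⁺]ᵢ, setting the summed GHK currents of Ca²⁺ (z = +2) and the
monovalent pool (z = +1) to zero at the reversal potential gives

    P_Ca/P_mono = [Mono]i · e^u · (e^u + 1) / (4 [Ca]o),   u = Erev F/(RT).

This relation is strictly increasing in Erev and exactly invertible for
[Mono⁺]ᵢ, which is how calibration works: a reference channel of known
P_Ca/P_mono is measured per oocyte batch and the relation is inverted at
its reversal potential. When no calibration sweep exists, [Mono⁺]ᵢ may be
supplied directly; the recomputation scripts obtain it by inverting one
published operating point (−29.3 mV at ratio 2.3 in 4 mM Ca²⁺, giving
89.4 mM). Defaults: F = 9.65·10⁴ C·mol⁻¹, R = 8.314 J·mol⁻¹·K⁻¹,
T = 293.15 K (room temperature, standard for oocyte TEVC; the value is
configurable), [Ca²⁺]ₒ = 4 mM. The 4 mM Ringer is the default permeability
condition because only it makes the published (Erev, ratio) pairs mutually
consistent at a single [Mono⁺]ᵢ near 89 mM; the 8 mM recipe is carried as
an alternate solution.

Reversal potentials are estimated from background-subtracted IVs by linear
interpolation between the grid points bracketing the zero crossing, with
the search window defaulting to −120…0 mV (all plausible biionic reversals
lie within it). Multiple crossings — possible under noise — resolve to the
crossing nearest the window's current-magnitude minimum, with a warning;
no crossing raises an error rather than guessing. The liquid-junction
correction adds the configured junction potential (default −4.5 mV, making
corrected values 4.5 mV more negative) exactly once per cell; per-cell
records carry a provenance flag so double correction is detectable.

Group values are means of per-cell quantities with SEM = SD/√n, and group
ratios are means of per-cell ratios, never the transform of the mean
reversal potential: the GHK relation is convex, so the two differ on
dispersed Erev samples (the regression suite demonstrates the direction of
that gap, which also explains why two published glycine-condition rows
cannot be regenerated from their printed mean reversal potentials under
any single calibration). Group comparisons use the classical
pooled-variance unpaired Student's t test (Welch available but off by
default) with significance tiers 0.05/0.01/0.005.

## Mg²⁺ block

Block is generated by a one-site Woodhull model: an extracellular cationic
blocker binding at fractional electrical depth δ with effective valence zδ
(dimensionless, bounded [0, 2]) and zero-voltage dissociation constant Kd₀
(mM), so Kd(V) = Kd₀·e^(zδ·VF/RT) and the unblocked fraction is
Kd/(Kd + [B]). Percent block is computed within a single application sweep
— plateau of the agonist segment vs plateau of the agonist + Mg²⁺ segment,
both baseline-subtracted against the pre-agonist wash — so slow drift
between sweeps cannot masquerade as block. Amplitudes are plateau means
over the last 25% of a segment (configurable to extremum); 20-s
applications reach steady state well within that window given the ~1 s
solution-exchange constant.

Apparent block above 100% is reproduced analytically by the leak/induced-
current decomposition: if the blocker suppresses fraction f_channel of the
agonist-induced current IC and fraction f_leak of the standing leak LC,
the measured block is 100·(f_channel·IC + f_leak·LC)/IC, which exceeds
100% exactly when f_leak·LC > (1 − f_channel)·IC — the regime of small
agonist responses and large LC/IC.

## Synthetic data generator

The generator emulates oocyte TEVC at the level the analysis needs:
agonist-gated GHK channel current (lumped monovalent pool plus Ca²⁺, with
the ground-truth P_Ca/P_mono as a model parameter), Woodhull block wired
to the bath's Mg²⁺ concentration, ohmic leak (µS·mV = nA), log-normal
per-cell expression scaling with configurable CV (default 0.5 — chosen as
a realistic oocyte-batch spread; the published per-condition SEMs imply
variability of this order), white Gaussian current noise, and an optional
junction-potential offset on the recorded voltage axis so the correction
step is exercised end to end. Two protocols are modelled: 2-s voltage
ramps from −150 to +50 mV (≥ 1 kHz default sampling) and timed application
series at a −70 mV hold (wash / agonist 20 s / agonist + 0.5 mM Mg²⁺ 20 s /
agonist / wash), with solution exchange as a causal first-order filter
(default τ = 1 s, representing superfusion at a few ml/min). Agonist
concentrations follow the standard recipes (10 µM glycine, 100 µM
glutamate in normal frog Ringer; 108.6 mM NMDG + 4 mM CaCl₂ biionic
Ringer).

Deliberately not modelled: Markov gating kinetics and single-channel
noise, capacitive and 50 Hz artifacts, Ca²⁺-activated Cl⁻ currents (EGTA
pretreatment is assumed effective and recorded as metadata), proton
inhibition (pH is metadata only), and the post-wash rebound of some mutant
combinations (a single-exponential desensitization sag is available but
off by default, since the phenomenon is qualitative). Passing recovery
tests therefore shows the analysis is correct for GHK-type currents with
ohmic leak and stationary noise — not that it is robust to every artifact
of real recordings.

Randomness is hierarchical (root seed → per-cell → per-sweep via
`numpy.random.SeedSequence.spawn`); each sweep's own integer seed is
stored in its metadata so any single sweep regenerates in isolation.

## Numerical choices

The GHK current's removable singularity at V = 0 is evaluated by its
analytic limit P·z·F·(cᵢ − cₒ) below |zFV/RT| < 10⁻⁹. Ramps are binned
onto a 1-mV grid by within-bin averaging before subtraction, making
pointwise arithmetic across sweeps well-defined. Normalization divides by
the linearly interpolated current at +20 mV and rejects curves whose
reference current is below an epsilon (degenerate normalization) instead
of amplifying noise. Calibration inversion is exact algebra; the round
trip holds to < 10⁻⁹ relative error across [10, 300] mM. The bundled
default run uses 5 cells × 3 conditions at 1 kHz ramp / 500 Hz application
sampling — sizes chosen so the whole synthetic study and its tests run
comfortably on a laptop while leaving all statistical checks well
powered.

## Known limitations

Permeability ratios assume exactly two permeant pools (Ca²⁺ vs lumped
monovalents); multi-ion or anomalous-mole-fraction behaviour is out of
scope, as are Eyring-style pore models and temperature dependence of
permeabilities. The block model is a single-site Boltzmann without
permeant block or trapping. Published current amplitudes and SEMs cannot
be reproduced without the raw recordings; they are carried as reference
data, and the machinery that would process such recordings is validated
on synthetic ground truth instead.
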