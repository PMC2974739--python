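"""Published whole-cell measurements for wild-type and pore-mutant
NMDA-receptor diheteromers expressed in Xenopus oocytes.

These tables are inputs to the recomputation pipeline, not outputs of it:
current amplitudes and Mg2+ block percentages (`AMPLITUDES_AND_BLOCK`) and
biionic reversal potentials with their Ca2+/monovalent permeability ratios
(`REVERSAL_AND_PERMEABILITY`), each as mean ± SEM with the number of oocytes.

Condition labels name the subunit combination; parenthesised letters are the
pore-loop point mutations at the N / N+1 sites (e.g. NR1-3a(GS) carries the
NR3-like glycine-serine pair, NR2B(GN) the glycine at its N site).

All reversal potentials are junction-corrected as published (in mV); ratios
are dimensionless; amplitudes in nA; block in percent of the agonist-evoked
current.  Recording conditions for the permeability rows: 4 mM Ca2+ Ringer
(monovalents replaced by NMDG), T taken as 293.15 K.
"""

from __future__ import annotations

import pandas as pd

#: extracellular Ca2+ (mM) of the biionic Ringer the reversal potentials
#: were recorded in
CA_O_MM = 4.0

#: junction potential (mV) applied to measured reversal potentials
JUNCTION_POTENTIAL_MV = -4.5

#: the operating point used to calibrate the intracellular monovalent
#: concentration when no per-batch calibration sweep is available: the
#: wild-type NR1-3a/NR2B glutamate/glycine row of the permeability table
CALIBRATION_ROW = {"condition": "NR1-3a/NR2B", "agonist": "Glu/Gly",
                   "erev_mv": -29.3, "p_ratio": 2.3}

_T1_ROWS = [
    # condition, I_gly (nA), sem, n, I_glugly, sem, n, block_gly (%), sem, n, block_glugly, sem, n
    ("NR1-3a/NR2B",          164,  38, 33,  2122,  328, 48, 125, 10, 20,  88,  3, 24),
    ("NR1-3a/NR2B(GN)",      827, 195, 11,  6959,  808, 11,  97, 25,  5,  71,  8,  7),
    ("NR1-3a(GS)/NR2B",      216,  43, 11,  5080, 1448, 12,  82, 12,  9,  56,  6,  8),
    ("NR1-3a(GS)/NR2B(GN)", 1764, 348, 11, 13076,  803, 11,  57,  5,  8,  25,  9,  8),
    ("NR1-3a/NR3B",          149,  27, 45,   171,   30, 45,   3,  1, 27,  13,  4, 15),
    ("NR1-3a/NR3B(NR)",      213,  62, 15,   258,   93, 15,  34,  8, 11,  30,  4, 11),
    ("NR1-3a/NR3B(GN)",      294,  42,  5,   476,   63,  5,  38,  6,  5,  46,  4,  5),
    ("NR1-3a/NR3B(NS)",      116,  68, 18,   170,   98, 18,   8,  8, 12,  31, 14, 15),
    ("NR1-3a(GS)/NR3B",      176,  64, 13,   200,   70, 13,  -3,  6,  9,  -4, 10, 10),
    ("NR1-3a(GS)/NR3B(NR)",  251,  79,  5,   361,   78,  5,  -3,  2,  5,   6,  3,  5),
    ("NR1-3a(GS)/NR3B(GN)",  579, 196,  5,   698,  194,  6,   5,  4,  5,   7,  3,  6),
    ("NR1-3a(GS)/NR3B(NS)",  252,  79,  5,   361,   78,  5,  -3,  2,  5,   6,  3,  5),
]

_T2_ROWS = [
    # condition, Erev_gly (mV), sem, n, P_gly, sem, Erev_glugly, sem, n, P_glugly, sem
    ("NR1-3a/NR2B",          -23.1,  3.93, 5, 3.1, 0.65, -29.3,  1.79, 5, 2.3, 0.21),
    ("NR1-3a/NR2B(GN)",      -15.3,  5.06, 5, 4.5, 1.02, -32.3,  2.73, 5, 2.0, 0.27),
    ("NR1-3a(GS)/NR2B",      -39.7,  2.05, 5, 1.4, 0.13, -44.7,  2.20, 5, 1.1, 0.10),
    ("NR1-3a(GS)/NR2B(GN)",  -46.8,  5.14, 5, 1.0, 0.18, -44.1,  1.24, 5, 1.1, 0.07),
    ("NR1-3a/NR3B",          -68.4,  5.65, 9, 0.4, 0.11, -64.9,  4.26, 8, 0.5, 0.11),
    ("NR1-3a/NR3B(NR)",      -34.7,  5.27, 9, 1.7, 0.61, -28.2,  1.71, 8, 2.5, 0.21),
    ("NR1-3a/NR3B(GN)",      -49.2,  7.66, 9, 0.4, 0.31, -36.3,  2.75, 8, 1.7, 0.21),
    ("NR1-3a/NR3B(NS)",      -46.8, 10.03, 5, 1.0, 0.57, -20.4,  4.74, 4, 2.5, 0.79),
    ("NR1-3a(GS)/NR3B",      -64.5, 12.62, 5, 0.2, 0.20, -76.2,  7.92, 5, 0.1, 0.07),
    ("NR1-3a(GS)/NR3B(NR)",  -83.1, 14.72, 5, 0.1, 0.13, -93.2, 10.33, 5, 0.1, 0.04),
    ("NR1-3a(GS)/NR3B(GN)",  -54.6,  7.02, 5, 0.3, 0.11, -59.5,  7.61, 5, 0.3, 0.07),
    ("NR1-3a(GS)/NR3B(NS)",  -38.0,  1.16, 5, 0.7, 0.03, -38.2,  2.74, 5, 0.7, 0.10),
]

AMPLITUDES_AND_BLOCK = pd.DataFrame(
    _T1_ROWS,
    columns=[
        "condition",
        "i_gly_na", "i_gly_sem", "i_gly_n",
        "i_glugly_na", "i_glugly_sem", "i_glugly_n",
        "block_gly_pct", "block_gly_sem", "block_gly_n",
        "block_glugly_pct", "block_glugly_sem", "block_glugly_n",
    ],
)

REVERSAL_AND_PERMEABILITY = pd.DataFrame(
    _T2_ROWS,
    columns=[
        "condition",
        "erev_gly_mv", "erev_gly_sem", "n_gly", "p_gly", "p_gly_sem",
        "erev_glugly_mv", "erev_glugly_sem", "n_glugly", "p_glugly", "p_glugly_sem",
    ],
)

#: permeability-table rows whose printed ratio is reproduced by forward GHK
#: evaluation of the printed reversal potential under the single calibration
#: above (condition, agonist, printed Erev, printed ratio, n)
GHK_CONSISTENT_ROWS = [
    ("NR1-3a(GS)/NR2B",     "Glu/Gly", -44.7, 1.1, 5),
    ("NR1-3a/NR2B(GN)",     "Glu/Gly", -32.3, 2.0, 5),
    ("NR1-3a(GS)/NR2B(GN)", "Glu/Gly", -44.1, 1.1, 5),
    ("NR1-3a/NR3B",         "Gly",     -68.4, 0.4, 9),
    ("NR1-3a/NR2B",         "Gly",     -23.1, 3.1, 5),
]

#: rows where the printed ratio is NOT the forward GHK value of the printed
#: mean reversal potential — consistent with per-batch calibration and with
#: averaging per-cell ratios rather than transforming the mean Erev
#: (condition, agonist, printed Erev, printed ratio, forward value rounded)
GHK_DISCREPANT_ROWS = [
    ("NR1-3a/NR3B(NR)", "Gly", -34.7, 1.7, 1.8),
    ("NR1-3a/NR3B(GN)", "Gly", -49.2, 0.4, 0.9),
]
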