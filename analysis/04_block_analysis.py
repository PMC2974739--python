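#!/usr/bin/env python
"""Percent Mg2+ block per condition, and why apparent block can exceed 100%.

Summarizes the within-sweep percent block of the simulated cohort (strongly
blocked wild-type-like NMDAR, partially blocked N-site mutant, unblocked
glycine receptor), then tabulates the leak/induced-current decomposition:
with the channel fully blocked, apparent block rises above 100% as soon as
the blocker also suppresses part of the standing leak and the agonist-
induced current (IC) is small relative to the leak (LC) — large LC/IC
ratios inflate apparent block, exactly the regime of small glycine-evoked
responses.  Writes results/block_table.tsv and
results/apparent_block_decomposition.tsv, plus the run report.
"""

import shutil
from pathlib import Path

import pandas as pd

from tevcperm.config import load_config
from tevcperm.pipeline import run_pipeline
from tevcperm.traces import apparent_block_decomposition

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "pipeline_run"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = load_config()
    run_pipeline(cfg, stages=("block", "report"), output_dir=RUN_DIR)
    RESULTS.mkdir(exist_ok=True)
    shutil.copy(RUN_DIR / "block_table.tsv", RESULTS / "block_table.tsv")
    block = pd.read_csv(RESULTS / "block_table.tsv", sep="\t", comment="#")
    print(block.round(2).to_string(index=False))

    rows = []
    for lc_over_ic in (0.0, 0.2, 0.5, 1.0, 2.0):
        ic = 100.0
        lc = lc_over_ic * ic
        rows.append({
            "lc_over_ic": lc_over_ic,
            "apparent_block_pct_fleak_0": apparent_block_decomposition(ic, lc, 1.0, 0.0),
            "apparent_block_pct_fleak_0.5": apparent_block_decomposition(ic, lc, 1.0, 0.5),
        })
    decomp = pd.DataFrame(rows)
    decomp.to_csv(RESULTS / "apparent_block_decomposition.tsv", sep="\t",
                  index=False)
    print("\nfully blocked channel, varying leak/induced-current ratio:")
    print(decomp.to_string(index=False))


if __name__ == "__main__":
    main()
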