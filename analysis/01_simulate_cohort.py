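#!/usr/bin/env python
"""Simulate the default synthetic cohort.

Generates five oocytes for each of the three bundled receptor conditions —
a conventional glutamate/glycine-gated NMDAR (P_Ca/P_mono 2.3, strong Mg2+
block), its NR1 N-site glycine mutant (ratio 1.1, weakened block) and an
excitatory glycine receptor (ratio 0.4, unblocked) — each recording six
biionic voltage ramps and two timed agonist/Mg2+ applications.  Trace
bundles land under scratch/pipeline_run/traces/ (columnar TSV + YAML
sidecars), ready for 02_process_traces.py.
"""

from pathlib import Path

from tevcperm.config import load_config
from tevcperm.pipeline import run_pipeline

RUN_DIR = Path(__file__).resolve().parent.parent / "scratch" / "pipeline_run"


def main() -> None:
    cfg = load_config()
    run_pipeline(cfg, stages=("simulate",), output_dir=RUN_DIR)
    n_sweeps = sum(1 for _ in RUN_DIR.glob("traces/*/*.tsv"))
    print(f"simulated {len(cfg.conditions)} conditions x {cfg.n_cells} cells "
          f"-> {n_sweeps} sweeps under {RUN_DIR}/traces "
          f"(seed {cfg.seed}, config {cfg.config_hash()})")


if __name__ == "__main__":
    main()
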