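#!/usr/bin/env python
"""Scale simulation studies of the SEM engine: standardized-coefficient
recovery, goodness-of-fit calibration and power, and bootstrap CI coverage
of a known indirect effect.  These are the same computations the acceptance
script performs; run here for exploration with configurable sizes.

Writes results/simulation_studies.json.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))
from acceptance import bootstrap_coverage, gof_calibration, parameter_recovery

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--reps", type=int, default=100)
ap.add_argument("--out", type=Path, default=Path("results/simulation_studies.json"))
args = ap.parse_args()

results = {}
results.update(parameter_recovery(args.seed, n_rep=args.reps))
results.update(gof_calibration(args.seed, n_null=max(args.reps, 200), n_power=args.reps))
results.update(bootstrap_coverage(args.seed, n_rep=args.reps))

args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(results, indent=2) + "\n")
print(json.dumps(results, indent=2))
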