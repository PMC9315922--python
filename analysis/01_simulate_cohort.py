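#!/usr/bin/env python
"""Generate the synthetic cohort the downstream analyses run on.

Writes germline FASTA, pre-aligned AIRR rearrangement TSV, clinical CSV and
the generator's truth table under results/simulated_cohort/.  Defaults: 2,000
patients, ~35% with zero somatic mutations, burdens 1-36, hazard of first
treatment decreasing by exp(-0.05) per mutation, ~38% censored.
"""

import argparse
from pathlib import Path

from mutspec.simulate import SimConfig, simulate_cohort

ap = argparse.ArgumentParser()
ap.add_argument("--n-patients", type=int, default=2000)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/simulated_cohort"))
args = ap.parse_args()

sim = simulate_cohort(SimConfig(n_patients=args.n_patients, seed=args.seed))
paths = sim.write(args.out)

t = sim.truth
print(f"simulated {len(t)} patients -> {args.out}")
print(f"  zero-mutation fraction: {(t.n_mut == 0).mean():.3f} (target 0.35)")
mutated = t[t.n_mut > 0]
print(f"  burden range among mutated: {mutated.n_mut.min()}-{mutated.n_mut.max()}")
print(f"  censored fraction: {1 - t.event.mean():.3f}")
print(f"  ratio groups (truth): {t.group.value_counts().to_dict()}")
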