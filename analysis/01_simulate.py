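#!/usr/bin/env python
"""Simulate the synthetic mediation study analysed by the later scripts.

One binary exposure with 143 instruments, three genuine mediators
(alpha, beta_m) = (0.5, 0.4), (0.3, 0.3), (0.2, 0.5), one mediator not
caused by the exposure and one with no direct outcome effect, and a binary
outcome with direct effect beta_d = 0.1. Writes the summary-statistics
tables, the identity LD matrix, and a truth sidecar under
results/simulated_study/.
"""

import json
from pathlib import Path

from mrmediate import MediatorSpec, simulate_study, write_sumstats
from mrmediate.instruments import write_ld_matrix

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated_study"
SEED = 11

SPECS = [
    MediatorSpec("m1", alpha=0.5, beta_m=0.4),
    MediatorSpec("m2", alpha=0.3, beta_m=0.3),
    MediatorSpec("m3", alpha=0.2, beta_m=0.5),
    MediatorSpec("null_step1", alpha=0.0, beta_m=0.4),
    MediatorSpec("null_step2", alpha=0.4, beta_m=0.0),
]
BETA_D = 0.1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    exposure, mediators, outcome, ld = simulate_study(SPECS, beta_d=BETA_D, seed=SEED)
    write_sumstats(exposure, OUT / "exposure.tsv")
    for name, table in mediators.items():
        write_sumstats(table, OUT / f"{name}.tsv")
    write_sumstats(outcome, OUT / "outcome.tsv")
    write_ld_matrix(ld, OUT / "ld.tsv")

    total = BETA_D + sum(s.alpha * s.beta_m for s in SPECS)
    truth = {
        "seed": SEED,
        "beta_d": BETA_D,
        "mediators": [
            {"name": s.name, "alpha": s.alpha,
             "beta_m": s.beta_m,
             "proportion": s.alpha * s.beta_m / total}
            for s in SPECS
        ],
        "total_effect": total,
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(f"wrote {len(SPECS) + 2} summary tables to {OUT}")
    print(f"true total effect {total:.3f}; "
          f"true combined proportion {(total - BETA_D) / total:.3f}")


if __name__ == "__main__":
    main()
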