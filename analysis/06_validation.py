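"""Simulation studies validating the statistical machinery.

Three repeated-seed experiments over the synthetic generator:

1. FDR null control — any-discovery rate of the pixel-wise t + BH stage on
   full-null map stacks should sit near the 5% level;
2. trait-intensity association — power at the calibrated ~0.2 population
   Spearman effect and type-I error with the effect off, at n = 419;
3. ZINB recovery — the zero-part coefficient of -0.3 should be recovered
   without bias at n = 2000.

Default seed counts keep the script quick; pass --full for the larger
replications used by the test suite.  Tables land under results/.
"""

import argparse

from embody.experiments import (
    fdr_null_experiment,
    intensity_association_experiment,
    zinb_recovery_experiment,
)
from study_config import RESULTS


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--full", action="store_true",
                        help="run the full replication counts (slower)")
    args = parser.parse_args()
    n_assoc = 100 if args.full else 25
    n_zinb = 50 if args.full else 15

    fdr = fdr_null_experiment(n_reps=200, base_seed=0)
    fdr.to_csv(RESULTS / "validation_fdr_null.csv", index=False)
    print(f"FDR null control: any-discovery rate {fdr.any_discovery.mean():.3f} "
          f"over {len(fdr)} full-null stacks (target ~0.05)")

    power = intensity_association_experiment(n_seeds=n_assoc, base_seed=0)
    power.to_csv(RESULTS / "validation_power.csv", index=False)
    print(f"trait-intensity power: detected in {power.detected.mean():.0%} "
          f"of {len(power)} cohorts (mean rho {power.rho.mean():.3f})")

    null = intensity_association_experiment(n_seeds=n_assoc, gamma_intensity=0.0,
                                            base_seed=1)
    null.to_csv(RESULTS / "validation_type1.csv", index=False)
    print(f"type-I error with the effect off: {null.rejected_two_sided.mean():.3f} "
          f"(target ~0.05)")

    zinb = zinb_recovery_experiment(n_seeds=n_zinb, base_seed=0)
    zinb.to_csv(RESULTS / "validation_zinb.csv", index=False)
    print(f"ZINB zero-part recovery: mean estimate {zinb.estimate.mean():.3f} "
          f"over {len(zinb)} fits (truth -0.3)")


if __name__ == "__main__":
    main()
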