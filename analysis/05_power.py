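"""Correlation power at the study's sample size.

Fisher-z power of the two-sided test of zero correlation at n = 419,
alpha = 0.05, and the inverse problem: the smallest correlation detectable
at 80% and 90% power.  Writes results/power.csv.
"""

import pandas as pd

from embody.stats import correlation_power, detectable_r
from study_config import RESULTS

N, ALPHA = 419, 0.05


def main():
    rows = [{"r": r, "n": N, "alpha": ALPHA, "power": correlation_power(r, N, ALPHA)}
            for r in (0.1, 0.137, 0.158, 0.2, 0.3)]
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "power.csv", index=False)
    print(table.round(3).to_string(index=False))
    for target in (0.80, 0.90):
        r = detectable_r(target, N, ALPHA)
        print(f"minimum correlation detectable at {target:.0%} power: r = {r:.3f}")


if __name__ == "__main__":
    main()
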