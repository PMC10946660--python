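#!/usr/bin/env python
"""Stationary-state structure of the ATP subsystem.

The intracellular ATP balance is a one-dimensional rate law at frozen
substrate; this script scans its fixed points over substrate levels for the
two documented regimes and writes the scan tables.  Finding: the bistable
configuration shows one stable zero state at low substrate and, for
S in a window around ~0.3, three states (stable zero / unstable threshold /
stable high-ATP); the monostable "working" configuration instead has an
unstable zero and exactly one stable positive ATP state at every substrate
level — the homeostatic regime a growing cell needs.
"""

import json
from pathlib import Path

import pandas as pd

from luxqs.energy import bistable_demo, monostable_demo, regime_scan

OUT = Path("results/energy_regimes")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, demo in (("bistable", bistable_demo()), ("monostable", monostable_demo())):
        report = regime_scan(demo.params, demo.growth, demo.config, demo.S_grid,
                             a_max=demo.a_max)
        (OUT / f"{name}_scan.json").write_text(json.dumps(report, indent=2))
        rows = [
            {"S": row["S"], "root": root, "stability": stab}
            for row in report["per_S"]
            for root, stab in row["roots"]
        ]
        pd.DataFrame(rows).to_csv(OUT / f"{name}_roots.csv", index=False)
        print(f"{name}: {report['summary']}")
        for row in report["per_S"]:
            pattern = "/".join(s for _, s in row["roots"])
            print(f"  S={row['S']:>5}: {row['n_roots']} state(s) [{pattern}]")


if __name__ == "__main__":
    main()
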