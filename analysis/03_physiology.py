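#!/usr/bin/env python
"""Derived physiology of the two reference flux maps.

Branch-point partitioning (F1P, 6PGN, ICIT, MAL), carbon balances and
biomass yields, ATP/NADH/NADPH balances (absolute and normalised to
uptake), and the wild-type-vs-mutant change map.  Writes tables under
results/physiology/.
"""
from pathlib import Path

import pandas as pd

from pfmfa.network import load_packaged_model
from pfmfa.physiology import (
    biomass_yield,
    branch_ratios,
    carbon_balance,
    change_map,
    cofactor_balance,
)
from pfmfa.synth import RATE_TABLES, reference_flux_map

OUT = Path(__file__).resolve().parents[1] / "results" / "physiology"

# metabolome fold-changes (mutant / wild type) reported for the same strains
POOL_CHANGES = {"succinate": 2.4, "F1P": 8.0}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    model = load_packaged_model()
    maps = {s: reference_flux_map(s, model).state for s in ("wt", "mut")}

    rows = []
    for strain in ("wt", "pre", "mut"):
        rs = RATE_TABLES[strain]
        y_full, y_round = biomass_yield(rs)
        rows.append(
            {"strain": strain, "uptake_c": rs.uptake_c[0], "biomass_c": rs.biomass_c[0],
             "co2_balance": carbon_balance(rs), "yield_pct": y_round}
        )
    pd.DataFrame(rows).to_csv(OUT / "rates_and_yields.csv", index=False)
    print(pd.DataFrame(rows).to_string(index=False))

    branch_rows = []
    for node in ("F1P", "PGN6", "ICIT", "MAL"):
        for strain, st in maps.items():
            try:
                df = branch_ratios(st, node)
            except ValueError:
                continue
            for _, r in df.iterrows():
                branch_rows.append(
                    {"node": node, "strain": strain, "reaction": r.reaction,
                     "flux": r.flux, "percent": r.percent_rounded}
                )
    pd.DataFrame(branch_rows).to_csv(OUT / "branch_points.csv", index=False)

    cof_rows = []
    for strain, st in maps.items():
        for normalised in (False, True):
            bal = cofactor_balance(st, normalise_by_uptake=normalised)
            cof_rows.append({"strain": strain, "normalised": normalised, **bal})
    cof = pd.DataFrame(cof_rows)
    cof.to_csv(OUT / "cofactor_balances.csv", index=False)
    print(cof.to_string(index=False))

    cm = change_map(maps["wt"], maps["mut"], POOL_CHANGES)
    cm.to_csv(OUT / "change_map.csv", index=False)
    changed = cm[cm["class"].isin(["increased", "decreased"])]
    print(f"{len(changed)} fluxes/pools beyond the 150%/50% thresholds")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
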