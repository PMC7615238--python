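#!/usr/bin/env python
"""Tabulate the solvent doses and PTZ threshold examples.

Writes results/dose_table.csv: the DMSO mass dose for each tested
concentration at 1.5 uL/g, the 10% / 10 uL/g diluted-stock case, and
worked PTZ seizure-threshold examples.
"""

from pathlib import Path

import pandas as pd

from ihkalfp.dosing import (
    DoseSpec,
    InfusionSpec,
    dmso_dose_mg_per_kg,
    infused_volume_ml,
    ptz_threshold_mg_per_kg,
    round_to_printed,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for conc, volume in [(1.0, 1.5), (10.0, 1.5), (30.0, 1.5), (100.0, 1.5),
                         (10.0, 10.0)]:
        dose = dmso_dose_mg_per_kg(DoseSpec(conc, volume))
        rows.append(
            {
                "concentration_pct_vv": conc,
                "volume_ul_per_g": volume,
                "dose_mg_per_kg": dose,
                "dose_mg_per_kg_printed": round_to_printed(dose),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "dose_table.csv", index=False)
    print(table.to_string(index=False))

    volume = infused_volume_ml(duration_s=60.0)
    threshold = ptz_threshold_mg_per_kg(InfusionSpec(volume, body_weight_g=25.0))
    print(
        f"\nPTZ example: 60 s at 100 uL/min -> {volume:.3f} mL infused; "
        f"threshold for a 25 g mouse: {threshold:.1f} mg/kg"
    )


if __name__ == "__main__":
    main()
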