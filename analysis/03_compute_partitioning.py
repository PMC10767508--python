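#!/usr/bin/env python
"""Turn the leaching observations into pooled partition coefficients:
Kd from the soil/water amount ratio normalised by mass and volume,
geometric-mean pooling over duplicates, LOD censoring flags, and Koc via
the organic-carbon fraction of each soil.

Reads results/fixtures/{leach,soils}.csv; writes results/partition.csv.
"""

from pathlib import Path

from soilfate import mobility, pedotransfer

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    observations = mobility.read_leach_csv(ROOT / "fixtures" / "leach.csv")
    soils = pedotransfer.soils_to_frame(
        pedotransfer.read_soils_csv(ROOT / "fixtures" / "soils.csv")
    )
    oc = {sid: mobility.som_to_oc(row["som"]) for sid, row in soils.iterrows()}
    table, log = mobility.partition_table(observations, oc_percent=oc)
    table.to_csv(ROOT / "partition.csv", index=False)

    print(f"{len(table)} pooled Kd values "
          f"({len(observations)} observations, {len(log)} without a Kd)")
    print(f"rough estimates (log10 Kd > 2): {int(table['rough_estimate'].sum())}")
    print("\nmedian log10 Kd / log10 Koc per compound:")
    summary = table.groupby("compound")[["log10_kd", "log10_koc"]].median()
    print(summary.round(2).to_string())


if __name__ == "__main__":
    main()
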