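#!/usr/bin/env python
"""Run the whole chain end to end through the pipeline orchestrator and
render the reproduction report: per-compound DT50 and log10 Kd ranges with
max/min ratios, the log10 Koc summary, the soil-property correlation
matrix and the best-fit model table.

Writes results/report.md (plus the stage CSVs) and prints the report.
"""

import warnings
from pathlib import Path

from soilfate import pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    warnings.simplefilter("ignore")
    config = pipeline.RunConfig(
        soils_csv=ROOT / "fixtures" / "soils.csv",
        decay_csv=ROOT / "fixtures" / "decay.csv",
        leach_csv=ROOT / "fixtures" / "leach.csv",
        outdir=ROOT,
    )
    report = pipeline.run_pipeline(config)
    print(report.to_markdown())


if __name__ == "__main__":
    main()
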