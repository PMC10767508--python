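#!/usr/bin/env python
"""Generate the synthetic study that stands in for the unpublished per-soil
measurements: 29 correlated soils, decay series for the eight compounds
with degradation data, and duplicate leaching columns for all nine.

Writes results/fixtures/{soils,decay,leach,truths}.csv.
"""

from pathlib import Path

from soilfate import synthetic as S

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "fixtures"
SEED = 0


def main() -> None:
    config = S.StudyConfig(soil=S.SoilGeneratorConfig(seed=SEED), seed=SEED)
    bundle = S.generate_study(config)
    paths = S.write_study_csvs(bundle, OUTDIR)
    print(f"soils:  {len(bundle.soils)} samples "
          f"({sum(s.depth_class == 'shallow' for s in bundle.soils)} shallow)")
    print(f"decay:  {len(bundle.decay)} series x 8 sampling days")
    print(f"leach:  {len(bundle.leach)} observations (duplicate columns)")
    print(f"truths: {len(bundle.truths)} soil x compound records")
    for name, path in paths.items():
        print(f"  -> {path}")


if __name__ == "__main__":
    main()
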