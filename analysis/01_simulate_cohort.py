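#!/usr/bin/env python
"""Generate the two synthetic studies every later stage consumes.

Writes ``results/data/cohort`` (the default study: 300 patients, planted
window-level linear law and survival effect) and ``results/data/spatial``
(the wide-spacing geometry used for distance-profile recovery: 50k cSNVs
and 50k dbSNVs against 120 well-separated G4s).
"""

from pathlib import Path

from g4snv.pipeline import run_simulate
from g4snv.simulate import SyntheticConfig, spatial_study_config

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    out = ROOT / "scratch" / "data"
    cohort = run_simulate(SyntheticConfig(seed=SEED), out / "cohort", force=True)
    spatial = run_simulate(spatial_study_config(seed=SEED), out / "spatial", force=True)
    print(f"cohort study : {len(cohort.csnvs)} cSNVs, {len(cohort.dbsnvs)} dbSNVs, "
          f"{len(cohort.g4s)} G4s, {len(cohort.patients)} patients")
    print(f"spatial study: {len(spatial.csnvs)} cSNVs, {len(spatial.dbsnvs)} dbSNVs, "
          f"{len(spatial.g4s)} G4s")
    print(f"written under {out}")


if __name__ == "__main__":
    main()
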