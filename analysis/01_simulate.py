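"""Simulate the study's molecule table.

Generates distinct low-molecular-weight organics (1-12 carbons) from the
fragment grammar, plants the additive group-contribution logS model with
Gaussian measurement noise, and appends deliberate exact duplicates and
conflicting re-measurements so the curation stage has real work to do.
Writes the raw table and the planted model sidecar under results/analysis/data.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import _common
from aqsol import synthetic


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=_common.MASTER_SEED)
    args = ap.parse_args()

    _common.DATA.mkdir(parents=True, exist_ok=True)
    smis = synthetic.generate_molecules(
        _common.N_MOLECULES, _common.MAX_CARBONS, seed=args.seed
    )
    planted = synthetic.PlantedModel(noise_sd=_common.NOISE_SD, seed=args.seed)
    records = synthetic.assign_logS(smis, planted)
    raw = synthetic.inject_duplicates(
        records, _common.N_EXACT_DUP, _common.N_CONFLICT, seed=args.seed
    )
    out = _common.DATA / "synthetic.csv"
    synthetic.write_simulation(raw, planted, out)

    print(f"wrote {len(raw)} rows ({len(records)} molecules + "
          f"{_common.N_EXACT_DUP} exact duplicates + {_common.N_CONFLICT} conflicts)")
    print(f"planted model: intercept {planted.intercept}, noise sd {planted.noise_sd}")
    for k, v in planted.coefficients.items():
        print(f"  {k:>14s}: {v:+.2f} log units per count")
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
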