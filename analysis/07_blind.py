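"""Blind test: predict molecules the models never saw.

Draws fresh grammar molecules disjoint from the curated training data,
assigns their noise-free planted logS as the reference value, and compares
the absolute-error profile of the descriptor RF vs the fingerprint RF.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import _common
from aqsol import descriptors, fingerprints, models, synthetic
from aqsol.pipeline import evaluate_blind

N_BLIND = 32


def main():
    ds = _common.curated_dataset()
    desc, fpm, y = _common.feature_matrices(ds)
    sp = models.split(len(y), _common.SPLIT_FRACTION, seed=_common.MASTER_SEED)
    tr = sp.train_idx
    rf_d = models.train_rf(desc.values.to_numpy(float)[tr], y[tr],
                           _common.RF_TREES, _common.RF_SEED)
    rf_f = models.train_rf(fpm.bits.astype(float)[tr], y[tr],
                           _common.RF_TREES, _common.RF_SEED)

    planted = synthetic.PlantedModel.from_json(
        _common.DATA / "synthetic.csv.planted.json"
    )
    truth = synthetic.PlantedModel(
        intercept=planted.intercept, coefficients=planted.coefficients,
        noise_sd=0.0, seed=0,
    )
    train_set = set(ds.smiles)
    pool = synthetic.generate_molecules(
        _common.N_MOLECULES + 500, _common.MAX_CARBONS, seed=_common.MASTER_SEED + 1
    )
    blind_smis = [s for s in pool if s not in train_set][:N_BLIND]
    blind = pd.DataFrame({
        "name": [f"blind_{i}" for i in range(len(blind_smis))],
        "smiles": blind_smis,
        "logS": [r.logS for r in synthetic.assign_logS(blind_smis, truth)],
    })

    def predict_desc(smiles_list):
        full = descriptors.compute_2d_descriptors(smiles_list)
        X = full.values.reindex(columns=desc.feature_names).to_numpy(float)
        return rf_d.predict(np.nan_to_num(X))

    def predict_fp(smiles_list):
        return rf_f.predict(fingerprints.compute_morgan(smiles_list).bits.astype(float))

    table, means = evaluate_blind(
        {"descriptors": predict_desc, "fingerprints": predict_fp}, blind, ds.smiles
    )
    table.to_csv(_common.RESULTS / "blind_results.csv", index=False)
    print(table.round(3).to_string(index=False))
    print(f"\nmean absolute error: descriptors {means['descriptors']:.3f}, "
          f"fingerprints {means['fingerprints']:.3f} log units over {len(blind)} molecules")


if __name__ == "__main__":
    main()
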