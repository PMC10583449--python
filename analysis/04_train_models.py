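"""Train and evaluate RF and MLR on both molecular representations.

One shared 80/20 split and one fixed RF configuration across all
comparisons. Also runs the LASSO penalty grid on the fingerprint bits and
refits both model families on the selected subset, giving the four-way
representation x model comparison table.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import _common
from aqsol import fingerprints, models


def main():
    ds = _common.curated_dataset()
    desc, fpm, y = _common.feature_matrices(ds)
    sp = models.split(len(y), _common.SPLIT_FRACTION, seed=_common.MASTER_SEED)
    tr, te = sp.train_idx, sp.test_idx
    Xd = desc.values.to_numpy(float)
    Xf = fpm.bits.astype(float)

    rows = []

    def record(rep, name, model, X):
        for part, idx in (("train", tr), ("test", te)):
            m = models.evaluate(model, X[idx], y[idx], part)
            rows.append({"representation": rep, "model": name, **m.as_dict()})

    record("descriptors", "RF", models.train_rf(Xd[tr], y[tr], _common.RF_TREES, _common.RF_SEED), Xd)
    record("descriptors", "MLR", models.train_mlr(Xd[tr], y[tr], desc.feature_names), Xd)
    record("fingerprint_2048", "RF", models.train_rf(Xf[tr], y[tr], _common.RF_TREES, _common.RF_SEED), Xf)

    sel = fingerprints.lasso_select(Xf[tr], y[tr])
    k = len(sel.selected_bit_ids)
    print("LASSO selection size per alpha:", sel.n_selected_per_alpha)
    print(f"chosen alpha {sel.chosen_alpha:g} -> {k} bits")
    Xs = Xf[:, sel.selected_bit_ids]
    names = [f"bit_{i}" for i in sel.selected_bit_ids]
    record(f"fingerprint_{k}_selected", "RF",
           models.train_rf(Xs[tr], y[tr], _common.RF_TREES, _common.RF_SEED), Xs)
    record(f"fingerprint_{k}_selected", "MLR", models.train_mlr(Xs[tr], y[tr], names), Xs)

    table = pd.DataFrame(rows)
    table.to_csv(_common.RESULTS / "metrics.csv", index=False)
    print(table.pivot_table(index=["representation", "model"], columns="partition",
                            values=["r2", "rmse", "mae"]).round(3).to_string())
    test = table[table.partition == "test"]
    best = test.loc[test.rmse.idxmin()]
    print(f"\nbest test RMSE: {best.rmse:.3f} log units "
          f"({best.representation} / {best.model})")


if __name__ == "__main__":
    main()
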