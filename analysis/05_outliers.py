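"""Outlier diagnostics on the training partition.

LOF in standardized-descriptor space and in raw bit space; Welch t-tests
contrasting flagged vs unflagged molecules per descriptor; the rare-bit
frequency ratio contrast; and the effect on test metrics of refitting the
descriptor RF without the flagged rows.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

sys.path.insert(0, str(Path(__file__).resolve().parent))
import _common
from aqsol import fingerprints, models, outliers


def main():
    ds = _common.curated_dataset()
    desc, fpm, y = _common.feature_matrices(ds)
    sp = models.split(len(y), _common.SPLIT_FRACTION, seed=_common.MASTER_SEED)
    tr, te = sp.train_idx, sp.test_idx
    Xd = desc.values.to_numpy(float)
    Xf = fpm.bits.astype(float)
    sd = Xd.std(0)
    Xd_std = (Xd - Xd.mean(0)) / np.where(sd == 0, 1, sd)

    rep_d = outliers.lof_flags(Xd_std[tr])
    rep_f = outliers.lof_flags(Xf[tr])
    print(f"descriptor-space outliers: {rep_d.n_outliers} / {len(tr)}")
    print(f"bit-space outliers:        {rep_f.n_outliers} / {len(tr)}")

    if rep_d.n_outliers >= 2:
        tt = outliers.group_ttests(Xd[tr], rep_d.flags, desc.feature_names)
        tt = tt.sort_values("p", kind="stable")
        tt.to_csv(_common.RESULTS / "descriptor_ttests.csv", index=False)
        print("descriptors most different in the outlier group:")
        print(tt.head(8).to_string(index=False))
        refit = outliers.refit_without_outliers(
            Xd[tr], y[tr], Xd[te], y[te], rep_d.flags,
            lambda: RandomForestRegressor(n_estimators=_common.RF_TREES,
                                          random_state=_common.RF_SEED),
        )
        print(f"removing them: test RMSE {refit['with_outliers'].rmse:.3f} -> "
              f"{refit['without_outliers'].rmse:.3f} "
              f"(delta {refit['delta_rmse']:+.4f})")

    counts = fingerprints.bit_frequency_counts(fpm)
    ratios = np.array([fingerprints.rare_feature_ratio(fpm.bits[i], counts) for i in tr])
    flags = rep_f.flags if rep_f.n_outliers else rep_d.flags
    label = "bit-space" if rep_f.n_outliers else "descriptor-space"
    print(f"rare-bit ratio ({label} flags): outliers "
          f"{ratios[flags].mean() if flags.any() else float('nan'):.3f} vs "
          f"inliers {ratios[~flags].mean():.3f}")
    pd.DataFrame({
        "row": tr,
        "lof_descriptor": rep_d.scores, "outlier_descriptor": rep_d.flags,
        "lof_fingerprint": rep_f.scores, "outlier_fingerprint": rep_f.flags,
        "rare_feature_ratio": ratios,
    }).to_csv(_common.RESULTS / "outlier_report.csv", index=False)


if __name__ == "__main__":
    main()
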