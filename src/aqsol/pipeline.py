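"""End-to-end study orchestration: curate -> featurize -> train -> diagnose
-> interpret (-> blind test), with seeded configuration and audited outputs.

Every stochastic stage takes its seed from :class:`RunConfig`; a run
directory contains the curated table, both feature matrices with stage logs,
metrics tables shaped like the study's descriptor/fingerprint comparison,
outlier and importance reports, the fragment Gibbs-energy table, and a
``run_meta.json`` recording the config hash so any two runs are
distinguishable from their outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from . import chem_io, descriptors, fingerprints, interpret, models, outliers

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "evaluate_blind"]

log = logging.getLogger("aqsol.pipeline")


@dataclass
class RunConfig:
    """Full configuration of one study run. Round-trips through JSON."""

    input_csv: str = ""
    out_dir: str = "results/run"
    blind_csv: str = ""  # optional; empty = skip blind stage

    # curation
    conflict_tolerance: float = 0.01
    # split
    split_fraction: float = 0.8
    split_seed: int = 0
    # descriptor cascade
    variance_threshold: float = 0.1
    corr_cutoff: float = 0.95
    exclude_descriptors: tuple = ("FilterItLogS",)
    # fingerprints
    fp_radius: int = 2
    fp_bits: int = 2048
    # LASSO
    lasso_alpha_grid: tuple = fingerprints.DEFAULT_ALPHA_GRID
    lasso_chosen_alpha: float = 1e-3
    # RF
    rf_n_estimators: int = 500
    rf_seed: int = 42
    # LOF
    lof_n_neighbors: int = 20
    lof_score_threshold: float = 1.5
    remove_outliers: bool = False  # default keeps outliers; removal is opt-in
    # SHAP
    shap_max_rows: int = 2000
    shap_seed: int = 0
    top_k: int = 12

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        for f in dataclasses.fields(cls):
            if f.name in data and isinstance(data[f.name], list):
                data[f.name] = tuple(data[f.name])
        return cls(**data)


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    dataset: chem_io.CuratedDataset
    profile: dict
    descriptor_matrix: descriptors.DescriptorMatrix
    fingerprint_matrix: fingerprints.FingerprintMatrix
    split: models.SplitIndices
    metrics: pd.DataFrame
    lasso: fingerprints.BitSelection
    fitted: dict = field(default_factory=dict)
    outlier_summary: dict = field(default_factory=dict)
    importance: dict = field(default_factory=dict)
    fragment_thermo: pd.DataFrame | None = None
    concordance: dict = field(default_factory=dict)


def _banner(stage: str, t0: float) -> None:
    log.info("[%7.2fs] ==== %s ====", time.perf_counter() - t0, stage)


def _metric_rows(rep: str, mdl: str, train_m: models.ModelMetrics, test_m: models.ModelMetrics):
    out = []
    for m in (train_m, test_m):
        d = m.as_dict()
        d.update({"representation": rep, "model": mdl})
        out.append(d)
    return out


def run_pipeline(config: RunConfig, raw_records=None) -> PipelineResult:
    """Execute the whole study under one configuration.

    *raw_records* may supply the input table directly (e.g. from the
    synthetic generator); otherwise ``config.input_csv`` is read. All tables
    are written under ``config.out_dir``.
    """
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_json(out / "config.json")

    # ---- curation -------------------------------------------------------
    _banner("curate", t0)
    if raw_records is None:
        raw_records, bad = chem_io.read_molecule_table(config.input_csv)
        log.info("read %d rows (%d unusable reported)", len(raw_records) + len(bad), len(bad))
    dataset = chem_io.curate(raw_records, config.conflict_tolerance)
    prov = dataset.provenance
    log.info(
        "kept %d molecules (collapsed %d, conflict-dropped %d records, %d parse failures)",
        prov.n_kept, prov.n_collapsed, prov.n_conflict_records, prov.n_parse_failures,
    )
    chem_io.write_curated_csv(dataset, out / "curated.csv")
    profile = chem_io.profile_dataset(dataset)
    (out / "profile.json").write_text(json.dumps(profile, indent=2))

    y = np.asarray(dataset.logS)
    smiles = dataset.smiles

    # ---- featurization --------------------------------------------------
    _banner("descriptors", t0)
    desc_raw = descriptors.compute_2d_descriptors(smiles)
    desc = descriptors.full_cascade(
        desc_raw,
        variance_threshold=config.variance_threshold,
        corr_cutoff=config.corr_cutoff,
        exclude=config.exclude_descriptors,
    )
    for rec in desc.stage_log:
        log.info("cascade %-22s %4d -> %4d columns", rec.stage, rec.n_before, rec.n_after)
    desc.write(out / "descriptors.csv")

    _banner("fingerprints", t0)
    fpm = fingerprints.compute_morgan(smiles, config.fp_radius, config.fp_bits)
    log.info("fingerprints: %d x %d, density %.4f", *fpm.shape, fpm.bits.mean())

    # ---- split and models ----------------------------------------------
    _banner("models", t0)
    sp = models.split(len(y), config.split_fraction, config.split_seed)
    tr, te = sp.train_idx, sp.test_idx
    Xd = desc.values.to_numpy(dtype=float)
    Xf = fpm.bits.astype(float)

    rows = []
    fitted: dict = {}

    rf_d = models.train_rf(Xd[tr], y[tr], config.rf_n_estimators, config.rf_seed)
    rows += _metric_rows("descriptors", "RF",
                         models.evaluate(rf_d, Xd[tr], y[tr], "train"),
                         models.evaluate(rf_d, Xd[te], y[te], "test"))
    mlr_d = models.train_mlr(Xd[tr], y[tr], desc.feature_names)
    rows += _metric_rows("descriptors", "MLR",
                         models.evaluate(mlr_d, Xd[tr], y[tr], "train"),
                         models.evaluate(mlr_d, Xd[te], y[te], "test"))
    fitted["rf_descriptors"], fitted["mlr_descriptors"] = rf_d, mlr_d

    rf_f = models.train_rf(Xf[tr], y[tr], config.rf_n_estimators, config.rf_seed)
    rows += _metric_rows(f"fingerprint_{config.fp_bits}", "RF",
                         models.evaluate(rf_f, Xf[tr], y[tr], "train"),
                         models.evaluate(rf_f, Xf[te], y[te], "test"))
    fitted["rf_fingerprints"] = rf_f

    _banner("lasso", t0)
    sel = fingerprints.lasso_select(
        Xf[tr], y[tr], config.lasso_alpha_grid, config.lasso_chosen_alpha
    )
    log.info("lasso: %s", sel.n_selected_per_alpha)
    k = len(sel.selected_bit_ids)
    log.info("chosen alpha %g -> %d bits", sel.chosen_alpha, k)
    (out / "lasso.json").write_text(json.dumps({
        "alpha_grid": list(sel.alpha_grid),
        "chosen_alpha": sel.chosen_alpha,
        "n_selected_per_alpha": sel.n_selected_per_alpha,
        "selected_bit_ids": sel.selected_bit_ids.tolist(),
    }, indent=2))

    bit_names = [f"bit_{i}" for i in range(config.fp_bits)]
    Xs = Xf[:, sel.selected_bit_ids]
    sel_names = [bit_names[i] for i in sel.selected_bit_ids]
    if k:
        rf_s = models.train_rf(Xs[tr], y[tr], config.rf_n_estimators, config.rf_seed)
        rows += _metric_rows(f"fingerprint_{k}_selected", "RF",
                             models.evaluate(rf_s, Xs[tr], y[tr], "train"),
                             models.evaluate(rf_s, Xs[te], y[te], "test"))
        fitted["rf_fingerprints_selected"] = rf_s
    # MLR needs p < n: full-width bits only when the training set is big enough
    if len(tr) > config.fp_bits:
        mlr_f = models.train_mlr(Xf[tr], y[tr], bit_names)
        rows += _metric_rows(f"fingerprint_{config.fp_bits}", "MLR",
                             models.evaluate(mlr_f, Xf[tr], y[tr], "train"),
                             models.evaluate(mlr_f, Xf[te], y[te], "test"))
        fitted["mlr_fingerprints"] = mlr_f
    if 0 < k < len(tr):
        mlr_s = models.train_mlr(Xs[tr], y[tr], sel_names)
        rows += _metric_rows(f"fingerprint_{k}_selected", "MLR",
                             models.evaluate(mlr_s, Xs[tr], y[tr], "train"),
                             models.evaluate(mlr_s, Xs[te], y[te], "test"))
        fitted["mlr_fingerprints_selected"] = mlr_s

    metrics = pd.DataFrame(rows)[
        ["representation", "model", "partition", "n", "r2", "rmse", "mae"]
    ]
    metrics.to_csv(out / "metrics.csv", index=False)

    # ---- outlier diagnostics -------------------------------------------
    _banner("outliers", t0)
    outlier_summary: dict = {}
    if len(tr) > config.lof_n_neighbors:
        Xd_std = (Xd - Xd.mean(0)) / np.where(Xd.std(0) == 0, 1, Xd.std(0))
        rep_d = outliers.lof_flags(Xd_std[tr], config.lof_n_neighbors, config.lof_score_threshold)
        rep_f = outliers.lof_flags(Xf[tr], config.lof_n_neighbors, config.lof_score_threshold)
        log.info("LOF: %d descriptor-space, %d bit-space outliers of %d train rows",
                 rep_d.n_outliers, rep_f.n_outliers, len(tr))
        outlier_summary["descriptor_report"] = rep_d
        outlier_summary["fingerprint_report"] = rep_f
        if 2 <= rep_d.n_outliers <= len(tr) - 2:
            tt = outliers.group_ttests(Xd[tr], rep_d.flags, desc.feature_names)
            tt.sort_values("p", kind="stable").to_csv(out / "descriptor_ttests.csv", index=False)
            outlier_summary["ttests"] = tt
            refit = outliers.refit_without_outliers(
                Xd[tr], y[tr], Xd[te], y[te], rep_d.flags,
                lambda: RandomForestRegressor(
                    n_estimators=config.rf_n_estimators, random_state=config.rf_seed
                ),
            )
            outlier_summary["refit_descriptors"] = refit
            log.info("refit without outliers: delta RMSE %+0.4f, delta MAE %+0.4f",
                     refit["delta_rmse"], refit["delta_mae"])
        # rare-bit frequency ratios on the whole dataset's counts
        counts = fingerprints.bit_frequency_counts(fpm)
        ratios = np.array([
            fingerprints.rare_feature_ratio(Xf[i], counts) for i in tr
        ])
        flags_f = rep_f.flags
        outlier_summary["rare_ratio"] = {
            "outlier_mean": float(ratios[flags_f].mean()) if flags_f.any() else float("nan"),
            "inlier_mean": float(ratios[~flags_f].mean()) if (~flags_f).any() else float("nan"),
        }
        pd.DataFrame({
            "row": tr,
            "lof_score_descriptor": rep_d.scores,
            "outlier_descriptor": rep_d.flags,
            "lof_score_fingerprint": rep_f.scores,
            "outlier_fingerprint": rep_f.flags,
            "rare_feature_ratio": ratios,
        }).to_csv(out / "outlier_report.csv", index=False)
        (out / "outlier_summary.json").write_text(json.dumps({
            "n_train": len(tr),
            "n_outliers_descriptor": rep_d.n_outliers,
            "n_outliers_fingerprint": rep_f.n_outliers,
            "rare_ratio": outlier_summary["rare_ratio"],
        }, indent=2))
    else:
        log.info("training partition too small for LOF diagnostics; skipped")

    # ---- interpretation -------------------------------------------------
    _banner("interpret", t0)
    importance: dict = {}
    imp_f = interpret.shap_importance(
        rf_f, Xf[tr], bit_names,
        mlr_model=fitted.get("mlr_fingerprints") or fitted.get("mlr_fingerprints_selected"),
        max_rows=config.shap_max_rows, seed=config.shap_seed,
    )
    importance["fingerprints"] = imp_f
    imp_f.table.to_csv(out / "importance_fingerprints.csv", index=False)
    imp_d = interpret.shap_importance(
        rf_d, Xd[tr], desc.feature_names, mlr_model=mlr_d,
        max_rows=config.shap_max_rows, seed=config.shap_seed,
    )
    importance["descriptors"] = imp_d
    imp_d.table.to_csv(out / "importance_descriptors.csv", index=False)
    log.info("SHAP local-accuracy error: fp %.2e, desc %.2e",
             imp_f.local_accuracy_error(), imp_d.local_accuracy_error())

    atlas = fingerprints.build_bit_atlas(smiles, config.fp_radius, config.fp_bits)
    top_bits = [int(f.split("_")[1]) for f in imp_f.top(config.top_k)["feature"]]
    thermo = interpret.fragment_thermo_table(atlas, top_bits)
    thermo.to_csv(out / "fragment_thermo.csv", index=False)
    concordance = interpret.shap_gibbs_concordance(thermo, imp_f)
    log.info("dG vs signed-SHAP Spearman rho = %.3f (n=%d)",
             concordance["spearman_rho"], concordance["n"])

    result = PipelineResult(
        config=config, dataset=dataset, profile=profile,
        descriptor_matrix=desc, fingerprint_matrix=fpm, split=sp,
        metrics=metrics, lasso=sel, fitted=fitted,
        outlier_summary=outlier_summary, importance=importance,
        fragment_thermo=thermo, concordance=concordance,
    )

    (out / "run_meta.json").write_text(json.dumps({
        "config_hash": chash,
        "seeds": {"split": config.split_seed, "rf": config.rf_seed, "shap": config.shap_seed},
        "n_molecules": len(dataset),
        "n_descriptors_final": desc.shape[1],
        "n_bits_selected": int(len(sel.selected_bit_ids)),
        "tables": sorted(p.name for p in out.glob("*.csv")),
        "elapsed_s": round(time.perf_counter() - t0, 2),
    }, indent=2))
    _banner("done", t0)
    return result


def evaluate_blind(
    predictors: dict,
    blind_table: pd.DataFrame,
    train_smiles,
) -> tuple[pd.DataFrame, dict]:
    """Predict a never-seen blind set with each model and tabulate errors.

    *predictors* maps model name -> callable(list of SMILES) -> predictions.
    *blind_table* needs columns name, smiles, logS. The blind set must be
    disjoint from training (canonical-SMILES intersection empty) — any
    overlap is an error, not a warning.
    """
    for col in ("name", "smiles", "logS"):
        if col not in blind_table.columns:
            raise KeyError(f"blind table missing column {col!r}")
    blind_can = [chem_io.canonicalize_smiles(s) for s in blind_table["smiles"]]
    train_can = {chem_io.canonicalize_smiles(s) for s in train_smiles}
    overlap = sorted(set(blind_can) & train_can)
    if overlap:
        raise ValueError(f"blind set overlaps training data: {overlap[:5]} ...")

    out = blind_table[["name", "smiles", "logS"]].copy()
    means = {}
    for model_name, predict in predictors.items():
        pred = np.asarray(predict(blind_can), dtype=float)
        out[f"pred_{model_name}"] = pred
        out[f"abs_error_{model_name}"] = np.abs(pred - out["logS"].to_numpy(dtype=float))
        means[model_name] = float(out[f"abs_error_{model_name}"].mean())
    return out, means
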