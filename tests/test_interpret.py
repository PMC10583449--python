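import numpy as np
import pytest

from aqsol import synthetic
from aqsol.fingerprints import build_bit_atlas, compute_morgan
from aqsol.interpret import (
    FragmentThermo,
    coefficient_report,
    fragment_properties,
    fragment_thermo_table,
    gibbs_energy,
    shap_gibbs_concordance,
    shap_importance,
)
from aqsol.models import train_mlr, train_rf


def test_gibbs_energy_hand_values():
    assert gibbs_energy(0, 0, 0) == pytest.approx(-0.5)
    assert gibbs_energy(10, 1, 1) == pytest.approx(-13.33)
    assert gibbs_energy(1, 0, 1) == pytest.approx(-4.84)


def test_gibbs_energy_monotone_grid():
    grid = np.linspace(0, 20, 9)
    for ca in (0.0, 1.0, 3.0):
        for cd in (0.0, 1.0, 3.0):
            dg = [gibbs_energy(a, ca, cd) for a in grid]
            assert all(x > y for x, y in zip(dg, dg[1:]))  # decreasing in alpha
    for alpha in (0.0, 5.0):
        dg_ca = [gibbs_energy(alpha, ca, 1.0) for ca in grid]
        assert all(x < y for x, y in zip(dg_ca, dg_ca[1:]))  # increasing in Ca
        dg_cd = [gibbs_energy(alpha, 1.0, cd) for cd in grid]
        assert all(x > y for x, y in zip(dg_cd, dg_cd[1:]))  # decreasing in Cd


def test_fragment_properties_donor_acceptor_counts():
    alpha, ca, cd = fragment_properties("C")  # methane after capping
    assert alpha > 0 and ca == 0 and cd == 0
    _, _, cd_oh = fragment_properties("O")  # hydroxyl -> water
    assert cd_oh >= 1
    _, ca_acid, cd_acid = fragment_properties("OC=O")  # carboxyl -> formic acid
    assert ca_acid >= 1 and cd_acid >= 1


def test_fragment_properties_open_valence_aromatic():
    # bare aromatic-carbon environment fragments must still cap and score
    alpha, ca, cd = fragment_properties("ccc")
    assert np.isfinite(alpha) and alpha > 0
    with pytest.raises(ValueError):
        fragment_properties("][")


def test_fragment_thermo_consistency_enforced():
    FragmentThermo(1, "O", 1.0, 0.0, 1.0, gibbs_energy(1.0, 0.0, 1.0))
    with pytest.raises(ValueError):
        FragmentThermo(1, "O", 1.0, 0.0, 1.0, 0.0)


def test_coefficient_report_ranking_and_signs():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(100, 2))
    y = 3.0 * X[:, 0] - 1.0 * X[:, 1]
    rep = coefficient_report(train_mlr(X, y, ["x1", "x2"]))
    assert list(rep.feature) == ["x1", "x2"]
    assert rep.coefficient.iloc[0] > 0 > rep.coefficient.iloc[1]


def test_shap_importance_constant_model_all_zero():
    X = np.random.default_rng(1).normal(size=(40, 3))
    rf = train_rf(X, np.full(40, 2.0), n_estimators=10)
    rep = shap_importance(rf, X, ["a", "b", "c"])
    np.testing.assert_allclose(rep.table.mean_abs_shap, 0.0, atol=1e-12)
    assert rep.local_accuracy_error() < 1e-9


def test_shap_importance_feature_mismatch_errors():
    X = np.random.default_rng(2).normal(size=(30, 4))
    rf = train_rf(X, X[:, 0], n_estimators=5)
    with pytest.raises(ValueError, match="feature mismatch"):
        shap_importance(rf, X[:, :3])


def test_shap_and_mlr_agree_on_planted_groups(molecules_1000):
    """On planted data the top SHAP features are the planted groups and their
    direction matches the MLR coefficient sign."""
    smis = molecules_1000[:400]
    model = synthetic.PlantedModel(noise_sd=0.1, seed=3)
    records = synthetic.assign_logS(smis, model)
    X = synthetic.group_count_matrix(smis)
    y = np.array([r.logS for r in records])
    rf = train_rf(X, y, n_estimators=60)
    mlr = train_mlr(X, y, list(synthetic.GROUP_FEATURES))
    rep = shap_importance(rf, X, list(synthetic.GROUP_FEATURES), mlr_model=mlr)
    assert rep.local_accuracy_error() < 1e-6
    t = rep.table.set_index("feature")
    for feat, coef in model.coefficients.items():
        if t.loc[feat, "direction"] != 0:
            assert t.loc[feat, "direction"] == np.sign(t.loc[feat, "mlr_coefficient"])
            assert t.loc[feat, "direction"] == np.sign(coef)


def test_fragment_thermo_table_aligns_with_bits(molecules_1000):
    smis = molecules_1000[:50]
    atlas = build_bit_atlas(smis)
    observed = sorted(atlas.entries)[:5]
    table = fragment_thermo_table(atlas, observed + [2047])
    assert list(table.bit_id) == observed + [2047]
    scored = table.dropna(subset=["dg298"])
    for _, row in scored.iterrows():
        assert row.dg298 == pytest.approx(gibbs_energy(row.alpha, row.ca_sum, row.cd_sum))


def test_concordance_reports_spearman(molecules_1000):
    smis = molecules_1000[:150]
    model = synthetic.PlantedModel(noise_sd=0.1, seed=5)
    records = synthetic.assign_logS(smis, model)
    y = np.array([r.logS for r in records])
    fpm = compute_morgan(smis)
    rf = train_rf(fpm.bits.astype(float), y, n_estimators=40)
    rep = shap_importance(rf, fpm.bits.astype(float), [f"bit_{i}" for i in range(2048)])
    atlas = build_bit_atlas(smis)
    top_bits = [int(f.split("_")[1]) for f in rep.top(12)["feature"]]
    thermo = fragment_thermo_table(atlas, top_bits)
    out = shap_gibbs_concordance(thermo, rep)
    assert set(out) == {"spearman_rho", "p_value", "n"}
    assert out["n"] > 0
    assert -1.0 <= out["spearman_rho"] <= 1.0


def test_shap_top_bits_for_planted_hydroxyl_map_to_oh_fragments(molecules_1000):
    """A pure-hydroxyl planted signal concentrates SHAP mass on bits whose
    atlas fragments contain the hydroxyl oxygen."""
    smis = molecules_1000[:300]
    model = synthetic.PlantedModel(
        intercept=0.0, coefficients={"hydroxyl": 1.5}, noise_sd=0.05, seed=6
    )
    records = synthetic.assign_logS(smis, model)
    y = np.array([r.logS for r in records])
    fpm = compute_morgan(smis)
    rf = train_rf(fpm.bits.astype(float), y, n_estimators=60)
    rep = shap_importance(rf, fpm.bits.astype(float), [f"bit_{i}" for i in range(2048)])
    atlas = build_bit_atlas(smis)
    top = [int(f.split("_")[1]) for f in rep.top(5)["feature"]]
    has_oxygen = [
        any("O" in frag or "o" in frag for frag in atlas.fragments(bit)) for bit in top
    ]
    assert any(has_oxygen[:3])
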