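import numpy as np
import pytest
from rdkit import Chem

from aqsol.fingerprints import (
    FingerprintMatrix,
    bit_frequency_counts,
    bit_info_map,
    bit_to_substructure,
    build_bit_atlas,
    compute_morgan,
    lasso_select,
    rare_feature_ratio,
)

FIXTURE_MOLECULES = [
    "CCO", "CC(=O)O", "c1ccccc1", "Oc1ccccc1", "CCN", "CCCl", "CC(C)O",
    "OCCO", "CCCC", "NCCO", "CC(=O)C", "Clc1ccccc1", "CCBr", "OC(=O)CC",
    "CCCCCC", "CC(C)(C)O", "NCC(=O)O", "FCC", "CCOC", "Cc1ccccc1",
]


def test_row_width_and_binary_entries():
    m = compute_morgan(FIXTURE_MOLECULES)
    assert m.shape == (20, 2048)
    assert set(np.unique(m.bits)) <= {0, 1}


def test_spelling_invariance():
    a = compute_morgan(["CCO"]).bits
    b = compute_morgan(["OCC"]).bits
    np.testing.assert_array_equal(a, b)


def test_ethanol_set_bit_bound():
    # 3 heavy atoms x radii {0,1,2} bounds the environment count
    m = compute_morgan(["CCO"])
    assert 0 < m.bits.sum() <= 9


def test_atom_renumbering_invariance():
    rng = np.random.default_rng(0)
    gen_ref = compute_morgan(FIXTURE_MOLECULES).bits
    for i, smi in enumerate(FIXTURE_MOLECULES):
        mol = Chem.MolFromSmiles(smi)
        n = mol.GetNumAtoms()
        for _ in range(5):
            perm = list(map(int, rng.permutation(n)))
            renum = Chem.RenumberAtoms(mol, perm)
            row = compute_morgan([renum]).bits[0]
            np.testing.assert_array_equal(row, gen_ref[i])


def test_bit_to_substructure_radius0_is_single_atom():
    info = bit_info_map("CCO")
    r0_bits = [b for b, envs in info.items() if any(r == 0 for _, r in envs)]
    for bit in r0_bits:
        for env in bit_to_substructure("CCO", bit):
            if env.radius == 0:
                frag = Chem.MolFromSmiles(env.smiles, sanitize=False)
                assert frag.GetNumAtoms() == 1


def test_bit_to_substructure_round_trip_all_set_bits():
    """Every extracted (center, radius) environment re-hashes to its bit."""
    for smi in FIXTURE_MOLECULES:
        info = bit_info_map(smi)
        for bit in info:
            for env in bit_to_substructure(smi, bit):
                assert (env.center_atom, env.radius) in info[bit]
                assert env.smiles  # non-empty fragment


def test_bit_to_substructure_unset_bit_errors():
    info = bit_info_map("CCO")
    unset = next(b for b in range(2048) if b not in info)
    with pytest.raises(ValueError):
        bit_to_substructure("CCO", unset)


def test_hydroxyl_environment_of_ethanol_bits():
    # On ethanol the O-centered radius-0/1 environments land on bits 807/222
    # (2048-bit folding); their fragments must contain the hydroxyl oxygen.
    info = bit_info_map("CCO")
    mol = Chem.MolFromSmiles("CCO")
    o_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O")
    o_bits = [b for b, envs in info.items() if any(a == o_idx for a, _ in envs)]
    assert 807 in o_bits and 222 in o_bits
    for env in bit_to_substructure("CCO", 807):
        assert "O" in env.smiles
    # carboxyl-type fragment recoverable on a matching molecule
    acid_info = bit_info_map("CC(=O)O")
    acid_bits = {
        b
        for b, envs in acid_info.items()
        for a, r in envs
        if r == 1 and Chem.MolFromSmiles("CC(=O)O").GetAtomWithIdx(a).GetSymbol() == "C"
    }
    frags = [e.smiles for b in acid_bits for e in bit_to_substructure("CC(=O)O", b)]
    assert any("C(=O)O" in f or "O=C" in f for f in frags)


def test_atlas_entries_verified_by_refingerprinting():
    atlas = build_bit_atlas(FIXTURE_MOLECULES)
    assert atlas.entries
    for bit, entries in list(atlas.entries.items())[:50]:
        for e in entries:
            assert e["radius"] <= 2
            info = bit_info_map(e["smiles"])
            assert bit in info
            assert (e["center_atom"], e["radius"]) in info[bit]


def test_lasso_heavy_penalty_empties_selection():
    rng = np.random.default_rng(3)
    X = (rng.random((60, 2048)) < 0.05).astype(np.uint8)
    y = rng.normal(size=60)
    sel = lasso_select(X, y, chosen_alpha=10.0)
    assert len(sel.selected_bit_ids) <= 2


def test_lasso_recovers_single_informative_bit():
    rng = np.random.default_rng(4)
    X = (rng.random((200, 2048)) < 0.05).astype(np.uint8)
    y = 2.0 * X[:, 3].astype(float)  # noiseless, bit 3 only
    sel = lasso_select(X, y, chosen_alpha=1e-3)
    assert 3 in sel.selected_bit_ids
    assert np.argmax(np.abs(sel.coefficients)) == 3


def test_lasso_selection_size_monotone_in_alpha():
    rng = np.random.default_rng(5)
    X = (rng.random((150, 2048)) < 0.05).astype(np.uint8)
    y = X[:, :10].astype(float) @ rng.normal(size=10) + 0.1 * rng.normal(size=150)
    sel = lasso_select(X, y)
    sizes = [sel.n_selected_per_alpha[a] for a in sorted(sel.n_selected_per_alpha)]
    assert sizes == sorted(sizes, reverse=True)


def test_lasso_validation():
    X = np.zeros((10, 2048), dtype=np.uint8)
    with pytest.raises(ValueError):
        lasso_select(X, np.ones(10))  # constant y
    with pytest.raises(ValueError):
        lasso_select(X, np.ones(9))  # misaligned


def test_bit_frequency_counts():
    assert bit_frequency_counts(np.zeros((4, 2048), dtype=np.uint8)).sum() == 0
    toy = np.zeros((3, 2048), dtype=np.uint8)
    toy[0, [1, 5]] = 1
    toy[1, [5]] = 1
    toy[2, [1, 5, 7]] = 1
    counts = bit_frequency_counts(toy)
    assert counts[1] == 2 and counts[5] == 3 and counts[7] == 1
    assert counts.sum() == toy.sum()


def test_rare_feature_ratio_cases():
    counts = np.zeros(2048, dtype=int)
    counts[[10, 11, 12]] = [50, 150, 99]
    counts[20] = 5000
    row = np.zeros(2048, dtype=np.uint8)
    row[20] = 1
    assert rare_feature_ratio(row, counts) == 0.0
    row = np.zeros(2048, dtype=np.uint8)
    row[[10, 11, 12]] = 1
    assert rare_feature_ratio(row, counts) == pytest.approx(2 / 3)
    with pytest.warns(UserWarning):
        assert rare_feature_ratio(np.zeros(2048, dtype=np.uint8), counts) == 0.0


def test_rare_feature_ratio_matches_set_oracle():
    rng = np.random.default_rng(6)
    X = (rng.random((30, 2048)) < 0.03).astype(np.uint8)
    counts = bit_frequency_counts(X)
    threshold = 10
    # separate weights so some counts straddle the threshold
    counts = counts + rng.integers(0, 20, size=2048)
    for i in range(X.shape[0]):
        on = {int(b) for b in np.flatnonzero(X[i])}
        rare = {b for b in on if counts[b] < threshold}
        expected = len(rare) / len(on) if on else 0.0
        if on:
            assert rare_feature_ratio(X[i], counts, threshold) == pytest.approx(expected)


def test_matrix_validation():
    with pytest.raises(ValueError):
        FingerprintMatrix(np.full((2, 2048), 2, dtype=np.uint8))
    with pytest.raises(ValueError):
        FingerprintMatrix(np.zeros((2, 100), dtype=np.uint8))
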