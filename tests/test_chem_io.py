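import numpy as np
import pytest

from aqsol.chem_io import (
    CuratedDataset,
    RawRecord,
    SmilesParseError,
    canonicalize_smiles,
    curate,
    profile_dataset,
    read_molecule_table,
)


@pytest.mark.parametrize("a,b", [("OCC", "CCO"), ("c1ccccc1", "C1=CC=CC=C1")])
def test_canonicalization_merges_spellings(a, b):
    assert canonicalize_smiles(a) == canonicalize_smiles(b)


def test_canonicalization_is_fixed_point():
    for smi in ["OCC", "C1=CC=CC=C1", "CC(C)C(=O)O", "NCCc1ccccc1"]:
        can = canonicalize_smiles(smi)
        assert canonicalize_smiles(can) == can


def test_invalid_smiles_raises_with_offender():
    with pytest.raises(SmilesParseError) as err:
        canonicalize_smiles("XYZ")
    assert err.value.smiles == "XYZ"


def test_read_molecule_table(tmp_path):
    p = tmp_path / "mols.csv"
    p.write_text("smiles,logS\nCCO,-0.5\nCC,-1.2\nc1ccccc1,-1.6\n")
    records, bad = read_molecule_table(p)
    assert len(records) == 3 and bad == []

    p2 = tmp_path / "gap.csv"
    p2.write_text("smiles,logS\nCCO,-0.5\nCC,\nc1ccccc1,-1.6\n")
    records, bad = read_molecule_table(p2)
    assert len(records) == 2
    assert len(bad) == 1 and bad[0]["smiles"] == "CC"


def test_read_molecule_table_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_molecule_table(tmp_path / "absent.csv")
    p = tmp_path / "wrong.csv"
    p.write_text("structure,value\nCCO,-0.5\n")
    with pytest.raises(KeyError):
        read_molecule_table(p)
    with pytest.raises(KeyError):
        read_molecule_table(p, column_map={"smiles": "structure"})
    # remapped correctly it reads fine
    records, _ = read_molecule_table(p, column_map={"smiles": "structure", "logS": "value"})
    assert len(records) == 1


def test_curate_collapses_and_drops_conflicts():
    # A measured twice identically, B once, C twice in conflict
    raw = [
        RawRecord("CCO", -1.0, "s1"),
        RawRecord("OCC", -1.0, "s2"),  # same molecule, different spelling
        RawRecord("CC", -2.0, "s1"),
        RawRecord("CO", -1.0, "s1"),
        RawRecord("CO", -3.0, "s2"),
    ]
    ds = curate(raw, conflict_tolerance=0.01)
    kept = {r.smiles: r.logS for r in ds.records}
    assert kept == {"CCO": -1.0, "CC": -2.0}
    p = ds.provenance
    assert (p.n_kept, p.n_collapsed, p.n_conflict_records, p.n_conflict_molecules) == (2, 1, 2, 1)


def test_curate_tolerance_averages_near_duplicates():
    raw = [RawRecord("CCO", -1.00), RawRecord("CCO", -1.20)]
    assert len(curate(raw, conflict_tolerance=0.5).records) == 1
    assert curate(raw, conflict_tolerance=0.5).records[0].logS == pytest.approx(-1.10)
    assert len(curate(raw, conflict_tolerance=0.1).records) == 0


def test_curate_empty_input():
    ds = curate([])
    assert len(ds) == 0
    p = ds.provenance
    assert (p.n_input, p.n_kept, p.n_collapsed, p.n_conflict_records, p.n_parse_failures) == (0,) * 5


def test_curate_routes_failures_not_raises():
    raw = [RawRecord("notasmiles", -1.0), RawRecord("[Na+].[Cl-]", 0.5), RawRecord("CCO", -1.0)]
    ds = curate(raw)
    assert len(ds) == 1
    assert ds.provenance.n_parse_failures == 2
    reasons = {r for _, r in ds.provenance.failures}
    assert reasons == {"parse error", "salt/mixture"}


def test_curate_idempotent_and_order_insensitive():
    rng = np.random.default_rng(0)
    pool = ["CCO", "CC", "CO", "CCN", "CCCl", "c1ccccc1", "OCC", "C1=CC=CC=C1"]
    raw = [RawRecord(pool[rng.integers(len(pool))], float(rng.integers(-3, 0))) for _ in range(40)]
    ds1 = curate(raw)
    # idempotence: re-curating the curated output changes nothing
    ds2 = curate([RawRecord(r.smiles, r.logS, r.source) for r in ds1.records])
    assert [(r.smiles, r.logS) for r in ds2.records] == [(r.smiles, r.logS) for r in ds1.records]
    # order-insensitivity
    perm = list(rng.permutation(len(raw)))
    ds3 = curate([raw[i] for i in perm])
    assert {(r.smiles, r.logS) for r in ds3.records} == {(r.smiles, r.logS) for r in ds1.records}


def test_kept_smiles_are_canonical_fixed_points():
    raw = [RawRecord("OCC", -1.0), RawRecord("C1=CC=CC=C1", -1.6)]
    for rec in curate(raw).records:
        assert canonicalize_smiles(rec.smiles) == rec.smiles
        assert rec.mw > 0 and rec.n_carbon >= 0


def test_provenance_conservation_randomized():
    """inputs = kept + collapsed + conflict-dropped + parse-failures, always."""
    rng = np.random.default_rng(123)
    pool = ["CCO", "CC", "CO", "CCN", "CCCl", "c1ccccc1", "CCC", "CC(C)O", "bad(", "C.C"]
    for _ in range(1000):
        n = int(rng.integers(0, 12))
        raw = [
            RawRecord(pool[rng.integers(len(pool))], float(rng.choice([-1.0, -1.0, -2.5])))
            for _ in range(n)
        ]
        prov = curate(raw).provenance
        prov.check()  # raises on violation
        assert prov.n_input == n


def test_profile_single_molecule():
    ds = curate([RawRecord("CCO", -0.5)])
    prof = profile_dataset(ds)
    assert prof["substructure_counts"]["hydroxyl"] == 1
    assert prof["substructure_counts"]["aromatic"] == 0
    assert prof["carbon_range"] == (2, 2)


def test_profile_counts_by_hand():
    ds = curate([RawRecord("c1ccccc1", -1.6), RawRecord("Clc1ccccc1", -2.4)])
    prof = profile_dataset(ds)
    assert prof["substructure_counts"]["aromatic"] == 2
    assert prof["substructure_counts"]["halogen"] == 1
    assert prof["carbon_range"] == (6, 6)
    assert sum(prof["mw_histogram"]["counts"]) == 2


def test_profile_empty_errors_and_wide_carbon_warns():
    with pytest.raises(ValueError):
        profile_dataset(CuratedDataset([], curate([]).provenance))
    ds = curate([RawRecord("C" * 14, -6.0)])
    with pytest.warns(UserWarning, match="carbon range"):
        profile_dataset(ds)


def test_write_round_trip(tmp_path):
    from aqsol.chem_io import write_curated_csv

    ds = curate([RawRecord("CCO", -0.5, "a"), RawRecord("CC", -1.2, "b")])
    path = tmp_path / "curated.csv"
    write_curated_csv(ds, path)
    records, bad = read_molecule_table(path)
    assert bad == []
    assert {r.smiles for r in records} == {"CCO", "CC"}
    assert path.with_suffix(".csv.provenance.json").exists()
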