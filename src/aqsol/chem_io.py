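"""Molecule tables: reading, SMILES canonicalization, and dataset curation.

The study target throughout is logS, the base-10 logarithm of aqueous
solubility in mol/L. Source tables are merged from several literature
collections and therefore contain exact repeats and conflicting
re-measurements of the same molecule; :func:`curate` collapses the former
and drops the latter, keeping an exact provenance account.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _Desc

__all__ = [
    "SmilesParseError",
    "RawRecord",
    "MoleculeRecord",
    "Provenance",
    "CuratedDataset",
    "canonicalize_smiles",
    "read_molecule_table",
    "curate",
    "profile_dataset",
    "write_curated_csv",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the string."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        self.reason = reason
        super().__init__(f"{reason}: {smiles!r}")


class RawRecord(NamedTuple):
    """One uncurated table row."""

    smiles: str
    logS: float
    source: str = ""


def canonicalize_smiles(smiles: str) -> str:
    """Return the canonical SMILES for *smiles*.

    Two spellings of the same molecule map to the same output, and the
    output is a fixed point of this function. Raises
    :class:`SmilesParseError` for strings RDKit cannot parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class MoleculeRecord:
    """One curated molecule: canonical SMILES, logS (log10 mol/L), source tag.

    ``mw`` (g/mol) and ``n_carbon`` are derived from the structure at
    construction time via :meth:`from_smiles`.
    """

    smiles: str
    logS: float
    source: str = ""
    mw: float = 0.0
    n_carbon: int = 0

    @classmethod
    def from_smiles(cls, smiles: str, logS: float, source: str = "") -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SmilesParseError(smiles)
        return cls(
            smiles=Chem.MolToSmiles(mol),
            logS=float(logS),
            source=source,
            mw=float(_Desc.MolWt(mol)),
            n_carbon=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6),
        )


@dataclass
class Provenance:
    """Record-level accounting for a curation pass.

    Conservation identity:
    ``n_input == n_kept + n_collapsed + n_conflict_records + n_parse_failures``.
    """

    n_input: int = 0
    n_kept: int = 0
    n_collapsed: int = 0
    n_conflict_records: int = 0
    n_conflict_molecules: int = 0
    n_parse_failures: int = 0
    failures: list = field(default_factory=list)  # (smiles, reason) pairs

    def check(self) -> None:
        total = self.n_kept + self.n_collapsed + self.n_conflict_records + self.n_parse_failures
        if total != self.n_input:
            raise AssertionError(
                f"provenance does not conserve records: {total} != {self.n_input}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class CuratedDataset:
    records: list[MoleculeRecord]
    provenance: Provenance

    def __len__(self) -> int:
        return len(self.records)

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def logS(self) -> list[float]:
        return [r.logS for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.smiles, r.logS, r.source, r.mw, r.n_carbon) for r in self.records],
            columns=["smiles", "logS", "source", "mw", "n_carbon"],
        )


def read_molecule_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[RawRecord], list[dict]]:
    """Read a molecule CSV into raw records.

    *column_map* maps the logical names ``smiles``, ``logS`` and (optionally)
    ``source`` to the file's column headers. Rows whose logS cell does not
    parse as a finite number are returned in the second element instead of
    being silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = {"smiles": "smiles", "logS": "logS", "source": "source"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    if df.empty:
        raise ValueError(f"empty molecule table: {path}")
    for key in ("smiles", "logS"):
        if cmap[key] not in df.columns:
            raise KeyError(f"mapped column {cmap[key]!r} (for {key!r}) not in {list(df.columns)}")
    has_source = cmap["source"] in df.columns

    records: list[RawRecord] = []
    bad_rows: list[dict] = []
    for i, row in df.iterrows():
        smi = row[cmap["smiles"]].strip()
        raw_y = row[cmap["logS"]].strip()
        src = row[cmap["source"]].strip() if has_source else ""
        try:
            y = float(raw_y)
        except ValueError:
            y = float("nan")
        if smi == "" or y != y:  # blank SMILES or non-numeric logS
            bad_rows.append({"row": int(i), "smiles": smi, "logS": raw_y, "reason": "bad logS" if smi else "blank smiles"})
            continue
        records.append(RawRecord(smi, y, src))
    return records, bad_rows


def curate(
    raw: Iterable[RawRecord | tuple],
    conflict_tolerance: float = 0.01,
) -> CuratedDataset:
    """Collapse repeats and drop conflicting re-measurements.

    Records are grouped on the full canonical SMILES (stereochemistry
    retained). Within a group, if every logS agrees within
    *conflict_tolerance* (log units) a single record with the mean logS is
    kept; otherwise the molecule is dropped entirely. Salts/mixtures
    (SMILES containing ``.``) and unparseable strings are routed to the
    provenance failure list, never raised.
    """
    prov = Provenance()
    groups: dict[str, list[RawRecord]] = {}
    for rec in raw:
        rec = RawRecord(*rec)
        prov.n_input += 1
        if "." in rec.smiles:
            prov.n_parse_failures += 1
            prov.failures.append((rec.smiles, "salt/mixture"))
            continue
        try:
            can = canonicalize_smiles(rec.smiles)
        except SmilesParseError:
            prov.n_parse_failures += 1
            prov.failures.append((rec.smiles, "parse error"))
            continue
        groups.setdefault(can, []).append(rec)

    kept: list[MoleculeRecord] = []
    for can in sorted(groups):
        members = groups[can]
        values = [m.logS for m in members]
        if max(values) - min(values) <= conflict_tolerance:
            source = ";".join(sorted({m.source for m in members if m.source}))
            kept.append(
                MoleculeRecord.from_smiles(can, sum(values) / len(values), source)
            )
            prov.n_kept += 1
            prov.n_collapsed += len(members) - 1
        else:
            prov.n_conflict_records += len(members)
            prov.n_conflict_molecules += 1
    prov.check()
    return CuratedDataset(records=kept, provenance=prov)


# substructure queries used for dataset profiling
_PROFILE_SMARTS = {
    "nitrogen": "[#7]",
    "sulfur": "[#16]",
    "halogen": "[F,Cl,Br,I]",
    "hydroxyl": "[OX2H]",
    "aromatic": "a",
}


def profile_dataset(dataset: CuratedDataset, mw_bin_width: float = 25.0) -> dict:
    """Summarize a curated dataset: MW distribution, substructure counts,
    carbon range.

    Emits a warning (not an error) if the carbon range strays outside the
    1-12 window characteristic of low-molecular-weight organics.
    """
    if len(dataset) == 0:
        raise ValueError("cannot profile an empty dataset")
    queries = {k: Chem.MolFromSmarts(s) for k, s in _PROFILE_SMARTS.items()}
    counts = dict.fromkeys(queries, 0)
    mws, carbons = [], []
    for rec in dataset.records:
        mol = Chem.MolFromSmiles(rec.smiles)
        mws.append(rec.mw)
        carbons.append(rec.n_carbon)
        for name, q in queries.items():
            if mol.HasSubstructMatch(q):
                counts[name] += 1
    c_min, c_max = min(carbons), max(carbons)
    if c_min < 1 or c_max > 12:
        warnings.warn(
            f"carbon range ({c_min},{c_max}) outside the expected 1-12 window",
            stacklevel=2,
        )
    n_bins = max(1, int(max(mws) // mw_bin_width) + 1)
    hist = [0] * n_bins
    for mw in mws:
        hist[min(int(mw // mw_bin_width), n_bins - 1)] += 1
    return {
        "n_molecules": len(dataset),
        "mean_mw": sum(mws) / len(mws),
        "mw_histogram": {"bin_width": mw_bin_width, "counts": hist},
        "substructure_counts": counts,
        "carbon_range": (c_min, c_max),
    }


def write_curated_csv(dataset: CuratedDataset, path: str | Path) -> None:
    """Persist a curated dataset; provenance goes to ``<path>.provenance.json``."""
    path = Path(path)
    dataset.to_dataframe().to_csv(path, index=False)
    dataset.provenance.to_json(path.with_suffix(path.suffix + ".provenance.json"))
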