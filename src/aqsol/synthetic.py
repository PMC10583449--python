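"""Synthetic molecule tables with a planted, known structure-logS relationship.

The generator emulates the statistical shape of a curated low-molecular-weight
organic solubility collection: 1-12 carbons, a mix of alkyl chains and benzene
rings decorated with hydroxyl / carboxyl / amine / halogen substituents, an
additive group-contribution logS signal with Gaussian measurement noise, and
(on request) deliberate duplicate and conflicting records to exercise curation.

The planted model is a test oracle, not solubility physics: its coefficients
follow the qualitative directions a solubility model should recover (polar
H-bonding groups raise logS; carbon count, halogens and aromatic rings lower
it), with magnitudes that put logS in a realistic -8..+2 window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeRecord, RawRecord

__all__ = [
    "GROUP_FEATURES",
    "PlantedModel",
    "count_groups",
    "group_count_matrix",
    "generate_molecules",
    "assign_logS",
    "inject_duplicates",
    "write_simulation",
]

#: Feature order of the planted additive model.
GROUP_FEATURES = ("carbon", "hydroxyl", "carboxyl", "amine", "halogen", "aromatic_ring")

# Hydroxyl excludes the acid OH so the two counts do not overlap.
_GROUP_SMARTS = {
    "hydroxyl": "[OX2H][#6;!$([CX3]=O)]",
    "carboxyl": "[CX3](=O)[OX2H1]",
    "amine": "[NX3;H2;!$(NC=O)]",
    "halogen": "[F,Cl,Br,I]",
}
_GROUP_QUERIES = {k: Chem.MolFromSmarts(s) for k, s in _GROUP_SMARTS.items()}


def count_groups(smiles: str) -> dict[str, int]:
    """Count the planted-model functional groups in one molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    counts = {
        "carbon": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6),
        "aromatic_ring": Chem.rdMolDescriptors.CalcNumAromaticRings(mol),
    }
    for name, q in _GROUP_QUERIES.items():
        counts[name] = len(mol.GetSubstructMatches(q))
    return counts


def group_count_matrix(smiles_list) -> np.ndarray:
    """n x 6 matrix of group counts in :data:`GROUP_FEATURES` order."""
    rows = []
    for smi in smiles_list:
        c = count_groups(smi)
        rows.append([c[f] for f in GROUP_FEATURES])
    return np.asarray(rows, dtype=float).reshape(len(rows), len(GROUP_FEATURES))


@dataclass(frozen=True)
class PlantedModel:
    """Additive group-contribution logS model planted into synthetic tables.

    logS = intercept + sum(coefficients[g] * count_g) + Normal(0, noise_sd).
    Units are log10(mol/L) throughout. Regeneration with the same seed is
    byte-for-byte reproducible.
    """

    intercept: float = 0.5
    coefficients: dict = field(
        default_factory=lambda: {
            "carbon": -0.55,
            "hydroxyl": 0.9,
            "carboxyl": 1.0,
            "amine": 0.7,
            "halogen": -0.4,
            "aromatic_ring": -0.6,
        }
    )
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.coefficients) - set(GROUP_FEATURES)
        if unknown:
            raise ValueError(f"unknown group features: {sorted(unknown)}")

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients.get(f, 0.0) for f in GROUP_FEATURES])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedModel":
        return cls(**json.loads(Path(path).read_text()))


_PREFIXES = ["", "O", "N", "F", "Cl", "Br"]
# (smiles tail, carbon cost)
_SUFFIXES = [
    ("", 0),
    ("O", 0),
    ("N", 0),
    ("F", 0),
    ("Cl", 0),
    ("Br", 0),
    ("C(=O)O", 1),
    ("c1ccccc1", 6),
]
_BRANCHES = [("C", 1), ("CC", 2), ("O", 0), ("N", 0), ("F", 0), ("Cl", 0), ("Br", 0)]


def _propose(rng: np.random.Generator, max_carbons: int) -> str | None:
    """Draw one molecule from the fragment grammar, or None if over budget.

    Shape: [prefix]-(C)*k[(branch)]-(C)*m-[suffix]; every emitted string is a
    valid SMILES by construction, so downstream stages see parser-clean input.
    """
    k = int(rng.integers(1, max_carbons + 1))
    carbons = k
    prefix = _PREFIXES[rng.integers(0, len(_PREFIXES))]
    suffix, suffix_cost = _SUFFIXES[rng.integers(0, len(_SUFFIXES))]
    carbons += suffix_cost
    core = "C" * k
    if k >= 2 and rng.random() < 0.4:
        branch, branch_cost = _BRANCHES[rng.integers(0, len(_BRANCHES))]
        carbons += branch_cost
        cut = int(rng.integers(1, k))
        core = "C" * cut + f"({branch})" + "C" * (k - cut)
    if carbons > max_carbons:
        return None
    return prefix + core + suffix


def generate_molecules(n: int, max_carbons: int = 12, seed: int = 0) -> list[str]:
    """Generate *n* distinct valid molecules with 1..max_carbons carbons.

    Grammar-based (alkyl chains, benzene rings, OH/COOH/NH2/F/Cl/Br
    substituents) so every output parses; returned SMILES are canonical and
    unique. Deterministic under *seed*.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if max_carbons < 1:
        raise ValueError("max_carbons must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    limit = 500 * max(n, 1)
    while len(out) < n:
        attempts += 1
        if attempts > limit:
            raise RuntimeError(
                f"grammar exhausted: produced {len(out)}/{n} unique molecules "
                f"with max_carbons={max_carbons}"
            )
        smi = _propose(rng, max_carbons)
        if smi is None:
            continue
        can = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
        if can in seen:
            continue
        seen.add(can)
        out.append(can)
    return out


def assign_logS(smiles_list, model: PlantedModel) -> list[MoleculeRecord]:
    """Attach planted logS values (with noise) to a molecule list."""
    X = group_count_matrix(smiles_list)
    rng = np.random.default_rng(model.seed)
    noise = rng.normal(0.0, model.noise_sd, size=len(smiles_list)) if model.noise_sd > 0 else np.zeros(len(smiles_list))
    y = model.intercept + X @ model.coef_vector + noise
    return [
        MoleculeRecord.from_smiles(smi, float(val), source="synthetic")
        for smi, val in zip(smiles_list, y)
    ]


def inject_duplicates(
    records: list[MoleculeRecord],
    n_exact: int,
    n_conflict: int,
    seed: int = 0,
    conflict_offset: float = 1.0,
) -> list[RawRecord]:
    """Append exact duplicates and conflicting re-measurements.

    Picks *n_exact* + *n_conflict* distinct rows; the first group is copied
    verbatim (curation collapses them), the second is re-measured with logS
    shifted by *conflict_offset* log units (curation drops those molecules).
    Returns raw (smiles, logS, source) rows ready for :func:`aqsol.chem_io.curate`.
    """
    if n_exact + n_conflict > len(records):
        raise ValueError("not enough distinct rows to duplicate")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(records), size=n_exact + n_conflict, replace=False)
    raw = [RawRecord(r.smiles, r.logS, r.source) for r in records]
    for i in picks[:n_exact]:
        r = records[int(i)]
        raw.append(RawRecord(r.smiles, r.logS, r.source + "+dup"))
    for i in picks[n_exact:]:
        r = records[int(i)]
        raw.append(RawRecord(r.smiles, r.logS + conflict_offset, r.source + "+conflict"))
    return raw


def write_simulation(
    raw: list[RawRecord],
    model: PlantedModel,
    csv_path: str | Path,
) -> None:
    """Write the simulated table in the schema chem_io reads, plus the planted
    model as a JSON sidecar (used only by recovery tests)."""
    import pandas as pd

    csv_path = Path(csv_path)
    pd.DataFrame(raw, columns=["smiles", "logS", "source"]).to_csv(csv_path, index=False)
    model.to_json(csv_path.with_suffix(csv_path.suffix + ".planted.json"))
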