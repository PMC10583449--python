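"""Morgan/ECFP4 fingerprints, the bit->substructure atlas, LASSO bit
selection, and bit-frequency statistics.

Circular environments of radius 0-2 (ECFP4: diameter four) are hashed and
folded to 2048 bits. Because folding is many-to-one, interpretation needs the
inverse map: :class:`BitAtlas` records, per bit, the (molecule, center atom,
radius) environments that set it in a given dataset, with the environment's
fragment SMILES.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from rdkit import Chem
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator
from sklearn.linear_model import Lasso

__all__ = [
    "FingerprintMatrix",
    "FragmentEnv",
    "BitAtlas",
    "BitSelection",
    "compute_morgan",
    "bit_info_map",
    "bit_to_substructure",
    "build_bit_atlas",
    "lasso_select",
    "bit_frequency_counts",
    "rare_feature_ratio",
]

#: Default penalty grid for LASSO bit selection (decades from 1e-5 to 10).
DEFAULT_ALPHA_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 0.1, 1.0, 10.0)


def _mol(m: str | Chem.Mol) -> Chem.Mol:
    mol = Chem.MolFromSmiles(m) if isinstance(m, str) else m
    if mol is None:
        raise ValueError(f"invalid molecule: {m!r}")
    return mol


def _generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


@dataclass
class FingerprintMatrix:
    """n x n_bits binary matrix of folded circular-fingerprint bits."""

    bits: np.ndarray  # uint8, entries in {0, 1}
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[1] != self.n_bits:
            raise ValueError(f"expected shape (n, {self.n_bits}), got {self.bits.shape}")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0/1")

    @property
    def bit_ids(self) -> np.ndarray:
        return np.arange(self.n_bits)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape

    def write(self, csv_path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.bits, columns=[f"bit_{i}" for i in range(self.n_bits)]).to_csv(
            csv_path, index=False
        )


def compute_morgan(
    molecules: Iterable[str | Chem.Mol], radius: int = 2, n_bits: int = 2048
) -> FingerprintMatrix:
    """Hash molecules to folded Morgan bit vectors (ECFP4 at the defaults).

    Rows are independent of SMILES spelling and atom numbering: the hash is
    computed on canonical atom invariants.
    """
    gen = _generator(radius, n_bits)
    rows = np.zeros((0, n_bits), dtype=np.uint8)
    out = []
    for m in molecules:
        fp = gen.GetFingerprint(_mol(m))
        arr = np.zeros(n_bits, dtype=np.uint8)
        DataStructs.ConvertToNumpyArray(fp, arr)
        out.append(arr)
    rows = np.vstack(out) if out else rows
    return FingerprintMatrix(rows, radius=radius, n_bits=n_bits)


def bit_info_map(molecule: str | Chem.Mol, radius: int = 2, n_bits: int = 2048) -> dict[int, tuple]:
    """Map each set bit to its ((atom index, radius), ...) environments."""
    gen = _generator(radius, n_bits)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetFingerprint(_mol(molecule), additionalOutput=ao)
    return dict(ao.GetBitInfoMap())


class FragmentEnv(NamedTuple):
    """One circular environment: center atom, radius, fragment SMILES."""

    center_atom: int
    radius: int
    smiles: str


def _environment_smiles(mol: Chem.Mol, atom: int, radius: int) -> str:
    if radius == 0:
        return Chem.MolFragmentToSmiles(mol, atomsToUse=[atom], canonical=True)
    bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom)
    amap: dict[int, int] = {}
    sub = Chem.PathToSubmol(mol, bonds, atomMap=amap)
    return Chem.MolToSmiles(sub, canonical=True)


def bit_to_substructure(
    molecule: str | Chem.Mol, bit_id: int, radius: int = 2, n_bits: int = 2048
) -> list[FragmentEnv]:
    """Return every environment of *molecule* that sets *bit_id*.

    Each returned (center atom, radius) pair re-hashes to *bit_id* — that is
    the defining property, asserted by re-fingerprinting in the test suite.
    Raises if the bit is not set in this molecule.
    """
    mol = _mol(molecule)
    info = bit_info_map(mol, radius, n_bits)
    if bit_id not in info:
        raise ValueError(f"bit {bit_id} is not set for this molecule")
    return [FragmentEnv(a, r, _environment_smiles(mol, a, r)) for a, r in info[bit_id]]


@dataclass
class BitAtlas:
    """Per-bit catalogue of observed environments across a dataset.

    entries[bit] is a list of dicts with keys mol_index, smiles (molecule),
    center_atom, radius, fragment — capped at *max_examples* per bit.
    """

    entries: dict[int, list[dict]] = field(default_factory=dict)
    radius: int = 2
    n_bits: int = 2048

    def fragments(self, bit_id: int) -> list[str]:
        return [e["fragment"] for e in self.entries.get(bit_id, [])]

    def representative_fragment(self, bit_id: int) -> str | None:
        """Most frequently observed fragment SMILES for a bit, if any."""
        frags = self.fragments(bit_id)
        if not frags:
            return None
        uniq, counts = np.unique(frags, return_counts=True)
        return str(uniq[np.argmax(counts)])

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "radius": self.radius,
                    "n_bits": self.n_bits,
                    "entries": {str(k): v for k, v in sorted(self.entries.items())},
                },
                indent=1,
            )
        )


def build_bit_atlas(
    molecules: Sequence[str],
    radius: int = 2,
    n_bits: int = 2048,
    max_examples: int = 8,
) -> BitAtlas:
    """Scan a dataset and record example environments for every observed bit."""
    atlas = BitAtlas(radius=radius, n_bits=n_bits)
    for i, smi in enumerate(molecules):
        mol = _mol(smi)
        for bit, envs in bit_info_map(mol, radius, n_bits).items():
            bucket = atlas.entries.setdefault(bit, [])
            for atom, r in envs:
                if len(bucket) >= max_examples:
                    break
                bucket.append(
                    {
                        "mol_index": i,
                        "smiles": smi,
                        "center_atom": int(atom),
                        "radius": int(r),
                        "fragment": _environment_smiles(mol, atom, r),
                    }
                )
    return atlas


@dataclass
class BitSelection:
    """LASSO bit-selection result over a penalty grid."""

    alpha_grid: tuple
    chosen_alpha: float
    selected_bit_ids: np.ndarray
    n_selected_per_alpha: dict
    coefficients: np.ndarray  # full-width coefficient vector at chosen_alpha

    def __post_init__(self):
        nz = np.flatnonzero(self.coefficients)
        if not np.array_equal(np.sort(self.selected_bit_ids), nz):
            raise ValueError("selected bits must be exactly the nonzero coefficients")


def lasso_select(
    X: FingerprintMatrix | np.ndarray,
    y: np.ndarray,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    chosen_alpha: float = 1e-3,
    tol: float = 1e-6,
    max_iter: int = 50_000,
) -> BitSelection:
    """L1-penalized selection of informative bits.

    Bits are left unstandardized (they share the 0/1 scale) and an intercept
    is fitted. The whole grid is fitted and its selection sizes reported;
    *chosen_alpha* fixes the working selection.
    """
    B = X.bits if isinstance(X, FingerprintMatrix) else np.asarray(X)
    y = np.asarray(y, dtype=float)
    if B.shape[0] != y.shape[0]:
        raise ValueError("X rows must align with y")
    if np.ptp(y) == 0:
        raise ValueError("degenerate target: y is constant")
    if chosen_alpha not in alpha_grid:
        alpha_grid = tuple(alpha_grid) + (chosen_alpha,)
    n_selected = {}
    chosen_coef = None
    for a in alpha_grid:
        model = Lasso(alpha=a, fit_intercept=True, tol=tol, max_iter=max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter at tiny alpha
            model.fit(B, y)
        n_selected[float(a)] = int(np.count_nonzero(model.coef_))
        if a == chosen_alpha:
            chosen_coef = model.coef_.copy()
    return BitSelection(
        alpha_grid=tuple(float(a) for a in alpha_grid),
        chosen_alpha=float(chosen_alpha),
        selected_bit_ids=np.flatnonzero(chosen_coef),
        n_selected_per_alpha=n_selected,
        coefficients=chosen_coef,
    )


def bit_frequency_counts(X: FingerprintMatrix | np.ndarray) -> np.ndarray:
    """Occurrence count per bit: number of molecules with the bit set."""
    B = X.bits if isinstance(X, FingerprintMatrix) else np.asarray(X)
    return B.sum(axis=0).astype(int)


def rare_feature_ratio(
    row: np.ndarray, counts: np.ndarray, rare_threshold: int = 100
) -> float:
    """Fraction of a fingerprint's set bits that are rare in the dataset.

    rare = dataset occurrence count below *rare_threshold*. An all-zero
    fingerprint has no set bits; its ratio is defined as 0 (with a warning).
    """
    row = np.asarray(row)
    on = np.flatnonzero(row)
    if on.size == 0:
        warnings.warn("empty fingerprint: rare-feature ratio defined as 0", stacklevel=2)
        return 0.0
    return float(np.count_nonzero(np.asarray(counts)[on] < rare_threshold) / on.size)
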