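"""2D molecular descriptors and the pruning cascade.

The descriptor engine is RDKit's full 2D descriptor list (geometry-free;
3D descriptors are deliberately out of scope). The cascade reduces the raw
matrix in four audited stages:

1. drop non-numeric / non-finite columns,
2. drop low-variance columns (variance threshold on raw values),
3. greedy pairwise-correlation pruning (keep the earlier column),
4. remove named leakage columns (e.g. a solubility-model output such as
   FilterItLogS, if the engine provides one).

Every stage appends a :class:`StageRecord` so the column accounting chains
from the raw width down to the final working set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

__all__ = [
    "StageRecord",
    "DescriptorMatrix",
    "compute_2d_descriptors",
    "drop_non_numeric",
    "low_variance_filter",
    "pairwise_correlation_prune",
    "exclude_named",
    "full_cascade",
]


@dataclass(frozen=True)
class StageRecord:
    stage: str
    n_before: int
    n_after: int
    removed: tuple[str, ...]


@dataclass
class DescriptorMatrix:
    """n-molecules x p-descriptors table plus its pruning history."""

    values: pd.DataFrame
    stage_log: list[StageRecord] = field(default_factory=list)

    def __post_init__(self):
        names = list(self.values.columns)
        if len(names) != len(set(names)):
            raise ValueError("duplicated descriptor names")
        for a, b in zip(self.stage_log, self.stage_log[1:]):
            if a.n_after != b.n_before:
                raise ValueError(
                    f"stage log does not chain: {a.stage}.n_after={a.n_after} "
                    f"!= {b.stage}.n_before={b.n_before}"
                )

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def _evolve(self, keep: Sequence[str], stage: str) -> "DescriptorMatrix":
        removed = tuple(c for c in self.values.columns if c not in set(keep))
        rec = StageRecord(stage, self.values.shape[1], len(keep), removed)
        return DescriptorMatrix(self.values[list(keep)], self.stage_log + [rec])

    def write(self, csv_path: str | Path) -> None:
        """Persist as CSV with a JSON stage-log sidecar."""
        csv_path = Path(csv_path)
        self.values.to_csv(csv_path, index=False)
        log = [asdict(r) for r in self.stage_log]
        csv_path.with_suffix(csv_path.suffix + ".stages.json").write_text(
            json.dumps(log, indent=2)
        )


def compute_2d_descriptors(molecules: Iterable[str | Chem.Mol]) -> DescriptorMatrix:
    """Compute the engine's full 2D descriptor set, one column per descriptor.

    Accepts SMILES strings or RDKit molecules. Descriptor computations that
    fail for a molecule are recorded as NaN, to be handled by
    :func:`drop_non_numeric`.
    """
    mols = []
    for m in molecules:
        mol = Chem.MolFromSmiles(m) if isinstance(m, str) else m
        if mol is None:
            raise ValueError(f"invalid molecule: {m!r}")
        mols.append(mol)
    if not mols:
        raise ValueError("empty molecule list")
    rows = [Descriptors.CalcMolDescriptors(mol, missingVal=np.nan, silent=True) for mol in mols]
    df = pd.DataFrame(rows)
    return DescriptorMatrix(df, [StageRecord("compute_2d", df.shape[1], df.shape[1], ())])


def drop_non_numeric(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Keep only columns whose every value is a finite real number.

    Booleans/categoricals and columns containing any NaN/inf (failed
    computations) are removed, not imputed.
    """
    keep = []
    for col in matrix.values.columns:
        s = matrix.values[col]
        if not pd.api.types.is_numeric_dtype(s) or pd.api.types.is_bool_dtype(s):
            continue
        if np.isfinite(s.to_numpy(dtype=float)).all():
            keep.append(col)
    if not keep:
        raise ValueError("all columns dropped as non-numeric")
    return matrix._evolve(keep, "drop_non_numeric")


def low_variance_filter(matrix: DescriptorMatrix, threshold: float = 0.1) -> DescriptorMatrix:
    """Drop columns with sample variance below *threshold* (raw values)."""
    if threshold < 0:
        raise ValueError("variance threshold must be >= 0")
    var = matrix.values.var(axis=0, ddof=1)
    keep = [c for c in matrix.values.columns if var[c] >= threshold]
    return matrix._evolve(keep, "low_variance")


def pairwise_correlation_prune(matrix: DescriptorMatrix, cutoff: float = 0.95) -> DescriptorMatrix:
    """Greedy pairwise |Pearson r| pruning in column order.

    Scanning left to right, a column is dropped if it correlates above
    *cutoff* (absolute value) with any already-kept earlier column, so the
    survivor of every offending pair is the earlier one in the engine's
    canonical descriptor order. NaN correlations (possible only for
    zero-variance columns) never trigger a drop.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    X = matrix.values.to_numpy(dtype=float)
    p = X.shape[1]
    if p <= 1 or X.shape[0] < 2:
        return matrix._evolve(list(matrix.values.columns), "pairwise_correlation")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    kept_idx: list[int] = []
    for j in range(p):
        r = np.abs(corr[j, kept_idx]) if kept_idx else np.array([])
        if not np.any(r[~np.isnan(r)] > cutoff):
            kept_idx.append(j)
    keep = [matrix.values.columns[i] for i in kept_idx]
    return matrix._evolve(keep, "pairwise_correlation")


def exclude_named(matrix: DescriptorMatrix, names: Iterable[str] = ("FilterItLogS",)) -> DescriptorMatrix:
    """Remove listed leakage-prone columns; absent names are logged, not errors."""
    names = list(names)
    present = [n for n in names if n in matrix.values.columns]
    keep = [c for c in matrix.values.columns if c not in set(present)]
    out = matrix._evolve(keep, "exclude_named")
    return out


def full_cascade(
    matrix: DescriptorMatrix,
    variance_threshold: float = 0.1,
    corr_cutoff: float = 0.95,
    exclude: Iterable[str] = ("FilterItLogS",),
) -> DescriptorMatrix:
    """Apply the complete pruning cascade in its canonical order."""
    out = drop_non_numeric(matrix)
    out = low_variance_filter(out, variance_threshold)
    out = pairwise_correlation_prune(out, corr_cutoff)
    out = exclude_named(out, exclude)
    return out
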