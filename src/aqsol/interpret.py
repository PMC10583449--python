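"""Model interpretation: SHAP attribution, MLR coefficient ranking, and
fragment Gibbs-energy scoring.

Two complementary views of feature importance are produced: exact tree-SHAP
attributions for the random forest (local, nonlinear) and standardized MLR
coefficients (global, linear). For fingerprint bits the top features are
translated into substructures via the bit atlas and scored thermodynamically
with the Perlovich hydration-energy relation

    dG298 = -0.5 - 1.37 * alpha + 3.84 * sum(Ca) - 2.97 * sum(Cd)

where alpha is molecular polarizability (A^3), Ca/Cd are H-bond
acceptor/donor factors, and the published coefficient uncertainties
(+-1.6, +-0.06, +-0.25, +-0.26) are carried as metadata, not propagated.
A fragment with low dG is hydrated favourably, so it should coincide with a
positive (solubility-raising) SHAP direction; the pipeline reports this
concordance as a Spearman correlation rather than a hard threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from .fingerprints import BitAtlas
from .models import MLRModel
from .treeshap import shap_values

__all__ = [
    "ImportanceReport",
    "shap_importance",
    "coefficient_report",
    "fragment_properties",
    "gibbs_energy",
    "FragmentThermo",
    "fragment_thermo_table",
    "shap_gibbs_concordance",
    "GIBBS_COEFFICIENTS",
    "GIBBS_COEFFICIENT_UNCERTAINTIES",
]

# Perlovich hydration-energy relation: intercept, alpha, sum(Ca), sum(Cd)
GIBBS_COEFFICIENTS = (-0.5, -1.37, 3.84, -2.97)
GIBBS_COEFFICIENT_UNCERTAINTIES = (1.6, 0.06, 0.25, 0.26)  # metadata only

# Atomic polarizabilities (A^3), standard atomic-hybrid values.
_ATOMIC_POLARIZABILITY = {
    1: 0.667,  # H
    5: 3.03,  # B
    6: 1.76,  # C
    7: 1.10,  # N
    8: 0.802,  # O
    9: 0.557,  # F
    15: 3.63,  # P
    16: 2.90,  # S
    17: 2.18,  # Cl
    35: 3.05,  # Br
    53: 5.35,  # I
}


@dataclass
class ImportanceReport:
    """Per-feature SHAP summary with optional MLR coefficients alongside.

    ``table`` columns: feature, mean_abs_shap, direction (sign of the
    Pearson correlation between feature value and its SHAP value),
    mlr_coefficient (NaN when no linear model was supplied); sorted by
    mean_abs_shap descending.
    """

    table: pd.DataFrame
    shap_matrix: np.ndarray  # (n_explained, p) per-sample attributions
    base_value: float
    predictions: np.ndarray

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)

    def local_accuracy_error(self) -> float:
        """max |base + sum(phi) - prediction| over explained rows."""
        return float(
            np.abs(self.base_value + self.shap_matrix.sum(axis=1) - self.predictions).max()
        )


def _directions(X: np.ndarray, Phi: np.ndarray) -> np.ndarray:
    """Sign of corr(feature value, SHAP value) per feature; 0 if degenerate."""
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        x, s = X[:, j], Phi[:, j]
        if np.ptp(x) == 0 or np.ptp(s) == 0:
            continue
        out[j] = np.sign(np.corrcoef(x, s)[0, 1])
    return out


def shap_importance(
    rf_model,
    X_explain,
    feature_names=None,
    mlr_model: MLRModel | None = None,
    max_rows: int = 2000,
    seed: int = 0,
) -> ImportanceReport:
    """Exact tree-SHAP importance for a fitted tree ensemble.

    The explained sample is *X_explain* (normally the training partition),
    subsampled to *max_rows* with a seeded draw if larger. Ranking is by
    mean |SHAP|; per-feature direction is the sign of the correlation
    between feature value and attribution.
    """
    X_explain = np.asarray(X_explain, dtype=float)
    n_feat_model = rf_model.n_features_in_
    if X_explain.shape[1] != n_feat_model:
        raise ValueError(
            f"feature mismatch: model has {n_feat_model}, X_explain has {X_explain.shape[1]}"
        )
    if X_explain.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        X_explain = X_explain[rng.choice(X_explain.shape[0], max_rows, replace=False)]
    Phi, base = shap_values(rf_model, X_explain)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X_explain.shape[1])]
    coef = (
        mlr_model.coefficients.reindex(feature_names).to_numpy()
        if mlr_model is not None
        else np.full(len(feature_names), np.nan)
    )
    table = pd.DataFrame(
        {
            "feature": list(feature_names),
            "mean_abs_shap": np.abs(Phi).mean(axis=0),
            "direction": _directions(X_explain, Phi),
            "mlr_coefficient": coef,
        }
    ).sort_values("mean_abs_shap", ascending=False, kind="stable").reset_index(drop=True)
    return ImportanceReport(
        table=table,
        shap_matrix=Phi,
        base_value=base,
        predictions=np.asarray(rf_model.predict(X_explain), dtype=float),
    )


def coefficient_report(mlr_model: MLRModel, top_k: int | None = None) -> pd.DataFrame:
    """MLR coefficients (standardized scale) ranked by magnitude, sign kept."""
    coefs = mlr_model.coefficients
    df = (
        pd.DataFrame({"feature": coefs.index, "coefficient": coefs.to_numpy()})
        .assign(abs_coefficient=lambda d: d.coefficient.abs())
        .sort_values("abs_coefficient", ascending=False, kind="stable")
        .drop(columns="abs_coefficient")
        .reset_index(drop=True)
    )
    return df.head(top_k) if top_k else df


def _capped_fragment(fragment_smiles: str) -> Chem.Mol:
    """Parse a (possibly valence-open) fragment and cap it with hydrogens.

    Environment fragments extracted from fingerprints may carry aromatic
    atoms without their full ring; those are sanitized with kekulization
    relaxed so hybridization is kept while open valences fill with Hs.
    """
    from rdkit import rdBase

    with rdBase.BlockLogs():
        mol = Chem.MolFromSmiles(fragment_smiles)
        if mol is None:
            mol = Chem.MolFromSmiles(fragment_smiles, sanitize=False)
            if mol is None:
                raise ValueError(f"uncappable fragment: {fragment_smiles!r}")
            mol.UpdatePropertyCache(strict=False)
            Chem.SanitizeMol(
                mol,
                Chem.SanitizeFlags.SANITIZE_ALL
                ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
                catchErrors=True,
            )
    return mol


# Donor/acceptor *sites*: any N/O bearing a hydrogen donates; any N/O accepts.
# Deliberately simpler than druglikeness filters (which exclude e.g. water) so
# that bare-heteroatom fragments such as a lone hydroxyl still score.
_DONOR_QUERY = Chem.MolFromSmarts("[#7,#8;!H0]")
_ACCEPTOR_QUERY = Chem.MolFromSmarts("[#7,#8]")


def fragment_properties(fragment_smiles: str) -> tuple[float, float, float]:
    """(alpha, sum Ca, sum Cd) for a hydrogen-capped fragment.

    alpha is the atomic-polarizability sum over all atoms including the
    capping hydrogens; Ca/Cd count H-bond acceptor and donor sites of the
    capped fragment.
    """
    mol = _capped_fragment(fragment_smiles)
    mol_h = Chem.AddHs(mol)
    alpha = 0.0
    for atom in mol_h.GetAtoms():
        z = atom.GetAtomicNum()
        if z not in _ATOMIC_POLARIZABILITY:
            warnings.warn(f"no polarizability for Z={z}; contributing 0", stacklevel=2)
            continue
        alpha += _ATOMIC_POLARIZABILITY[z]
    ca = float(len(mol.GetSubstructMatches(_ACCEPTOR_QUERY)))
    cd = float(len(mol.GetSubstructMatches(_DONOR_QUERY)))
    return alpha, ca, cd


def gibbs_energy(alpha: float, ca_sum: float, cd_sum: float) -> float:
    """Hydration Gibbs energy at 298 K from the Perlovich linear relation."""
    b0, ba, bca, bcd = GIBBS_COEFFICIENTS
    return b0 + ba * alpha + bca * ca_sum + bcd * cd_sum


@dataclass(frozen=True)
class FragmentThermo:
    """One fragment's thermodynamic score (a Table-4-style row)."""

    bit_id: int
    fragment_smiles: str
    alpha: float
    ca_sum: float
    cd_sum: float
    dg298: float

    def __post_init__(self):
        expected = gibbs_energy(self.alpha, self.ca_sum, self.cd_sum)
        if abs(self.dg298 - expected) > 1e-9:
            raise ValueError("dg298 inconsistent with the Gibbs relation")


def fragment_thermo_table(atlas: BitAtlas, bit_ids) -> pd.DataFrame:
    """Score each bit's representative fragment with the Gibbs relation.

    Bits never observed in the atlas, or with uncappable fragments, get NaN
    rows rather than being dropped, so the output aligns with *bit_ids*.
    """
    rows = []
    for bit in bit_ids:
        frag = atlas.representative_fragment(int(bit))
        alpha = ca = cd = dg = float("nan")
        if frag is not None:
            try:
                alpha, ca, cd = fragment_properties(frag)
                dg = gibbs_energy(alpha, ca, cd)
            except ValueError:
                warnings.warn(f"bit {bit}: fragment {frag!r} could not be scored", stacklevel=2)
        rows.append(
            {
                "bit_id": int(bit),
                "fragment_smiles": frag,
                "alpha": alpha,
                "ca_sum": ca,
                "cd_sum": cd,
                "dg298": dg,
            }
        )
    return pd.DataFrame(rows)


def shap_gibbs_concordance(thermo: pd.DataFrame, importance: ImportanceReport) -> dict:
    """Spearman correlation between fragment dG298 and signed SHAP importance.

    Favourable hydration (low dG) is expected to co-occur with a positive,
    large SHAP contribution; the correlation should therefore be negative.
    Reported as a computed statistic, not a pass/fail gate.
    """
    imp = importance.table.set_index("feature")
    signed = []
    dgs = []
    for _, row in thermo.dropna(subset=["dg298"]).iterrows():
        name = f"bit_{row.bit_id}"
        if name not in imp.index:
            continue
        signed.append(imp.loc[name, "mean_abs_shap"] * imp.loc[name, "direction"])
        dgs.append(row.dg298)
    if len(dgs) < 3:
        return {"spearman_rho": float("nan"), "p_value": float("nan"), "n": len(dgs)}
    rho, p = stats.spearmanr(dgs, signed)
    return {"spearman_rho": float(rho), "p_value": float(p), "n": len(dgs)}
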