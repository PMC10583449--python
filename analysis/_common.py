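"""Shared study conditions and paths for the numbered analysis scripts.

The scripts form one narrative: simulate -> curate -> featurize -> train ->
diagnose -> interpret -> blind-test. Each reads its predecessors' outputs
from RESULTS (or recomputes cheap features from the curated table) and
writes its own tables there.
"""

from pathlib import Path

import numpy as np

from aqsol import chem_io, descriptors, fingerprints

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"
DATA = RESULTS / "data"

# Study conditions (synthetic stand-in for a low-MW organic logS collection)
N_MOLECULES = 1200
MAX_CARBONS = 12
NOISE_SD = 0.5
N_EXACT_DUP = 25
N_CONFLICT = 18
MASTER_SEED = 20
SPLIT_FRACTION = 0.8
RF_TREES = 200
RF_SEED = 42


def curated_dataset():
    raw, bad = chem_io.read_molecule_table(DATA / "synthetic.csv")
    if bad:
        raise RuntimeError(f"{len(bad)} unreadable rows in the simulated table")
    return chem_io.curate(raw)


def feature_matrices(dataset):
    """Recompute both representations from the curated table (cheap, exact)."""
    desc = descriptors.full_cascade(descriptors.compute_2d_descriptors(dataset.smiles))
    fpm = fingerprints.compute_morgan(dataset.smiles)
    y = np.asarray(dataset.logS)
    return desc, fpm, y
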