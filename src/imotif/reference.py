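"""Analysis of the deposited NMR ensembles (PDB 8BV6 / 8BQY).

The two NN4 i-motif ensembles are not bundled with the package and are never
downloaded automatically.  To run the reference analysis, fetch them once by
hand and drop the PDB-format files into ``data/reference/``::

    data/reference/8BV6.pdb    # neutral-pH structure
    data/reference/8BQY.pdb    # acidic-pH structure

(e.g. from https://files.rcsb.org/download/8BV6.pdb).  Everything else in
the package works without them — the synthetic builder covers all tests
that do not target the deposited coordinates themselves.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .structure import Structure, Ensemble, parse_structure, assign_charges
from .geometry import dimensions, ensemble_rmsd
from .titration import TitrationModel, LOOP_EXCLUSION_DEFAULT
from .electrostatics import EnergyModel

__all__ = ["load_reference_ensemble", "ensemble_mean",
           "paper_structure_analysis", "NN4_SEQUENCE",
           "REFERENCE_DIR", "RMSD_EXCLUSION_DEFAULT"]

NN4_SEQUENCE = "CCGTTCCGTTTTTCCGTTCCGT"
REFERENCE_DIR = Path("data") / "reference"

#: disordered loop thymines excluded from the ensemble-RMSD statistic
#: (axial loop + unstacked lateral-loop thymines; tetrad thymines kept)
RMSD_EXCLUSION_DEFAULT = (4, 9, 10, 11, 12, 13, 17, 22)


def load_reference_ensemble(code: str, directory=REFERENCE_DIR) -> Ensemble:
    """Load a manually downloaded deposited ensemble and check its sequence."""
    path = Path(directory) / f"{code.upper()}.pdb"
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found — download {code.upper()}.pdb manually into "
            f"{directory}/ (see imotif.reference docstring); it is not "
            "bundled and never fetched automatically")
    ens = parse_structure(path.read_text(), label=code.upper())
    for k, model in enumerate(ens.models, start=1):
        if model.sequence != NN4_SEQUENCE:
            raise ValueError(
                f"{code} model {k}: sequence {model.sequence} does not match "
                f"NN4 {NN4_SEQUENCE}")
    return ens


def ensemble_mean(ensemble: Ensemble) -> Structure:
    """Structure with coordinates averaged over all models."""
    mean = ensemble.models[0].copy()
    xyz = np.mean([m.coords() for m in ensemble.models], axis=0)
    mean.set_coords(xyz)
    mean.label = f"{ensemble.label}|mean"
    return mean


def paper_structure_analysis(directory=REFERENCE_DIR) -> dict:
    """Recompute the headline numbers from the deposited coordinates.

    Returns macroscopic pKa values of the neutral structure (level-1.5 and
    level-0.5 crossings, two-dielectric energy model), the elongation
    difference between the acidic and neutral mean structures, and both
    ensemble RMSDs with the documented loop exclusion.
    """
    neutral = load_reference_ensemble("8BV6", directory)
    acidic = load_reference_ensemble("8BQY", directory)
    charged = assign_charges(ensemble_mean(neutral))
    model = TitrationModel.from_structure(
        charged, energy_model=EnergyModel(variant="two-dielectric"),
        exclude_residues=LOOP_EXCLUSION_DEFAULT)
    res = model.solve()
    dims_acidic = dimensions(ensemble_mean(acidic))
    dims_neutral = dimensions(ensemble_mean(neutral))
    return {
        "pka_level_1.5": res.curve.pka_at_level(1.5),
        "pka_level_0.5": res.curve.pka_at_level(0.5),
        "elongation_difference": dims_acidic[0] - dims_neutral[0],
        "dims_acidic": dims_acidic,
        "dims_neutral": dims_neutral,
        "rmsd_neutral": ensemble_rmsd(neutral, RMSD_EXCLUSION_DEFAULT),
        "rmsd_acidic": ensemble_rmsd(acidic, RMSD_EXCLUSION_DEFAULT),
    }
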