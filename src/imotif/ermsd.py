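"""eRMSD: a base-centric metric for nucleic-acid conformations.

Each nucleobase gets a local frame from the three canonical six-ring atoms
C2, C4, C6 (origin at their centroid).  The relative position of every other
base in that frame is scaled anisotropically (in-plane 5 Å, normal 3 Å) and
smoothed into a 4-component G-vector that vanishes continuously at a scaled
distance of 2.4; the metric is the root-mean-square difference of G-vectors,

    eRMSD(a, b) = sqrt( Σ_{j≠k} |G_a(j,k) − G_b(j,k)|² / N )

normalised by the number N of included nucleobases (the field convention,
which puts typical folded-vs-unfolded distances on the familiar 0.5–2
scale).  Pairs beyond the cutoff contribute zero vectors, so absent
contacts never add distance.

By default thymines are excluded except those engaged in the minor-groove
tetrads of the acidic structure (T5/T10/T13/T18 in NN4 numbering).
"""

from __future__ import annotations

import numpy as np

from .structure import Structure

__all__ = ["ermsd", "gvectors", "base_frames", "default_ermsd_selection",
           "SelectionError", "MissingRingAtomError",
           "SCALE_PLANE", "SCALE_NORMAL", "CUTOFF"]

RING_ATOMS = ("C2", "C4", "C6")
SCALE_PLANE = 5.0    # Å
SCALE_NORMAL = 3.0   # Å
CUTOFF = 2.4         # scaled units

#: thymines retained by default (tetrad thymines of the acidic structure)
TETRAD_THYMINES = (5, 10, 13, 18)


class SelectionError(ValueError):
    pass


class MissingRingAtomError(ValueError):
    pass


def default_ermsd_selection(structure: Structure) -> list:
    """Residue indices entering the metric: everything but non-tetrad
    thymines."""
    out = []
    for r in structure.residues:
        if r.base == "T" and r.index not in TETRAD_THYMINES:
            continue
        out.append(r.index)
    return out


def ring_coords(structure: Structure, included_residues) -> np.ndarray:
    """(N, 3, 3) array of C2/C4/C6 positions for the included residues."""
    incl = list(included_residues)
    out = np.empty((len(incl), 3, 3))
    pos = {r.index: r for r in structure.residues}
    for i, idx in enumerate(incl):
        if idx not in pos:
            raise SelectionError(f"residue {idx} not in structure")
        r = pos[idx]
        for k, name in enumerate(RING_ATOMS):
            a = r.atom(name)
            if a is None:
                raise MissingRingAtomError(
                    f"residue {r.base}{idx} lacks ring atom {name}")
            out[i, k] = a.coords
    return out


def base_frames(ring: np.ndarray):
    """Frames from (N, 3, 3) ring-atom coordinates.

    Returns (origins (N,3), axes (N,3,3)); axes rows are x̂, ŷ, ẑ with
    x̂ toward C2 and ẑ the base normal; orthonormal to 1e-8.
    """
    origins = ring.mean(axis=1)
    x = ring[:, 0] - origins
    x = x / np.linalg.norm(x, axis=1, keepdims=True)
    v = ring[:, 1] - origins
    z = np.cross(x, v)
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    y = np.cross(z, x)
    return origins, np.stack([x, y, z], axis=1)


def gvectors(ring: np.ndarray) -> np.ndarray:
    """(N, N, 4) smoothed G-vectors for all ordered base pairs (j, k)."""
    origins, axes = base_frames(ring)
    # r[j, k] = position of base k in base j's frame
    rel = origins[None, :, :] - origins[:, None, :]
    local = np.einsum("jab,jkb->jka", axes, rel)
    scaled = local / np.array([SCALE_PLANE, SCALE_PLANE, SCALE_NORMAL])
    rho = np.linalg.norm(scaled, axis=-1)
    np.fill_diagonal(rho, np.inf)
    inside = rho < CUTOFF
    gamma = np.where(inside, np.pi * rho / CUTOFF, np.pi)
    with np.errstate(invalid="ignore", divide="ignore"):
        radial = np.where(inside[..., None],
                          np.sin(gamma)[..., None] * scaled / rho[..., None],
                          0.0)
    fourth = np.where(inside, 1.0 + np.cos(gamma), 0.0)
    return np.concatenate([radial, fourth[..., None]], axis=-1)


def ermsd_from_rings(ring_a: np.ndarray, ring_b: np.ndarray) -> float:
    if ring_a.shape != ring_b.shape:
        raise SelectionError("ring-atom arrays differ in shape")
    ga, gb = gvectors(ring_a), gvectors(ring_b)
    n = ring_a.shape[0]
    return float(np.sqrt(((ga - gb) ** 2).sum() / n))


def ermsd(struct_a: Structure, struct_b: Structure,
          included_residues=None) -> float:
    """eRMSD between two conformations of the same molecule."""
    if included_residues is None:
        sel_a = default_ermsd_selection(struct_a)
        sel_b = default_ermsd_selection(struct_b)
        if sel_a != sel_b:
            raise SelectionError(
                "structures disagree on the default residue selection; "
                "pass included_residues explicitly")
        included_residues = sel_a
    bases_a = {r.index: r.base for r in struct_a.residues}
    bases_b = {r.index: r.base for r in struct_b.residues}
    for idx in included_residues:
        if bases_a.get(idx) != bases_b.get(idx):
            raise SelectionError(f"residue {idx} differs between structures")
    ra = ring_coords(struct_a, included_residues)
    rb = ring_coords(struct_b, included_residues)
    return ermsd_from_rings(ra, rb)
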