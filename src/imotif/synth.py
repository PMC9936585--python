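"""Idealized i-motif fragment builder.

Generates hemiprotonated C:C+ stacks, optionally capped by slipped
minor-groove tetrads (G:C:G:C or G:T:G:T), with known ground truth for the
geometry, electrostatics and dynamics modules.  Residue numbering follows the
NN4 convention d(CCGTTCCGTTTTTCCGTTCCGT): the C:C+ stack uses C1/C2/C6/C7 and
C14/C15/C19/C20, tetrads use G3/G8/G16/G21 with T5/T10/T13/T18 (G:T:G:T) or
C1/C6/C14/C19 (G:C:G:C).

Templates are idealized planar nucleobases (regular hexagon/pentagon rings,
standard bond lengths); they are geometric fixtures, not refined models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, Residue, Structure, StructureError

__all__ = ["BuildSpec", "build_cc_pair", "build_imotif", "perturb",
           "build_gc_pair", "build_gt_pair", "ConfigError"]


class ConfigError(ValueError):
    """Invalid build specification."""


# ---------------------------------------------------------------------------
# Planar base templates
# ---------------------------------------------------------------------------

_RING_BOND = 1.38      # aromatic ring bond length (Å)
_C_O = 1.23            # carbonyl
_C_N = 1.34            # exocyclic amino
_N_H = 1.01
_N_C1P = 1.47          # glycosidic
_C_H = 1.08
_C_C7 = 1.50           # thymine methyl
_HB_NN = 2.80          # C:C+ N3...N3 distance
_HB_WC = 2.90          # WC/wobble heavy-atom H-bond distance
_HB_GG = 2.90          # slipped-tetrad N2...N3 distance


def _hexagon() -> dict:
    """Regular hexagon vertices, ring center at the origin, in the xy-plane."""
    pos = {}
    labels = ["N1", "C2", "N3", "C4", "C5", "C6"]
    for k, lab in enumerate(labels):
        ang = math.radians(90.0 - 60.0 * k)
        pos[lab] = np.array([_RING_BOND * math.cos(ang),
                             _RING_BOND * math.sin(ang), 0.0])
    return pos


def _outward(pos: dict, atom: str, origin=None) -> np.ndarray:
    o = np.zeros(3) if origin is None else origin
    v = pos[atom] - o
    return v / np.linalg.norm(v)


def _place(pos, host, name, bond, direction):
    pos[name] = pos[host] + bond * direction


def _amino_hydrogens(pos, n_atom, host, h1, h2):
    """Two in-plane hydrogens on an exocyclic amino nitrogen, ±60° off axis."""
    axis = _outward({"a": pos[n_atom] - pos[host]}, "a")
    for name, sign in ((h1, +1.0), (h2, -1.0)):
        ang = sign * math.radians(60.0)
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        pos[name] = pos[n_atom] + _N_H * (rot @ axis)


def _cytosine(protonated: bool) -> dict:
    pos = _hexagon()
    _place(pos, "C2", "O2", _C_O, _outward(pos, "C2"))
    _place(pos, "C4", "N4", _C_N, _outward(pos, "C4"))
    _amino_hydrogens(pos, "N4", "C4", "H41", "H42")
    _place(pos, "C5", "H5", _C_H, _outward(pos, "C5"))
    _place(pos, "C6", "H6", _C_H, _outward(pos, "C6"))
    _place(pos, "N1", "C1'", _N_C1P, _outward(pos, "N1"))
    if protonated:
        _place(pos, "N3", "H3", _N_H + 0.02, _outward(pos, "N3"))
    return pos


def _thymine() -> dict:
    pos = _hexagon()
    _place(pos, "C2", "O2", _C_O, _outward(pos, "C2"))
    _place(pos, "C4", "O4", _C_O, _outward(pos, "C4"))
    _place(pos, "N3", "H3", _N_H, _outward(pos, "N3"))
    _place(pos, "C5", "C7", _C_C7, _outward(pos, "C5"))
    _place(pos, "C6", "H6", _C_H, _outward(pos, "C6"))
    _place(pos, "N1", "C1'", _N_C1P, _outward(pos, "N1"))
    return pos


def _purine(base: str) -> dict:
    """Guanine or adenine: hexagon fused with a regular pentagon on C4-C5."""
    pos = _hexagon()
    a, b = pos["C5"], pos["C4"]          # shared edge, pentagon outside
    mid = (a + b) / 2.0
    edge = float(np.linalg.norm(b - a))
    apothem = edge / (2.0 * math.tan(math.radians(36.0)))
    # pentagon center lies on the far side of the C4-C5 edge from the hexagon
    center5 = mid + apothem * (mid / np.linalg.norm(mid))
    radius5 = edge / (2.0 * math.sin(math.radians(36.0)))
    ang_a = math.atan2(a[1] - center5[1], a[0] - center5[0])
    ang_b = math.atan2(b[1] - center5[1], b[0] - center5[0])
    step = (ang_b - ang_a + math.pi) % (2 * math.pi) - math.pi  # signed 72°
    # remaining vertices run the other way around: C5-N7-C8-N9-C4
    for k, lab in enumerate(["N7", "C8", "N9"], start=1):
        ang = ang_a - k * step
        pos[lab] = center5 + radius5 * np.array([math.cos(ang), math.sin(ang), 0.0])
    five_center = center5
    if base == "G":
        _place(pos, "C6", "O6", _C_O, _outward(pos, "C6"))
        _place(pos, "N1", "H1", _N_H, _outward(pos, "N1"))
        _place(pos, "C2", "N2", _C_N, _outward(pos, "C2"))
        _amino_hydrogens(pos, "N2", "C2", "H21", "H22")
    else:
        _place(pos, "C6", "N6", _C_N, _outward(pos, "C6"))
        _amino_hydrogens(pos, "N6", "C6", "H61", "H62")
        _place(pos, "C2", "H2", _C_H, _outward(pos, "C2"))
    _place(pos, "C8", "H8", _C_H, _outward(pos, "C8", five_center))
    _place(pos, "N9", "C1'", _N_C1P, _outward(pos, "N9", five_center))
    return pos


_TEMPLATES = {
    "C": lambda: _cytosine(False),
    "C+": lambda: _cytosine(True),
    "T": _thymine,
    "G": lambda: _purine("G"),
    "A": lambda: _purine("A"),
}


def _ring_center(pos: dict) -> np.ndarray:
    return np.mean([pos[n] for n in ("N1", "C2", "N3", "C4", "C5", "C6")], axis=0)


def _make_residue(pos: dict, base: str, index: int, chain: str = "A",
                  protonated: bool = False) -> Residue:
    from .structure import _BASE_ATOMS, _element_from_name
    order = sorted(pos.keys(), key=lambda n: (n == "C1'", n))
    atoms = [Atom(name=n, element=_element_from_name(n), coords=pos[n],
                  is_base_atom=n in _BASE_ATOMS[base])
             for n in order]
    return Residue(index=index, base=base, chain=chain, atoms=atoms,
                   protonated=protonated)


# ---------------------------------------------------------------------------
# Rigid placement helpers
# ---------------------------------------------------------------------------

def _rot_z_about(pos: dict, point: np.ndarray) -> dict:
    """180° rotation about the vertical axis through ``point`` (in-plane C2)."""
    out = {}
    for n, p in pos.items():
        out[n] = np.array([2 * point[0] - p[0], 2 * point[1] - p[1], p[2]])
    return out


def _flip(pos: dict) -> dict:
    """Flip the base over (y -> -y): antiparallel partner orientation."""
    return {n: np.array([p[0], -p[1], -p[2]]) for n, p in pos.items()}


def _fit_2d(pos: dict, pairs: list) -> dict:
    """Rigidly move a planar template so that named atoms hit target points.

    ``pairs`` is a list of (atom_name, target_xy) tuples; least-squares 2D
    Kabsch with a proper rotation.
    """
    P = np.array([pos[n][:2] for n, _ in pairs])
    Q = np.array([t[:2] for _, t in pairs])
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    out = {}
    for n, p in pos.items():
        xy = R @ (p[:2] - cp) + cq
        out[n] = np.array([xy[0], xy[1], p[2]])
    return out


def _transform(pos: dict, azimuth_deg: float = 0.0,
               dz: float = 0.0, origin: np.ndarray | None = None) -> dict:
    """Center at ``origin``, rotate about z by azimuth, lift by dz."""
    o = np.zeros(3) if origin is None else origin
    a = math.radians(azimuth_deg)
    c, s = math.cos(a), math.sin(a)
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    return {n: R @ (p - o) + np.array([0, 0, dz]) for n, p in pos.items()}


# ---------------------------------------------------------------------------
# Base pairs
# ---------------------------------------------------------------------------

def _cc_pair_positions(protonated: bool) -> tuple[dict, dict, np.ndarray]:
    """C:C(+) pair coordinates; returns (base_a, base_b, pair_center)."""
    a = _TEMPLATES["C+" if protonated else "C"]()
    u = _outward(a, "N3")
    center = a["N3"] + (_HB_NN / 2.0) * u
    b_tmpl = _TEMPLATES["C"]()
    b = _rot_z_about(b_tmpl, center)
    return a, b, center


def build_cc_pair(protonated: bool = True, index_a: int = 1, index_b: int = 2,
                  chain: str = "A") -> Structure:
    """Planar C:C(+) pair in the three-H-bond geometry (N3...N3 shared proton
    flanked by two N4-H...O2 bonds); residue ``index_a`` carries the proton."""
    a, b, center = _cc_pair_positions(protonated)
    a = {n: p - center for n, p in a.items()}
    b = {n: p - center for n, p in b.items()}
    res = [_make_residue(a, "C", index_a, chain, protonated=protonated),
           _make_residue(b, "C", index_b, chain)]
    res.sort(key=lambda r: r.index)
    return Structure(res, label="cc_pair")


def _gc_pair_positions() -> tuple[dict, dict]:
    """Watson-Crick G:C pair (G first), G template frame."""
    g = _TEMPLATES["G"]()
    c = _TEMPLATES["C"]()   # clockwise template viewed from the back = antiparallel
    # the three H-bonds of a WC pair run roughly parallel to the pair axis,
    # taken as the outward direction at G:N1
    u = _outward(g, "N1")
    targets = [
        ("N3", g["N1"] + _HB_WC * u),
        ("N4", g["O6"] + _HB_WC * u),
        ("O2", g["N2"] + _HB_WC * u),
    ]
    c = _fit_2d(c, targets)
    return g, c


def _gt_pair_positions() -> tuple[dict, dict]:
    """Wobble G:T pair (G first): G N1-H...O2(T) and T N3-H...O6(G)."""
    g = _TEMPLATES["G"]()
    t = _TEMPLATES["T"]()   # antiparallel partner (see _gc_pair_positions)
    u = _outward(g, "N1")      # both wobble H-bonds parallel to the pair axis
    targets = [
        ("O2", g["N1"] + _HB_WC * u),
        ("N3", g["O6"] + _HB_WC * u),
    ]
    t = _fit_2d(t, targets)
    return g, t


def build_gc_pair(index_g: int = 1, index_c: int = 2, chain: str = "A") -> Structure:
    g, c = _gc_pair_positions()
    res = sorted([_make_residue(g, "G", index_g, chain),
                  _make_residue(c, "C", index_c, chain)], key=lambda r: r.index)
    return Structure(res, label="gc_pair")


def build_gt_pair(index_g: int = 1, index_t: int = 2, chain: str = "A") -> Structure:
    g, t = _gt_pair_positions()
    res = sorted([_make_residue(g, "G", index_g, chain),
                  _make_residue(t, "T", index_t, chain)], key=lambda r: r.index)
    return Structure(res, label="gt_pair")


def _tetrad_positions(kind: str) -> tuple[list, np.ndarray]:
    """Slipped minor-groove tetrad from two pairs joined by the two
    inter-guanine N2-H...N3 bonds.  Returns ([(posdict, base)...], center)."""
    if kind == "GCGC":
        g1, p1 = _gc_pair_positions()
        partner_base = "C"
    elif kind == "GTGT":
        g1, p1 = _gt_pair_positions()
        partner_base = "T"
    else:
        raise ConfigError(f"unknown tetrad kind {kind!r}")
    edge_mid = (g1["N2"] + g1["N3"]) / 2.0
    u = _outward({"m": edge_mid - _ring_center(g1)}, "m")
    m = edge_mid + (_HB_GG / 2.0) * u
    g2 = _rot_z_about(g1, m)
    p2 = _rot_z_about(p1, m)
    return [(g2, "G"), (p2, partner_base), (g1, "G"), (p1, partner_base)], m


# ---------------------------------------------------------------------------
# BuildSpec and the full fragment builder
# ---------------------------------------------------------------------------

@dataclass
class BuildSpec:
    n_cc_pairs: int = 2
    rise: float = 3.1
    twist: float = 30.0
    capping: str = "none"          # none | GCGC | GTGT
    topology: str = "3E"           # 3E | 5E
    seed: int = 0
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.n_cc_pairs < 1:
            raise ConfigError("n_cc_pairs must be >= 1")
        if self.rise <= 0:
            raise ConfigError("rise must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.capping not in ("none", "GCGC", "GTGT"):
            raise ConfigError(f"unknown capping {self.capping!r}")
        if self.topology not in ("3E", "5E"):
            raise ConfigError(f"unknown topology {self.topology!r}")


# NN4-numbering pair stacks, listed bottom (z=0) to top.
_STACKS = {
    "3E": {1: [(2, 20)], 2: [(2, 20), (7, 15)],
           3: [(2, 20), (6, 14), (1, 19)],
           4: [(2, 20), (6, 14), (1, 19), (7, 15)]},
    "5E": {1: [(1, 19)], 2: [(1, 19), (6, 14)],
           3: [(1, 19), (7, 15), (2, 20)],
           4: [(1, 19), (7, 15), (2, 20), (6, 14)]},
}

# Tetrad residue numbers: (G_pair1, partner_pair1, G_pair2, partner_pair2).
# For G:C:G:C capping the tetrad cytosines are the four not engaged in the
# C:C+ stack, which depends on the stack topology.
_TETRAD_IDS = {
    ("GTGT", "3E"): {"top": (3, 18, 16, 5), "bottom": (8, 13, 21, 10)},
    ("GTGT", "5E"): {"top": (3, 18, 16, 5), "bottom": (8, 13, 21, 10)},
    ("GCGC", "3E"): {"top": (3, 14, 16, 1), "bottom": (8, 19, 21, 6)},
    ("GCGC", "5E"): {"top": (3, 15, 16, 2), "bottom": (8, 20, 21, 7)},
}


def build_imotif(spec: BuildSpec) -> Structure:
    """Intercalated C:C+ stack, optionally capped by two slipped tetrads."""
    n = spec.n_cc_pairs
    if n > 4:
        raise ConfigError("NN4-numbered fragments support at most 4 C:C+ pairs")
    if spec.capping == "GCGC" and n > 2:
        raise ConfigError("G:C:G:C capping reuses cytosines C1/C6/C14/C19; "
                          "n_cc_pairs must be <= 2")
    stack = _STACKS[spec.topology][n]
    residues = []
    for level, (ia, ib) in enumerate(stack):
        a, b, center = _cc_pair_positions(protonated=True)
        az = level * spec.twist + (90.0 if level % 2 else 0.0)
        a = _transform(a, az, level * spec.rise, center)
        b = _transform(b, az, level * spec.rise, center)
        residues.append(_make_residue(a, "C", ia, protonated=True))
        residues.append(_make_residue(b, "C", ib))
    if spec.capping != "none":
        ids = _TETRAD_IDS[(spec.capping, spec.topology)]
        z_top = len(stack) * spec.rise
        z_bot = -spec.rise
        for where, dz, az in (("top", z_top, len(stack) * spec.twist + 45.0),
                              ("bottom", z_bot, -spec.twist - 45.0)):
            bases, center = _tetrad_positions(spec.capping)
            g1, p1, g2, p2 = ids[where]
            numbers = [g1, p1, g2, p2]
            for (pos, base), num in zip(bases, numbers):
                pos = _transform(pos, az, dz, center)
                residues.append(_make_residue(pos, base, num))
    residues.sort(key=lambda r: r.index)
    struct = Structure(residues, label=f"imotif_{n}cc_{spec.capping}_{spec.topology}")
    if spec.noise_sigma > 0:
        struct = perturb(struct, spec.noise_sigma, spec.seed)
        struct.label = f"imotif_{n}cc_{spec.capping}_{spec.topology}"
    return struct


def perturb(structure: Structure, sigma: float, seed: int = 0) -> Structure:
    """i.i.d. Gaussian coordinate jitter; same seed, same output."""
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    out = structure.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    xyz = out.coords()
    out.set_coords(xyz + rng.normal(0.0, sigma, size=xyz.shape))
    out.label = f"{structure.label}|perturbed"
    return out
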