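"""Geometric annotation of i-motif structures.

Hydrogen bonds, base-pair and minor-groove-tetrad classification,
intercalation topology, sugar pseudorotation, glycosidic classes, global
dimensions and ensemble RMSD.

Conventions
-----------
* H-bond detection: heavy donor-acceptor distance <= 3.5 Å and, when the
  donor carries a hydrogen, a D-H...A angle >= 120°; both configurable.
* C:C+ pairs require the shared N3...N3 contact plus at least one
  N4-H...O2 bond in each direction; Watson-Crick G:C requires
  N1(G)...N3(C) plus one of O6...N4 / N2...O2; wobble G:T requires both
  N1(G)...O2(T) and N3(T)...O6(G).
* A minor-groove tetrad is two base pairs joined by inter-guanine
  N2-H...N3 bonds; "slipped" when both reciprocal bonds are present.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Structure, Ensemble, Residue, StructureError

__all__ = [
    "HBond", "BasePair", "Tetrad", "GeometryReport",
    "detect_hbonds", "classify_pairs_and_tetrads", "pseudorotation",
    "generate_ring_torsions", "classify_glycosidic", "classify_pucker",
    "dimensions", "ensemble_rmsd", "intercalation_topology",
    "sugar_torsions", "glycosidic_chi", "describe",
]

# donor atoms (with their hydrogens) per base; acceptors per base
_DONORS = {
    "A": {"N6": ("H61", "H62")},
    "G": {"N1": ("H1",), "N2": ("H21", "H22")},
    "C": {"N4": ("H41", "H42"), "N3": ("H3",)},   # N3 donates only when protonated
    "T": {"N3": ("H3",)},
}
_ACCEPTORS = {
    "A": {"N1", "N3", "N7"},
    "G": {"O6", "N3", "N7"},
    "C": {"O2", "N3"},
    "T": {"O2", "O4"},
}


class DegeneratePuckerError(ValueError):
    pass


class EmptySelectionError(ValueError):
    pass


@dataclass
class HBond:
    donor_res: Residue
    donor_atom: str
    acceptor_res: Residue
    acceptor_atom: str
    distance: float
    angle: float | None = None     # D-H...A angle, degrees, if H present

    def key(self):
        return ((self.donor_res.chain, self.donor_res.index, self.donor_atom),
                (self.acceptor_res.chain, self.acceptor_res.index,
                 self.acceptor_atom))


@dataclass
class BasePair:
    res_a: Residue
    res_b: Residue
    pair_class: str                # CC+ | WC-GC | wobble-GT | other
    hbonds: list = field(default_factory=list)

    @property
    def indices(self):
        return tuple(sorted((self.res_a.index, self.res_b.index)))


@dataclass
class Tetrad:
    pair_1: BasePair
    pair_2: BasePair
    tetrad_class: str              # G:C:G:C | G:T:G:T | G:C:G:T | other
    slipped: bool
    gg_bonds: list = field(default_factory=list)


@dataclass
class GeometryReport:
    label: str
    pairs: list
    tetrads: list
    topology: str
    dims: tuple
    pucker: dict                   # residue index -> (P, amplitude, class)
    glycosidic: dict               # residue index -> (chi, class)
    ensemble_rmsd: float | None = None

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "pairs": [{"residues": p.indices, "class": p.pair_class,
                       "n_hbonds": len(p.hbonds)} for p in self.pairs],
            "tetrads": [{"class": t.tetrad_class, "slipped": t.slipped,
                         "residues": sorted(t.pair_1.indices + t.pair_2.indices)}
                        for t in self.tetrads],
            "topology": self.topology,
            "dimensions": [round(float(d), 2) for d in self.dims],
            "pucker": {k: {"P": round(v[0], 1), "amplitude": round(v[1], 1),
                           "class": v[2]} for k, v in self.pucker.items()},
            "glycosidic": {k: {"chi": round(v[0], 1), "class": v[1]}
                           for k, v in self.glycosidic.items()},
            "ensemble_rmsd": (None if self.ensemble_rmsd is None
                              else round(float(self.ensemble_rmsd), 3)),
        }


# ---------------------------------------------------------------------------
# Hydrogen bonds / pairs / tetrads
# ---------------------------------------------------------------------------

def detect_hbonds(structure: Structure, max_dist: float = 3.5,
                  min_angle: float = 120.0) -> list:
    """All inter-residue base-base donor->acceptor contacts."""
    entries = []   # (residue, donor_name, donor_xyz, [h_xyz...])
    accs = []      # (residue, acceptor_name, xyz)
    for r in structure.residues:
        for dn, hs in _DONORS[r.base].items():
            if r.base == "C" and dn == "N3" and not r.protonated:
                continue
            d = r.atom(dn)
            if d is None:
                continue
            h_xyz = [r.atom(h).coords for h in hs if r.atom(h) is not None]
            entries.append((r, dn, d.coords, h_xyz))
        for an in _ACCEPTORS[r.base]:
            if r.base == "C" and an == "N3" and r.protonated:
                continue
            a = r.atom(an)
            if a is not None:
                accs.append((r, an, a.coords))
    bonds = []
    seen = set()
    for (rd, dn, dxyz, hxyz) in entries:
        for (ra, an, axyz) in accs:
            if ra is rd:
                continue
            dist = float(np.linalg.norm(dxyz - axyz))
            if dist > max_dist:
                continue
            angle = None
            if hxyz:
                best = -1.0
                for h in hxyz:
                    v1 = dxyz - h
                    v2 = axyz - h
                    cosang = float(np.dot(v1, v2) /
                                   (np.linalg.norm(v1) * np.linalg.norm(v2)))
                    best = max(best, math.degrees(math.acos(np.clip(cosang, -1, 1))))
                angle = best
                if angle < min_angle:
                    continue
            hb = HBond(rd, dn, ra, an, dist, angle)
            if hb.key() in seen:
                continue
            seen.add(hb.key())
            bonds.append(hb)
    return bonds


def _bond_set(hbonds, res_a, res_b):
    """Directional (donor_base:atom -> acceptor_base:atom) contacts between
    two residues, as a set of strings like 'C:N3>C:N3'."""
    out = {}
    for hb in hbonds:
        if hb.donor_res is res_a and hb.acceptor_res is res_b:
            out[f"{res_a.base}:{hb.donor_atom}>{res_b.base}:{hb.acceptor_atom}"] = hb
        elif hb.donor_res is res_b and hb.acceptor_res is res_a:
            out[f"{res_b.base}:{hb.donor_atom}<{res_a.base}:{hb.acceptor_atom}"] = hb
    return out


def _classify_pair(res_a, res_b, hbonds) -> BasePair | None:
    pair_bonds = [hb for hb in hbonds
                  if {id(hb.donor_res), id(hb.acceptor_res)} == {id(res_a), id(res_b)}]
    if not pair_bonds:
        return None
    names = set()
    for hb in pair_bonds:
        names.add((hb.donor_res.base, hb.donor_atom,
                   hb.acceptor_res.base, hb.acceptor_atom,
                   hb.donor_res is res_a))
    bases = {res_a.base, res_b.base}
    cls = "other"
    if bases == {"C"}:
        nn = any(n[1] == "N3" and n[3] == "N3" for n in names)
        n4o2_ab = any(n[1] == "N4" and n[3] == "O2" and n[4] for n in names)
        n4o2_ba = any(n[1] == "N4" and n[3] == "O2" and not n[4] for n in names)
        if nn and n4o2_ab and n4o2_ba:
            cls = "CC+"
    elif bases == {"G", "C"}:
        n1n3 = any({(n[0], n[1]), (n[2], n[3])} == {("G", "N1"), ("C", "N3")}
                   for n in names)
        o6n4 = any({(n[0], n[1]), (n[2], n[3])} == {("C", "N4"), ("G", "O6")}
                   for n in names)
        n2o2 = any({(n[0], n[1]), (n[2], n[3])} == {("G", "N2"), ("C", "O2")}
                   for n in names)
        if n1n3 and (o6n4 or n2o2):
            cls = "WC-GC"
    elif bases == {"G", "T"}:
        n1o2 = any((n[0], n[1], n[2], n[3]) == ("G", "N1", "T", "O2") for n in names)
        n3o6 = any((n[0], n[1], n[2], n[3]) == ("T", "N3", "G", "O6") for n in names)
        if n1o2 and n3o6:
            cls = "wobble-GT"
    if cls == "other" and len(pair_bonds) < 2:
        return None
    return BasePair(res_a, res_b, cls, pair_bonds)


def classify_pairs_and_tetrads(structure: Structure, max_dist: float = 3.5,
                               min_angle: float = 120.0):
    """Classify base pairs by H-bond pattern and group them into tetrads."""
    hbonds = detect_hbonds(structure, max_dist, min_angle)
    pairs = []
    claimed = set()
    candidates = []
    for ra, rb in itertools.combinations(structure.residues, 2):
        bp = _classify_pair(ra, rb, hbonds)
        if bp is not None:
            candidates.append(bp)
    # prefer classified pairs, then more H-bonds; one pairing per residue
    order = {"CC+": 0, "WC-GC": 0, "wobble-GT": 0, "other": 1}
    for bp in sorted(candidates, key=lambda p: (order[p.pair_class], -len(p.hbonds))):
        ka = (bp.res_a.chain, bp.res_a.index)
        kb = (bp.res_b.chain, bp.res_b.index)
        if ka in claimed or kb in claimed:
            continue
        claimed.update((ka, kb))
        pairs.append(bp)
    # tetrads: pair pairs joined by inter-guanine N2-H...N3 bond(s)
    tetrads = []
    gg = [hb for hb in hbonds
          if hb.donor_res.base == "G" and hb.acceptor_res.base == "G"
          and hb.donor_atom == "N2" and hb.acceptor_atom == "N3"]
    paired_pairs = [p for p in pairs if p.pair_class in ("WC-GC", "wobble-GT")]
    for p1, p2 in itertools.combinations(paired_pairs, 2):
        res1 = {id(p1.res_a), id(p1.res_b)}
        res2 = {id(p2.res_a), id(p2.res_b)}
        links = [hb for hb in gg
                 if (id(hb.donor_res) in res1 and id(hb.acceptor_res) in res2)
                 or (id(hb.donor_res) in res2 and id(hb.acceptor_res) in res1)]
        if not links:
            continue
        slipped = (any(id(hb.donor_res) in res1 for hb in links)
                   and any(id(hb.donor_res) in res2 for hb in links))
        classes = sorted([p1.pair_class, p2.pair_class])
        if classes == ["WC-GC", "WC-GC"]:
            tcls = "G:C:G:C"
        elif classes == ["wobble-GT", "wobble-GT"]:
            tcls = "G:T:G:T"
        else:
            tcls = "G:C:G:T"
        tetrads.append(Tetrad(p1, p2, tcls, slipped, links))
    return pairs, tetrads


# ---------------------------------------------------------------------------
# Sugar pucker and glycosidic torsions
# ---------------------------------------------------------------------------

def pseudorotation(nu) -> tuple[float, float]:
    """Pseudorotation phase P (degrees, in [0, 360)) and puckering amplitude
    from the five endocyclic sugar torsions ν0..ν4 (degrees)."""
    nu = [float(x) for x in nu]
    if len(nu) != 5 or not all(math.isfinite(x) for x in nu):
        raise ValueError("five finite torsions required")
    num = (nu[4] + nu[1]) - (nu[3] + nu[0])
    den = 2.0 * nu[2] * (math.sin(math.radians(36.0)) +
                         math.sin(math.radians(72.0)))
    if abs(den) < 1e-12 and abs(num) < 1e-12:
        raise DegeneratePuckerError("flat ring: phase undefined")
    p = math.degrees(math.atan2(num, den)) % 360.0
    cosp = math.cos(math.radians(p))
    if abs(cosp) < 1e-9:
        amplitude = abs(num) / (2.0 * (math.sin(math.radians(36.0)) +
                                       math.sin(math.radians(72.0))))
    else:
        amplitude = nu[2] / cosp
    return p, amplitude


def generate_ring_torsions(p: float, tau_m: float) -> list:
    """Inverse of :func:`pseudorotation`: ν_j = τ_m·cos(P + 144°·(j−2))."""
    return [tau_m * math.cos(math.radians(p + 144.0 * (j - 2)))
            for j in range(5)]


def classify_pucker(p: float) -> str:
    """north for P around 0, south for the constrained [144°,180°] interval,
    southeast between, else other."""
    p = p % 360.0
    if p < 90.0 or p >= 270.0:
        return "north"
    if 144.0 <= p <= 180.0:
        return "south"
    if 90.0 <= p < 144.0:
        return "southeast"
    return "other"


def classify_glycosidic(chi: float) -> str:
    """Fixed-window classification of the glycosidic torsion χ (degrees)."""
    if not -180.0 < chi <= 180.0:
        raise ValueError("chi must lie in (-180, 180]")
    if -120.0 < chi <= -60.0:
        return "anti"
    if -60.0 < chi <= 0.0:
        return "high-anti"
    if 0.0 < chi <= 90.0:
        return "syn"
    return "other"


def _torsion(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


_RING_PATH = ["C4'", "O4'", "C1'", "C2'", "C3'"]


def sugar_torsions(residue: Residue) -> list | None:
    """ν0..ν4 from the furanose ring atoms, or None if atoms are missing."""
    ring = {}
    for name in _RING_PATH:
        a = residue.atom(name)
        if a is None:
            return None
        ring[name] = a.coords
    seq = ["C4'", "O4'", "C1'", "C2'", "C3'"]
    nus = []
    for j in range(5):
        quad = [ring[seq[(j + k) % 5]] for k in range(4)]
        nus.append(_torsion(*quad))
    return nus


def glycosidic_chi(residue: Residue) -> float | None:
    """χ torsion: O4'-C1'-N1-C2 (pyrimidines) or O4'-C1'-N9-C4 (purines)."""
    if residue.base in ("C", "T"):
        names = ["O4'", "C1'", "N1", "C2"]
    else:
        names = ["O4'", "C1'", "N9", "C4"]
    pts = []
    for n in names:
        a = residue.atom(n)
        if a is None:
            return None
        pts.append(a.coords)
    return _torsion(*pts)


# ---------------------------------------------------------------------------
# Dimensions, RMSD, topology
# ---------------------------------------------------------------------------

def _heavy_coords(structure: Structure, exclude_residues=()):
    excl = set(exclude_residues)
    pts = []
    for r in structure.residues:
        if r.index in excl:
            continue
        for a in r.atoms:
            if a.element != "H":
                pts.append(a.coords)
    return np.array(pts)


def dimensions(structure: Structure) -> tuple:
    """Extents of heavy atoms along the principal axes of the coordinate
    covariance, sorted L1 >= L2 >= L3 (Å)."""
    pts = _heavy_coords(structure)
    if len(pts) < 4:
        raise StructureError("need >= 4 heavy atoms")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    if np.linalg.matrix_rank(cov, tol=1e-10) < 1:
        raise StructureError("degenerate geometry")
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs
    ext = proj.max(axis=0) - proj.min(axis=0)
    return tuple(sorted((float(e) for e in ext), reverse=True))


def _kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD after optimal least-squares superposition of P onto Q."""
    p = P - P.mean(axis=0)
    q = Q - Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(q, p)
    diff = rot.apply(p) - q
    return float(np.sqrt((diff ** 2).sum() / len(p)))


def ensemble_rmsd(ensemble: Ensemble, exclude_residues=()) -> float:
    """Mean pairwise heavy-atom RMSD after optimal superposition."""
    if len(ensemble) < 2:
        raise StructureError("need >= 2 models")
    coords = [_heavy_coords(m, exclude_residues) for m in ensemble]
    if any(len(c) == 0 for c in coords):
        raise EmptySelectionError("exclusion removed all atoms")
    vals = [_kabsch_rmsd(a, b)
            for a, b in itertools.combinations(coords, 2)]
    return float(np.mean(vals))


def _c_tracts(structure: Structure) -> dict:
    """Map cytosine (chain,index) -> ('5p'|'3p'|'mid'|'single') within its
    maximal run of consecutive cytosines in the sequence numbering."""
    by_chain: dict[str, list[int]] = {}
    for r in structure.residues:
        if r.base == "C":
            by_chain.setdefault(r.chain, []).append(r.index)
    out = {}
    for chain, idxs in by_chain.items():
        idxs = sorted(idxs)
        runs = []
        run = [idxs[0]]
        for i in idxs[1:]:
            if i == run[-1] + 1:
                run.append(i)
            else:
                runs.append(run)
                run = [i]
        runs.append(run)
        for run in runs:
            for i in run:
                if len(run) == 1:
                    out[(chain, i)] = "single"
                elif i == run[0]:
                    out[(chain, i)] = "5p"
                elif i == run[-1]:
                    out[(chain, i)] = "3p"
                else:
                    out[(chain, i)] = "mid"
    return out


def intercalation_topology(structure: Structure, pairs) -> str:
    """3E if the outermost C:C+ pairs engage the 3'-end cytosines of their
    C-tracts, 5E for the 5'-end; none when undetermined."""
    cc = [p for p in pairs if p.pair_class == "CC+"]
    if len(cc) < 2:
        return "none"
    centers = []
    for p in cc:
        pts = np.concatenate([p.res_a.coords(), p.res_b.coords()])
        centers.append(pts.mean(axis=0))
    centers = np.array(centers)
    axis_dir = centers - centers.mean(axis=0)
    # principal axis of the pair centers = stack axis
    _, _, vt = np.linalg.svd(axis_dir)
    z = centers @ vt[0]
    order = np.argsort(z)
    outer = [cc[order[0]], cc[order[-1]]]
    tracts = _c_tracts(structure)
    sides = []
    for p in outer:
        for r in (p.res_a, p.res_b):
            sides.append(tracts.get((r.chain, r.index), "single"))
    if all(s == "3p" for s in sides):
        return "3E"
    if all(s == "5p" for s in sides):
        return "5E"
    return "none"


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def describe(obj: Structure | Ensemble, exclude_residues=()) -> GeometryReport:
    """Full geometric annotation of a structure or NMR-style ensemble.

    For an ensemble, pairs/tetrads/topology/dimensions are computed on the
    first model and the mean pairwise RMSD on all models.
    """
    if isinstance(obj, Ensemble):
        structure = obj.models[0]
        rmsd = ensemble_rmsd(obj, exclude_residues) if len(obj) > 1 else None
        label = obj.label or structure.label
    else:
        structure = obj
        rmsd = None
        label = obj.label
    pairs, tetrads = classify_pairs_and_tetrads(structure)
    topo = intercalation_topology(structure, pairs)
    dims = dimensions(structure)
    pucker = {}
    chi_map = {}
    for r in structure.residues:
        nus = sugar_torsions(r)
        if nus is not None:
            try:
                p, amp = pseudorotation(nus)
                pucker[r.index] = (p, amp, classify_pucker(p))
            except DegeneratePuckerError:
                pass
        chi = glycosidic_chi(r)
        if chi is not None:
            chi_map[r.index] = (chi, classify_glycosidic(chi))
    return GeometryReport(label=label, pairs=pairs, tetrads=tetrads,
                          topology=topo, dims=dims, pucker=pucker,
                          glycosidic=chi_map, ensemble_rmsd=rmsd)
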