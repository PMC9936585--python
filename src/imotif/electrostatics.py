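"""Electrostatic inputs to the multisite titration model.

Computes intrinsic pKa values (aqueous reference corrected for desolvation
and interaction with non-titratable charges) and the pairwise coupling
matrix g_ij between titratable cytosines, under a pluggable continuum
energy contract.

Two variants are provided:

* ``uniform-screened`` (default): screened Coulomb with a uniform effective
  dielectric equal to the solvent value; no desolvation term.  Magnitudes
  are qualitative — solvent screening is applied to buried pairs too.
* ``two-dielectric``: distance-independent approximation of a
  Poisson-Boltzmann setup with interior dielectric 6 and solvent 80 —
  charge-charge interactions screened by the interior dielectric plus a
  Born-style burial penalty on the proton charge distribution.

A full grid PB solver is deliberately out of scope; the ``EnergyModel``
contract keeps it pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_KCAL, CYTOSINE_PKA_WATER, T_DEFAULT, ln10_kt
from .structure import Structure, Residue, default_charge_set

__all__ = ["EnergyModel", "SiteDefinition", "ChargeGroup", "pair_energy",
           "intrinsic_pka", "coupling_matrix", "define_site",
           "DegenerateGeometryError", "SiteDefinitionError"]


class DegenerateGeometryError(ValueError):
    """Coincident atoms across interacting charge groups."""


class SiteDefinitionError(ValueError):
    """Invalid titratable-site definition."""


@dataclass
class EnergyModel:
    eps_in: float = 6.0
    eps_out: float = 80.0
    ionic_screening_length: float | None = None   # Debye length, Å
    coulomb_constant: float = COULOMB_KCAL
    variant: str = "uniform-screened"   # uniform-screened | two-dielectric
    temperature: float = T_DEFAULT
    born_radius: float = 2.0            # Å, for the burial penalty

    def __post_init__(self):
        if self.eps_in < 1 or self.eps_out < 1:
            raise ValueError("dielectric constants must be >= 1")
        if self.variant not in ("uniform-screened", "two-dielectric"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def eps_eff(self) -> float:
        return self.eps_out if self.variant == "uniform-screened" else self.eps_in


@dataclass
class ChargeGroup:
    """A set of point charges (coords in Å, charges in e)."""
    coords: np.ndarray
    charges: np.ndarray

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        if self.coords.shape != (len(self.charges), 3):
            raise ValueError("coords/charges shape mismatch")

    @classmethod
    def from_residues(cls, residues) -> "ChargeGroup":
        coords, charges = [], []
        for r in residues:
            for a in r.atoms:
                coords.append(a.coords)
                charges.append(a.charge)
        if not coords:
            return cls(np.zeros((0, 3)), np.zeros(0))
        return cls(np.array(coords), np.array(charges))


def _as_group(g) -> ChargeGroup:
    if isinstance(g, ChargeGroup):
        return g
    if isinstance(g, Residue):
        return ChargeGroup.from_residues([g])
    if isinstance(g, tuple) and len(g) == 2:
        return ChargeGroup(g[0], g[1])
    raise TypeError("expected ChargeGroup, Residue or (coords, charges)")


def pair_energy(group_a, group_b, model: EnergyModel | None = None) -> float:
    """Screened Coulomb interaction energy between two disjoint charge
    groups, kcal/mol; symmetric in its arguments."""
    model = model or EnergyModel()
    a, b = _as_group(group_a), _as_group(group_b)
    if len(a.charges) == 0 or len(b.charges) == 0:
        return 0.0
    d = np.linalg.norm(a.coords[:, None, :] - b.coords[None, :, :], axis=-1)
    if np.any(d < 0.5):
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise DegenerateGeometryError(
            f"atoms closer than 0.5 Å across groups (r = {d[i, j]:.3f} Å)")
    qq = np.outer(a.charges, b.charges)
    kernel = 1.0 / d
    if model.ionic_screening_length is not None:
        kernel = kernel * np.exp(-d / model.ionic_screening_length)
    return float(model.coulomb_constant / model.eps_eff * (qq * kernel).sum())


@dataclass
class SiteDefinition:
    """A titratable cytosine N3 site.

    ``delta_coords``/``delta_q`` hold the proton charge-difference
    distribution (protonated C+ minus neutral C, per atom); the sum of
    ``delta_q`` is +1 within 0.01.
    """
    res_index: int
    chain: str
    delta_coords: np.ndarray
    delta_q: np.ndarray
    pka_ref: float = CYTOSINE_PKA_WATER
    label: str = ""

    def __post_init__(self):
        self.delta_coords = np.atleast_2d(np.asarray(self.delta_coords, float))
        self.delta_q = np.atleast_1d(np.asarray(self.delta_q, float))
        total = float(self.delta_q.sum())
        if abs(total - 1.0) > 0.01:
            raise SiteDefinitionError(
                f"proton charge difference sums to {total:.4f}, expected +1")
        if not self.label:
            self.label = f"C{self.res_index}"

    @property
    def group(self) -> ChargeGroup:
        return ChargeGroup(self.delta_coords, self.delta_q)


def define_site(structure: Structure, res_index: int, chain: str | None = None,
                charge_set: dict | None = None,
                pka_ref: float = CYTOSINE_PKA_WATER) -> SiteDefinition:
    """Build the proton charge-difference distribution for a cytosine.

    If the residue lacks an explicit H3 atom, the proton charge is folded
    onto N3 (united-proton fallback).
    """
    charge_set = charge_set or default_charge_set()
    try:
        residue = structure.residue(res_index, chain)
    except KeyError:
        raise SiteDefinitionError(
            f"residue {res_index} not present in structure") from None
    if residue.base != "C":
        raise SiteDefinitionError(
            f"residue {res_index} is {residue.base}, only cytosine titrates")
    qp, qn = charge_set["DCP"], charge_set["DC"]
    coords, dq = [], []
    h3_assigned = False
    for a in residue.atoms:
        delta = qp.get(a.name, 0.0) - qn.get(a.name, 0.0)
        if a.name == "H3":
            h3_assigned = True
        if delta != 0.0:
            coords.append(a.coords)
            dq.append(delta)
    if not h3_assigned and qp.get("H3", 0.0) != 0.0:
        n3 = residue.atom("N3")
        if n3 is None:
            raise SiteDefinitionError(f"residue {res_index} lacks N3")
        coords.append(n3.coords)
        dq.append(qp["H3"])
    return SiteDefinition(res_index=residue.index, chain=residue.chain,
                          delta_coords=np.array(coords), delta_q=np.array(dq),
                          pka_ref=pka_ref)


def _background_group(structure: Structure, site: SiteDefinition,
                      all_sites, charge_set: dict) -> ChargeGroup:
    """All non-titratable charges; other titratable sites in neutral form."""
    other = {(s.chain, s.res_index) for s in all_sites} - {(site.chain, site.res_index)}
    qn = charge_set["DC"]
    coords, charges = [], []
    for r in structure.residues:
        key = (r.chain, r.index)
        if key == (site.chain, site.res_index):
            continue
        neutralize = key in other
        for a in r.atoms:
            if neutralize:
                q = qn.get(a.name, 0.0)   # H3 of a protonated form drops to 0
            else:
                q = a.charge
            if q != 0.0:
                coords.append(a.coords)
                charges.append(q)
    if not coords:
        return ChargeGroup(np.zeros((0, 3)), np.zeros(0))
    return ChargeGroup(np.array(coords), np.array(charges))


def _burial_fraction(structure: Structure, site: SiteDefinition,
                     radius: float = 6.0, saturation: int = 40) -> float:
    """Crude burial estimate: heavy-atom neighbour count around the site N3,
    scaled to [0, 1]."""
    residue = structure.residue(site.res_index, site.chain)
    n3 = residue.atom("N3")
    if n3 is None:
        return 0.0
    n = 0
    for r in structure.residues:
        if r is residue:
            continue
        for a in r.atoms:
            if a.element != "H" and np.linalg.norm(a.coords - n3.coords) < radius:
                n += 1
    return min(1.0, n / saturation)


def desolvation_penalty(site: SiteDefinition, structure: Structure,
                        model: EnergyModel) -> float:
    """Born-style burial penalty (kcal/mol); zero for the uniform variant."""
    if model.variant == "uniform-screened":
        return 0.0
    f = _burial_fraction(structure, site)
    born = (model.coulomb_constant / 2.0) * float((site.delta_q ** 2).sum()) \
        / model.born_radius * (1.0 / model.eps_in - 1.0 / model.eps_out)
    return f * born


def intrinsic_pka(site: SiteDefinition, structure: Structure,
                  model: EnergyModel | None = None, all_sites=None,
                  charge_set: dict | None = None) -> float:
    """Intrinsic pKa: aqueous reference shifted by desolvation + background
    interaction, pK_int = pKa_ref − ΔΔG/(ln10·kT)."""
    model = model or EnergyModel()
    charge_set = charge_set or default_charge_set()
    all_sites = all_sites if all_sites is not None else [site]
    background = _background_group(structure, site, all_sites, charge_set)
    ddg = pair_energy(site.group, background, model)
    ddg += desolvation_penalty(site, structure, model)
    return site.pka_ref - ddg / ln10_kt(model.temperature)


def _residue_forms(structure: Structure, site: SiteDefinition,
                   charge_set: dict):
    """(protonated, neutral) charge groups for a site's residue, on the
    residue's coordinates (H3 folded onto N3 when absent)."""
    residue = structure.residue(site.res_index, site.chain)
    qp, qn = charge_set["DCP"], charge_set["DC"]
    coords, cp, cn = [], [], []
    names = {a.name for a in residue.atoms}
    for a in residue.atoms:
        coords.append(a.coords)
        qpp = qp.get(a.name, 0.0)
        if a.name == "N3" and "H3" not in names:
            qpp += qp.get("H3", 0.0)
        cp.append(qpp)
        cn.append(qn.get(a.name, 0.0))
    coords = np.array(coords)
    return ChargeGroup(coords, np.array(cp)), ChargeGroup(coords, np.array(cn))


def coupling_matrix(sites, structure: Structure,
                    model: EnergyModel | None = None,
                    charge_set: dict | None = None) -> np.ndarray:
    """Symmetric coupling matrix g_ij (kcal/mol), zero diagonal.

    g_ij is the double difference over the four protonation combinations of
    the pair, E(C_iH+:C_jH+) − E(C_iH+:C_j) − E(C_i:C_jH+) + E(C_i:C_j),
    each term evaluated with :func:`pair_energy`.
    """
    model = model or EnergyModel()
    charge_set = charge_set or default_charge_set()
    n = len(sites)
    if n < 2:
        raise SiteDefinitionError("need at least two sites")
    keys = [(s.chain, s.res_index) for s in sites]
    if len(set(keys)) != n:
        raise SiteDefinitionError("overlapping site definitions")
    forms = [_residue_forms(structure, s, charge_set) for s in sites]
    g = np.zeros((n, n))
    for i in range(n):
        pi, ni = forms[i]
        for j in range(i + 1, n):
            pj, nj = forms[j]
            val = (pair_energy(pi, pj, model) - pair_energy(pi, nj, model)
                   - pair_energy(ni, pj, model) + pair_energy(ni, nj, model))
            g[i, j] = g[j, i] = val
    return g
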