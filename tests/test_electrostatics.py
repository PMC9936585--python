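import numpy as np
import pytest

from imotif.constants import COULOMB_KCAL, ln10_kt
from imotif.electrostatics import (EnergyModel, ChargeGroup, SiteDefinition,
                                   pair_energy, intrinsic_pka, coupling_matrix,
                                   define_site, desolvation_penalty,
                                   DegenerateGeometryError,
                                   SiteDefinitionError)
from imotif.structure import Atom, Residue, Structure, assign_charges
from imotif.titration import TitrationModel
from imotif.synth import BuildSpec, build_imotif


def point(q, x, y=0.0, z=0.0):
    return ChargeGroup(np.array([[x, y, z]]), np.array([q]))


class TestPairEnergy:
    def test_two_unit_charges_at_3_32A_eps80(self):
        e = pair_energy(point(1, 0), point(1, 3.32),
                        EnergyModel(variant="uniform-screened"))
        assert e == pytest.approx(332.0636 / (80 * 3.32), abs=1e-6)
        assert e == pytest.approx(1.250, abs=1e-3)

    def test_zero_charge_group_gives_zero(self):
        assert pair_energy(point(0.0, 0), point(1.0, 5)) == 0.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a = ChargeGroup(rng.normal(size=(4, 3)), rng.normal(size=4))
        b = ChargeGroup(rng.normal(size=(5, 3)) + 8.0, rng.normal(size=5))
        assert pair_energy(a, b) == pytest.approx(pair_energy(b, a), rel=1e-12)

    def test_doubling_dielectric_halves_energy(self):
        e80 = pair_energy(point(1, 0), point(1, 4), EnergyModel(eps_out=80))
        e160 = pair_energy(point(1, 0), point(1, 4), EnergyModel(eps_out=160))
        assert e80 == pytest.approx(2 * e160, rel=1e-12)

    def test_coincident_atoms_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            pair_energy(point(1, 0), point(1, 0.3))

    def test_debye_screening_damps(self):
        unscreened = pair_energy(point(1, 0), point(1, 5), EnergyModel())
        screened = pair_energy(point(1, 0), point(1, 5),
                               EnergyModel(ionic_screening_length=5.0))
        assert screened == pytest.approx(unscreened * np.exp(-1.0), rel=1e-9)


def _isolated_site(res_index=1):
    """A site whose proton difference is one +1 point charge at the origin."""
    return SiteDefinition(res_index=res_index, chain="A",
                          delta_coords=np.array([[0.0, 0.0, 0.0]]),
                          delta_q=np.array([1.0]))


def _charged_residue(index, q, x):
    atom = Atom("N1", "N", np.array([x, 0.0, 0.0]), charge=q)
    return Residue(index, "C", "A", [atom])


class TestIntrinsicPKa:
    def test_no_shift_reproduces_aqueous_reference(self):
        structure = Structure([_charged_residue(1, 0.0, 0.0)])
        assert intrinsic_pka(_isolated_site(), structure) \
            == pytest.approx(4.4, abs=1e-12)

    @pytest.mark.parametrize("q,n_units,expected", [(1.0, 1, 3.4),
                                                    (-1.0, -2, 6.4)])
    def test_shift_is_one_ph_unit_per_2p303_kT(self, q, n_units, expected):
        # place a background charge so ΔΔG equals n·ln10·kT exactly
        r = abs(q) * COULOMB_KCAL / (80.0 * abs(n_units) * ln10_kt())
        structure = Structure([_charged_residue(1, 0.0, 0.0),
                               _charged_residue(2, q, r)])
        got = intrinsic_pka(_isolated_site(), structure,
                            EnergyModel(variant="uniform-screened"))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_affine_in_ddg(self):
        # pK_int = 4.4 − ΔΔG/(ln10 kT): check slope on a grid of distances
        shifts, energies = [], []
        for r in (2.0, 4.0, 8.0, 16.0):
            structure = Structure([_charged_residue(1, 0.0, 0.0),
                                   _charged_residue(2, 1.0, r)])
            pk = intrinsic_pka(_isolated_site(), structure)
            shifts.append(4.4 - pk)
            energies.append(COULOMB_KCAL / (80.0 * r))
        np.testing.assert_allclose(np.array(shifts) * ln10_kt(),
                                   energies, rtol=1e-9)

    def test_missing_site_residue(self, neutral_fragment, charge_set):
        with pytest.raises(SiteDefinitionError):
            define_site(neutral_fragment, 99, charge_set=charge_set)

    def test_site_delta_q_sums_to_one(self, charged_neutral, charge_set):
        for idx in (2, 7, 15, 20):
            site = define_site(charged_neutral, idx, charge_set=charge_set)
            assert site.delta_q.sum() == pytest.approx(1.0, abs=0.01)

    def test_desolvation_zero_in_uniform_variant(self, charged_neutral,
                                                 charge_set):
        site = define_site(charged_neutral, 2, charge_set=charge_set)
        assert desolvation_penalty(site, charged_neutral, EnergyModel()) == 0.0
        two = EnergyModel(variant="two-dielectric")
        assert desolvation_penalty(site, charged_neutral, two) > 0.0


class TestCouplingMatrix:
    def test_point_charge_pair_reduces_to_coulomb(self):
        # two sites whose proton differences are +1 charges 3.32 Å apart and
        # whose neutral forms are uncharged
        r1 = _charged_residue(1, 0.0, 0.0)
        r2 = _charged_residue(2, 0.0, 3.32)
        structure = Structure([r1, r2])
        charge_set = {"DCP": {"N1": 1.0}, "DC": {"N1": 0.0}}
        sites = [define_site(structure, 1, charge_set=charge_set),
                 define_site(structure, 2, charge_set=charge_set)]
        g = coupling_matrix(sites, structure, EnergyModel(), charge_set)
        assert g[0, 1] == pytest.approx(1.250, abs=1e-3)
        assert g[0, 0] == 0.0 and g[1, 1] == 0.0

    def test_distant_sites_decouple(self):
        r1 = _charged_residue(1, 0.0, 0.0)
        r2 = _charged_residue(2, 0.0, 1e7)
        structure = Structure([r1, r2])
        charge_set = {"DCP": {"N1": 1.0}, "DC": {"N1": 0.0}}
        sites = [define_site(structure, i, charge_set=charge_set)
                 for i in (1, 2)]
        g = coupling_matrix(sites, structure, EnergyModel(), charge_set)
        assert abs(g[0, 1]) < 1e-6

    def test_symmetric_on_synthetic_stack(self, charged_neutral, charge_set):
        sites = [define_site(charged_neutral, i, charge_set=charge_set)
                 for i in (2, 7, 15, 20)]
        g = coupling_matrix(sites, charged_neutral, EnergyModel(), charge_set)
        np.testing.assert_allclose(g, g.T, atol=1e-12)
        assert np.all(np.diag(g) == 0)

    def test_overlapping_sites_rejected(self, charged_neutral, charge_set):
        sites = [define_site(charged_neutral, 2, charge_set=charge_set)] * 2
        with pytest.raises(SiteDefinitionError):
            coupling_matrix(sites, charged_neutral)


class TestTetradStabilization:
    def test_capping_tetrads_raise_macroscopic_pka(self, charge_set):
        """Adding minor-groove tetrads to the C:C+ stack must shift the
        level-1.5 macroscopic pKa upward (the direction of the titration
        comparison between the bare stack and the capped one)."""
        pkas = {}
        for cap in ("none", "GCGC"):
            s = assign_charges(build_imotif(BuildSpec(n_cc_pairs=2,
                                                      capping=cap)),
                               charge_set)
            res = TitrationModel.from_structure(s).solve()
            pkas[cap] = res.curve.pka_at_level(1.5)
        assert pkas["GCGC"] > pkas["none"]
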