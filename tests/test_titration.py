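import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imotif.constants import kt, ln10_kt, COULOMB_KCAL
from imotif.electrostatics import EnergyModel, SiteDefinition
from imotif.structure import Atom, Residue, Structure
from imotif.titration import (TitrationSystem, ProtonationState,
                              microstate_free_energy, site_curves,
                              macroscopic_pkas, TitrationModel, knockout_scan,
                              StateError, RangeError, default_ph_grid)


def system(pk, g=None, labels=None):
    pk = np.atleast_1d(pk)
    labels = labels or [f"s{i}" for i in range(len(pk))]
    g = np.zeros((len(pk), len(pk))) if g is None else np.asarray(g)
    return TitrationSystem(labels, pk, g)


def mc_mean_protonation(sys_, ph, n_sweeps=100_000, seed=0, burn=5_000):
    """Independent Metropolis oracle over protonation microstates.

    Returns (mean x_i, standard error per site from 10 block means).
    """
    rng = np.random.default_rng(seed)
    n = sys_.n_sites
    beta = 1.0 / kt(sys_.temperature)
    lkt = ln10_kt(sys_.temperature)
    x = np.zeros(n)
    flips = rng.integers(0, n, size=n_sweeps * n)
    us = rng.random(n_sweeps * n)
    samples = np.zeros((n_sweeps, n))
    t = 0
    for sweep in range(n_sweeps):
        for _ in range(n):
            i = flips[t]
            dE = lkt * (ph - sys_.pk_int[i]) + float(sys_.g[i] @ x)
            if x[i] == 1:
                dE = -dE
            if dE <= 0 or us[t] < np.exp(-beta * dE):
                x[i] = 1 - x[i]
            t += 1
        samples[sweep] = x
    samples = samples[burn:]
    blocks = np.array_split(samples, 10)
    block_means = np.array([b.mean(axis=0) for b in blocks])
    return samples.mean(axis=0), block_means.std(axis=0, ddof=1) / np.sqrt(10)


class TestMicrostateFreeEnergy:
    def test_all_zero_state_is_zero(self):
        s = system([4.4, 5.0, 6.0])
        assert microstate_free_energy(ProtonationState([0, 0, 0]), 7.3, s) == 0

    def test_single_site_at_its_pk(self):
        s = system([4.4])
        assert microstate_free_energy([1], 4.4, s) == pytest.approx(0.0)

    def test_only_coupling_survives_at_pk(self):
        g = np.array([[0.0, 1.0], [1.0, 0.0]])
        s = system([4.4, 4.4], g)
        assert microstate_free_energy([1, 1], 4.4, s) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(StateError):
            microstate_free_energy([1, 0], 7.0, system([4.4]))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 5 - 1))
    def test_matches_direct_formula(self, bits):
        rng = np.random.default_rng(11)
        pk = rng.uniform(2, 10, 5)
        g = rng.normal(0, 1, (5, 5))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        s = system(pk, g)
        x = np.array([(bits >> i) & 1 for i in range(5)], dtype=float)
        ph = 6.2
        expected = (x * ln10_kt() * (ph - pk)).sum() \
            + sum(g[i, j] * x[i] * x[j] for i in range(5) for j in range(i + 1, 5))
        assert microstate_free_energy(x.astype(int), ph, s) \
            == pytest.approx(expected, rel=1e-12)


class TestSiteCurves:
    def test_single_site_henderson_hasselbalch_points(self):
        curve = site_curves(system([4.4]))
        i44 = np.argmin(np.abs(curve.ph_grid - 4.4))
        i54 = np.argmin(np.abs(curve.ph_grid - 5.4))
        assert curve.site_curves[0, i44] == pytest.approx(0.5, abs=1e-12)
        assert curve.site_curves[0, i54] == pytest.approx(1 / 11, abs=1e-12)

    def test_two_uncoupled_sites_total(self):
        curve = site_curves(system([4.4, 4.4]))
        expected = 2.0 / (1.0 + 10 ** (curve.ph_grid - 4.4))
        np.testing.assert_allclose(curve.total_curve, expected, atol=1e-12)

    def test_uncoupled_curves_match_closed_form_everywhere(self):
        rng = np.random.default_rng(3)
        pk = rng.uniform(3, 11, 6)
        curve = site_curves(system(pk))
        hh = 1.0 / (1.0 + 10 ** (curve.ph_grid[None, :] - pk[:, None]))
        np.testing.assert_allclose(curve.site_curves, hh, atol=1e-10)

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(4)
        g = np.abs(rng.normal(0, 1.5, (5, 5)))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        curve = site_curves(system(rng.uniform(2, 12, 5), g))
        assert np.all(curve.site_curves >= 0) and np.all(curve.site_curves <= 1)
        assert np.all(np.diff(curve.total_curve) <= 1e-12)

    def test_enumeration_limit(self):
        with pytest.raises(StateError, match="sampling fallback"):
            site_curves(system(np.full(21, 4.4)))

    def test_matches_mc_oracle_random_system(self):
        rng = np.random.default_rng(42)
        n = 4
        pk = rng.uniform(3.5, 8.5, n)
        g = np.abs(rng.normal(0, 0.8, (n, n)))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        sys_ = system(pk, g)
        curve = site_curves(sys_, default_ph_grid(3, 9, 0.5))
        for ph, seed in [(4.0, 1), (5.5, 2), (7.0, 3)]:
            exact = curve.site_curves[:, np.argmin(np.abs(curve.ph_grid - ph))]
            mc, se = mc_mean_protonation(sys_, ph, n_sweeps=100_000, seed=seed)
            np.testing.assert_array_less(np.abs(mc - exact),
                                         3 * np.maximum(se, 1e-4))


class TestMacroscopicPKas:
    def test_single_site(self):
        assert macroscopic_pkas(site_curves(system([4.4]))) \
            == pytest.approx([4.4], abs=1e-3)

    def test_two_uncoupled_identical_sites(self):
        # closed form: crossings at 4.4 ± log10(3)
        got = macroscopic_pkas(site_curves(system([4.4, 4.4])))
        assert got == pytest.approx([4.4 - np.log10(3), 4.4 + np.log10(3)],
                                    abs=1e-3)

    def test_strong_coupling_separates_crossings(self):
        g_val = 5.0
        g = np.array([[0, g_val], [g_val, 0.0]])
        got = macroscopic_pkas(site_curves(system([6.0, 6.0], g)))
        separation = got[1] - got[0]
        assert separation >= g_val / ln10_kt() - np.log10(9) - 1e-3

    def test_unbracketed_level_raises(self):
        curve = site_curves(system([4.4]), default_ph_grid(6, 10, 0.1))
        with pytest.raises(RangeError, match="0.5"):
            macroscopic_pkas(curve, levels=[0.5])


class TestModelResults:
    def test_summary_and_frame(self, charged_neutral):
        res = TitrationModel.from_structure(charged_neutral).solve()
        text = res.summary()
        assert "macroscopic pKa" in text and "C2" in text
        frame = res.to_frame()
        assert {"pH", "total"} <= set(frame.columns)
        assert res.pka(1.5) == pytest.approx(
            res.curve.pka_at_level(1.5))

    def test_default_sites_are_persistent_pair_cytosines(self, charged_neutral):
        model = TitrationModel.from_structure(charged_neutral)
        assert model.system.sites == ["C2", "C7", "C15", "C20"]


class TestKnockout:
    def test_zero_charge_residue_has_no_effect(self):
        # a site plus an uncharged spectator residue
        charge_set = {"DCP": {"N1": 1.0}, "DC": {"N1": 0.0}}
        r1 = Residue(1, "C", "A", [Atom("N1", "N", np.zeros(3))])
        r2 = Residue(2, "C", "A", [Atom("N1", "N", np.array([4.0, 0, 0]))])
        r3 = Residue(3, "C", "A", [Atom("N1", "N", np.array([0, 6.0, 0]))])
        structure = Structure([r1, r2, r3])
        table = knockout_scan(structure, site_indices=(1, 2),
                              charge_set=charge_set, exclude_residues=(),
                              ph_grid=default_ph_grid(0, 9, 0.05))
        assert len(table) == 1
        dpk = table.filter(like="dpKa_").to_numpy()
        np.testing.assert_allclose(dpk, 0.0, atol=1e-9)

    def test_removing_point_charge_shifts_pk_int(self):
        # +1 charge 4 Å from the proton, uniform ε=80:
        # ΔpKa = +332.0636/(80·4)/1.364 = +0.761 on removal
        charge_set = {"DCP": {"N1": 1.0}, "DC": {"N1": 0.0}}
        r1 = Residue(1, "C", "A", [Atom("N1", "N", np.zeros(3))])
        bg = Residue(2, "T", "A",
                     [Atom("N1", "N", np.array([4.0, 0, 0]), charge=1.0)])
        structure = Structure([r1, bg])
        table = knockout_scan(structure, site_indices=(1,),
                              mode="remove-residue", charge_set=charge_set,
                              exclude_residues=(),
                              ph_grid=default_ph_grid(0, 9, 0.05))
        expected = COULOMB_KCAL / (80 * 4) / ln10_kt()
        assert table.loc[0, "dpKa_0.5"] == pytest.approx(expected, abs=2e-3)

    def test_zero_all_charges_equals_remove(self, charged_neutral, charge_set):
        grids = default_ph_grid(-6, 16, 0.1)
        tables = {}
        for mode in ("zero-all-charges", "remove-residue"):
            tables[mode] = knockout_scan(
                charged_neutral, (2, 7, 15, 20), mode=mode,
                charge_set=charge_set, ph_grid=grids)
        a = tables["zero-all-charges"].filter(like="dpKa_").to_numpy()
        b = tables["remove-residue"].filter(like="dpKa_").to_numpy()
        np.testing.assert_allclose(a, b, atol=2e-3)

    def test_unknown_mode_rejected(self, charged_neutral):
        with pytest.raises(ValueError, match="mode"):
            knockout_scan(charged_neutral, mode="banish")
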