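import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from imotif.structure import Ensemble
from imotif.synth import BuildSpec, build_imotif, build_gc_pair, build_gt_pair, \
    perturb
from imotif.geometry import (detect_hbonds, classify_pairs_and_tetrads,
                             pseudorotation, generate_ring_torsions,
                             classify_pucker, classify_glycosidic, dimensions,
                             ensemble_rmsd, intercalation_topology, describe,
                             DegeneratePuckerError)
from imotif.structure import Atom, Residue, Structure


def _rigid_copy(structure, seed=0):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng)
    shift = rng.normal(0, 20, 3)
    out = structure.copy()
    out.set_coords(rot.apply(out.coords()) + shift)
    return out


class TestHBonds:
    def test_cc_pair_three_bonds(self, cc_pair):
        assert len(detect_hbonds(cc_pair)) == 3

    def test_distant_bases_no_bonds(self):
        from imotif.synth import build_cc_pair
        pair = build_cc_pair(True)
        shifted = pair.copy()
        xyz = shifted.coords()
        n0 = len(shifted.residues[0].atoms)
        xyz[n0:] += np.array([10.0, 0, 0])
        shifted.set_coords(xyz)
        assert detect_hbonds(shifted) == []

    def test_slipped_tetrad_has_both_interguanine_bonds(self, acidic_fragment):
        gg = [hb for hb in detect_hbonds(acidic_fragment)
              if hb.donor_res.base == "G" and hb.acceptor_res.base == "G"
              and hb.donor_atom == "N2" and hb.acceptor_atom == "N3"]
        # two tetrads, two reciprocal bonds each
        assert len(gg) == 4


class TestClassification:
    CASES = [
        (BuildSpec(n_cc_pairs=4, capping="GTGT", topology="3E"),
         4, ["G:T:G:T", "G:T:G:T"], "3E"),
        (BuildSpec(n_cc_pairs=4, capping="GTGT", topology="5E"),
         4, ["G:T:G:T", "G:T:G:T"], "5E"),
        (BuildSpec(n_cc_pairs=2, capping="GCGC", topology="3E"),
         2, ["G:C:G:C", "G:C:G:C"], "3E"),
        (BuildSpec(n_cc_pairs=2, capping="GCGC", topology="5E"),
         2, ["G:C:G:C", "G:C:G:C"], "5E"),
        # with G:T:G:T capping and only two pairs, the tract-neighbour
        # cytosines are absent, so the 3'E/5'E annotation is indeterminate
        (BuildSpec(n_cc_pairs=2, capping="GTGT", topology="3E"),
         2, ["G:T:G:T", "G:T:G:T"], "none"),
    ]

    @pytest.mark.parametrize("spec,n_cc,tetrads,topo", CASES)
    def test_builder_ground_truth_recovered(self, spec, n_cc, tetrads, topo):
        s = build_imotif(spec)
        pairs, tets = classify_pairs_and_tetrads(s)
        cc = [p for p in pairs if p.pair_class == "CC+"]
        assert len(cc) == n_cc
        assert sorted(t.tetrad_class for t in tets) == sorted(tetrads)
        assert all(t.slipped for t in tets)
        assert intercalation_topology(s, pairs) == topo

    def test_single_cytosine_unpaired(self):
        from imotif.synth import build_cc_pair
        single = Structure([build_cc_pair(True).residues[0]])
        pairs, tets = classify_pairs_and_tetrads(single)
        assert pairs == [] and tets == []

    def test_single_pair_topology_none(self, cc_pair):
        pairs, _ = classify_pairs_and_tetrads(cc_pair)
        assert intercalation_topology(cc_pair, pairs) == "none"

    def test_wc_and_wobble_pairs(self):
        pairs, _ = classify_pairs_and_tetrads(build_gc_pair())
        assert pairs[0].pair_class == "WC-GC"
        pairs, _ = classify_pairs_and_tetrads(build_gt_pair())
        assert pairs[0].pair_class == "wobble-GT"


class TestPseudorotation:
    @pytest.mark.parametrize("p", list(range(0, 360, 36)))
    @pytest.mark.parametrize("tau", [30.0, 40.0])
    def test_inverts_generating_cosine_series(self, p, tau):
        got_p, got_tau = pseudorotation(generate_ring_torsions(p, tau))
        assert got_p == pytest.approx(p % 360.0, abs=1e-9)
        assert got_tau == pytest.approx(tau, abs=1e-9)

    def test_c2_endo_south(self):
        p, _ = pseudorotation(generate_ring_torsions(162.0, 38.0))
        assert p == pytest.approx(162.0, abs=1.0)
        assert classify_pucker(p) == "south"

    def test_north_at_zero(self):
        p, _ = pseudorotation(generate_ring_torsions(0.0, 35.0))
        assert p == pytest.approx(0.0, abs=1e-9)
        assert classify_pucker(p) == "north"

    def test_constraint_interval_midrange(self):
        # mid-range of the experimental restraint intervals
        p, _ = pseudorotation([-21.5, 34.8, -34.8, 21.5, 0.0])
        assert 144.0 < p < 180.0

    def test_flat_ring_degenerate(self):
        with pytest.raises(DegeneratePuckerError):
            pseudorotation([0.0, 0.0, 0.0, 0.0, 0.0])


class TestGlycosidic:
    @pytest.mark.parametrize("chi,cls", [(-100.0, "anti"), (-30.0, "high-anti"),
                                         (45.0, "syn"), (150.0, "other"),
                                         (-60.0, "anti"), (0.0, "high-anti")])
    def test_windows(self, chi, cls):
        assert classify_glycosidic(chi) == cls

    def test_domain_check(self):
        with pytest.raises(ValueError):
            classify_glycosidic(-180.0)


def _point_structure(points):
    residues = [Residue(i + 1, "C", "A",
                        [Atom("C2", "C", np.asarray(p, float))])
                for i, p in enumerate(points)]
    return Structure(residues)


class TestDimensions:
    def test_unit_cube(self):
        corners = list(itertools.product([0, 1], repeat=3))
        assert dimensions(_point_structure(corners)) \
            == pytest.approx((1.0, 1.0, 1.0))

    def test_line_segment(self):
        pts = [(t, 0, 0) for t in np.linspace(0, 20, 9)]
        dims = dimensions(_point_structure(pts))
        assert dims[0] == pytest.approx(20.0)
        assert dims[1] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, acidic_fragment):
        ref = dimensions(acidic_fragment)
        moved = dimensions(_rigid_copy(acidic_fragment, seed=3))
        assert moved == pytest.approx(ref, abs=1e-6)

    def test_acidic_more_elongated_than_neutral(self, acidic_fragment,
                                                neutral_fragment):
        la = dimensions(acidic_fragment)[0]
        ln = dimensions(neutral_fragment)[0]
        assert la - ln > 2.0


class TestEnsembleRMSD:
    def test_duplicate_model_zero(self, acidic_fragment):
        ens = Ensemble([acidic_fragment.copy(), acidic_fragment.copy()])
        assert ensemble_rmsd(ens) == pytest.approx(0.0, abs=1e-9)

    def test_superposition_invariance(self, acidic_fragment):
        ens = Ensemble([acidic_fragment.copy(), _rigid_copy(acidic_fragment)])
        assert ensemble_rmsd(ens) == pytest.approx(0.0, abs=1e-6)

    def test_jitter_scaling(self, acidic_fragment):
        sigma = 0.3
        ens = Ensemble([perturb(acidic_fragment, sigma, seed=s)
                        for s in range(6)])
        expected = np.sqrt(2) * sigma * np.sqrt(3)
        assert ensemble_rmsd(ens) == pytest.approx(expected, rel=0.25)

    def test_exclusion_empties_selection(self, cc_pair):
        from imotif.geometry import EmptySelectionError
        ens = Ensemble([cc_pair.copy(), cc_pair.copy()])
        with pytest.raises(EmptySelectionError):
            ensemble_rmsd(ens, exclude_residues=(1, 2))


class TestDescribe:
    def test_full_report_on_ensemble(self, neutral_fragment):
        ens = Ensemble([perturb(neutral_fragment, 0.05, seed=s)
                        for s in range(3)], label="synthetic")
        report = describe(ens)
        d = report.as_dict()
        assert d["topology"] == "3E"
        assert len(d["tetrads"]) == 2
        assert d["ensemble_rmsd"] is not None and d["ensemble_rmsd"] < 0.5
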