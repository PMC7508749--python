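"""Sugar-backbone geometry: dihedrals, pucker, BI/BII, filters, superposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wobblefit.idealized import (BI_JUNCTION, BII_JUNCTION, C2_ENDO, C3_ENDO,
                                 NucleotideParams, SugarPucker, idealized_duplex,
                                 idealized_triplet, write_pdb)
from wobblefit.survey import (BasePairRecord, c1c1_distance, classify_backbone,
                              dihedral, find_flanked_mismatches,
                              load_nucleotides, nu_from_pseudorotation,
                              pseudorotation, residue_torsions, superpose,
                              survey_structure)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == pytest.approx(0.0)

    def test_planar_anti_is_180(self):
        val = dihedral([-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0])
        assert abs(val) == pytest.approx(180.0)

    def test_perpendicular_sign_convention(self):
        # +90 when p4 rotates clockwise from p1 looking down p2->p3
        val = dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1])
        assert abs(val) == pytest.approx(90.0)
        # brute-force check: rotating p4 by +10 deg about the p2->p3 axis
        # (right-handed) must increase the torsion by 10 deg
        ang = np.radians(10.0)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(ang), -np.sin(ang)],
                        [0, np.sin(ang), np.cos(ang)]])
        val2 = dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], rot @ np.array([1, 0, 1.0]))
        assert (val2 - val) % 360.0 == pytest.approx(10.0, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_reversal_invariance_and_mirror_antisymmetry(self, seed):
        # chain reversal preserves a torsion angle (phi(ABCD) = phi(DCBA));
        # mirror reflection flips its sign
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3))
        fwd = dihedral(*pts)
        assert dihedral(*pts[::-1]) == pytest.approx(fwd, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert (dihedral(*mirrored) == pytest.approx(-fwd, abs=1e-9)
                or abs(abs(fwd) - 180.0) < 1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestPseudorotation:
    @pytest.mark.parametrize("p,numax", [(162.0, 35.0), (18.0, 38.0),
                                         (250.0, 30.0), (0.0, 40.0)])
    def test_round_trip(self, p, numax):
        nu = nu_from_pseudorotation(p, numax)
        p2, n2 = pseudorotation(nu)
        assert p2 == pytest.approx(p, abs=1e-9)
        assert n2 == pytest.approx(numax, abs=1e-9)

    def test_planar_ring_rejected(self):
        with pytest.raises(ValueError):
            pseudorotation(np.zeros(5))

    def test_stable_under_jitter(self, rng):
        nu = nu_from_pseudorotation(162.0, 35.0)
        for _ in range(20):
            p2, _ = pseudorotation(nu + rng.normal(0, 0.5, 5))
            assert abs(p2 - 162.0) < 3.0


class TestBackboneClass:
    def test_inside_window_is_bii(self):
        label, diff = classify_backbone(190.0, 100.0)
        assert (label, diff) == ("BII", pytest.approx(90.0))

    def test_outside_window_is_bi(self):
        label, diff = classify_backbone(170.0, 260.0)
        assert (label, diff) == ("BI", pytest.approx(270.0))

    def test_boundary_inclusive_with_wraparound(self):
        # -170 wraps to 190; 190 - 170 = 20, on the closed boundary -> BII
        label, diff = classify_backbone(-170.0, 170.0)
        assert (label, diff) == ("BII", pytest.approx(20.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(eps=st.floats(-720, 720), zeta=st.floats(-720, 720),
           k1=st.integers(-2, 2), k2=st.integers(-2, 2))
    def test_wrapping_invariance(self, eps, zeta, k1, k2):
        a = classify_backbone(eps, zeta)
        b = classify_backbone(eps + 360.0 * k1, zeta + 360.0 * k2)
        assert a[0] == b[0]
        # circular comparison: rounding can land the difference on either
        # side of the 0/360 seam
        circ = (a[1] - b[1] + 180.0) % 360.0 - 180.0
        assert abs(circ) < 1e-6


class TestSuperpose:
    def test_identical_sets_zero_rmsd(self, rng):
        pts = rng.normal(size=(6, 3))
        _, _, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_recovered(self, rng):
        pts = rng.normal(size=(8, 3))
        ang = np.radians(40.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        moved = pts @ R.T + np.array([1.0, -2.0, 3.0])
        Rhat, that, rmsd = superpose(moved, pts)
        assert rmsd < 1e-8
        assert np.allclose(moved @ Rhat.T + that, pts, atol=1e-8)

    def test_known_residual_two_points_displaced(self):
        # fixed points and a copy with one pair pulled apart symmetrically
        fixed = np.array([[0, 0, 0], [2, 0, 0], [1, 1, 0.0]])
        moving = fixed.copy()
        moving[2, 1] += 0.4
        _, _, rmsd = superpose(moving, fixed)
        # optimal alignment spreads the 0.4 A displacement over the set;
        # brute-force grid search oracle gives the same minimum
        assert 0.0 < rmsd < 0.4
        best = np.inf
        for dx in np.linspace(-0.3, 0.3, 61):
            for dy in np.linspace(-0.3, 0.3, 61):
                for ang in np.radians(np.linspace(-20, 20, 81)):
                    R = np.array([[np.cos(ang), -np.sin(ang), 0],
                                  [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
                    trial = moving @ R.T + [dx, dy, 0]
                    best = min(best, np.sqrt(np.mean(np.sum((trial - fixed) ** 2, 1))))
        assert rmsd == pytest.approx(best, abs=1e-3)

    def test_collinear_warns(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.warns(UserWarning, match="degenerate"):
            superpose(line, line)


class TestFlankedMismatches:
    @staticmethod
    def duplex(classes, duplex_id="d1"):
        out = []
        for i, cls in enumerate(classes):
            b1, b2 = ("G", "T") if cls == "wobble" else ("G", "C")
            out.append(BasePairRecord("A", i + 1, "B", len(classes) - i,
                                      cls, base1=b1, base2=b2,
                                      duplex_id=duplex_id))
        return out

    def test_centered_mismatch_found(self):
        hits = find_flanked_mismatches(self.duplex(["WC", "WC", "wobble", "WC", "WC"]))
        assert len(hits) == 1
        assert hits[0].resnum1 == 3

    def test_single_flank_rejected(self):
        hits = find_flanked_mismatches(self.duplex(["WC", "wobble", "WC", "WC"]))
        assert hits == []

    def test_two_independent_mismatches(self):
        classes = ["WC", "WC", "wobble", "WC", "WC", "wobble", "WC", "WC"]
        hits = find_flanked_mismatches(self.duplex(classes))
        assert [h.resnum1 for h in hits] == [3, 6]

    def test_non_gt_wobble_excluded(self):
        pairs = self.duplex(["WC", "WC", "wobble", "WC", "WC"])
        pairs[2].base1, pairs[2].base2 = "G", "U"
        assert find_flanked_mismatches(pairs) == []


class TestIdealizedFixture:
    def test_construction_parameters_reproduced(self):
        """The survey measures back exactly the torsions the synthetic
        duplex was built with: BI/BII labels exact, pucker phase to ~0.2 deg."""
        params = []
        for k, (eps, zeta) in enumerate([BI_JUNCTION, BII_JUNCTION, BI_JUNCTION,
                                         BII_JUNCTION, BI_JUNCTION]):
            phase, amp, delta = C2_ENDO if k % 2 == 0 else C3_ENDO
            params.append(NucleotideParams(
                base="DG", pucker=SugarPucker(phase, amp, delta),
                epsilon=eps, zeta=zeta))
        residues = idealized_duplex(["DG"] * 5, params1=params)
        expected_class = ["BII" if (e, z) == BII_JUNCTION else "BI"
                          for e, z in [BI_JUNCTION, BII_JUNCTION, BI_JUNCTION,
                                       BII_JUNCTION]]
        for i in range(4):
            g = residue_torsions(residues[("A", i + 1)])
            assert g.backbone_class == expected_class[i]
            target_phase = (C2_ENDO if i % 2 == 0 else C3_ENDO)[0]
            assert g.pucker_phase == pytest.approx(target_phase, abs=0.2)

    def test_triplet_pucker_in_c2_endo_range(self):
        residues = idealized_triplet()
        g = residue_torsions(residues[("A", 2)])
        assert 140.0 < g.pucker_phase < 185.0   # C2'-endo family

    def test_terminal_residue_lacks_eps_zeta(self):
        residues = idealized_triplet()
        g = residue_torsions(residues[("A", 3)])
        assert np.isnan(g.epsilon) and np.isnan(g.zeta)

    def test_central_pair_c1c1_distance(self):
        residues = idealized_triplet()
        bp = BasePairRecord("A", 2, "B", 2, "WC")
        assert c1c1_distance(bp, residues) == pytest.approx(10.5, abs=1e-6)

    def test_atom_alias_invariance(self):
        residues = idealized_triplet()
        nt = residues[("A", 1)]
        renamed = {k.replace("'", "*"): v for k, v in nt.atoms.items()}
        from wobblefit.survey import NucleotideCoords
        alias_nt = NucleotideCoords(chain=nt.chain, resnum=nt.resnum,
                                    base=nt.base, atoms=renamed,
                                    next_atoms=dict(nt.next_atoms))
        a = residue_torsions(nt)
        b = residue_torsions(alias_nt)
        assert b.pucker_phase == pytest.approx(a.pucker_phase, abs=1e-9)
        assert b.gamma == pytest.approx(a.gamma, abs=1e-9)


class TestFileRoundTrip:
    def test_pdb_survey_round_trip(self, tmp_path):
        residues = idealized_triplet()
        path = tmp_path / "triplet.pdb"
        write_pdb(residues, path)
        df = survey_structure(str(path))
        assert len(df) == 6
        interior = df[df["backbone_class"] != ""]
        assert set(interior["backbone_class"]) == {"BI"}
        assert np.allclose(df["pucker_phase"], 162.0, atol=0.5)

    def test_multi_model_access(self, tmp_path):
        residues = idealized_triplet()
        path = tmp_path / "triplet.pdb"
        write_pdb(residues, path)
        by_model = load_nucleotides(str(path), all_models=True)
        assert list(by_model) == [1]
        assert ("A", 1) in by_model[1]

    def test_mmcif_input(self, tmp_path):
        import gemmi
        residues = idealized_triplet()
        pdb = tmp_path / "triplet.pdb"
        write_pdb(residues, pdb)
        st = gemmi.read_structure(str(pdb))
        st.setup_entities()
        cif = tmp_path / "triplet.cif"
        st.make_mmcif_document().write_file(str(cif))
        df = survey_structure(str(cif))
        assert len(df) == 6
        assert np.allclose(df["pucker_phase"], 162.0, atol=0.5)


class TestAnnotationTable:
    def test_resolution_filter_and_parsing(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text(
            "chain1,resnum1,chain2,resnum2,pair_class,base1,base2,duplex_id,resolution\n"
            "A,1,B,5,WC,DG,DC,d1,2.0\n"
            "A,2,B,4,wobble,DG,DT,d1,2.0\n"
            "A,3,B,3,WC,DA,DT,d2,3.5\n")
        from wobblefit.survey import read_bp_annotation
        pairs = read_bp_annotation(path)
        assert len(pairs) == 2          # the 3.5 A row is dropped
        assert pairs[1].pair_class == "wobble"

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("chain1,resnum1\nA,1\n")
        from wobblefit.survey import read_bp_annotation
        with pytest.raises(ValueError, match="missing columns"):
            read_bp_annotation(path)
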