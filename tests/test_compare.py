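"""Superposition, screw axes, helix rotation, H-bonds, identity, morphs."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rdcrefine import compare as cmp, structure as st, synthetic as syn
from rdcrefine.errors import DegenerateGeometryError, MappingError, ValidationError


def quaternion_rmsd_oracle(p, q):
    """Best-fit RMSD via the quaternion characteristic-polynomial method."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key).max()
    g = (p**2).sum() + (q**2).sum()
    return np.sqrt(max(g - 2 * lam, 0.0) / len(p))


class TestSuperpose:
    def test_congruent_copies_have_zero_rmsd(self, helix20, rng):
        rot = Rotation.random(random_state=3).as_matrix()
        moved = helix20.transformed(rot, rng.normal(size=3) * 5)
        res = cmp.superpose(moved, helix20)
        assert res.rmsd <= 1e-8
        assert abs(np.linalg.det(res.rotation) - 1) <= 1e-8

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(20):
            p = rng.normal(size=(4, 3)) * 5
            q = rng.normal(size=(4, 3)) * 5
            a = st.Structure({"A": [
                st.Residue(i + 1, "GLY", {"CA": st.Atom("CA", "C", p[i])}) for i in range(4)
            ]})
            b = st.Structure({"A": [
                st.Residue(i + 1, "GLY", {"CA": st.Atom("CA", "C", q[i])}) for i in range(4)
            ]})
            res = cmp.superpose(a, b)
            assert res.rmsd == pytest.approx(quaternion_rmsd_oracle(p, q), abs=1e-10)

    def test_symmetric_in_its_arguments(self, helix20, mixed_structure):
        sub = {r.seq_id for r in mixed_structure.residues() if r.seq_id <= 20}
        r1 = cmp.superpose(helix20, mixed_structure, selection=sub)
        r2 = cmp.superpose(mixed_structure, helix20, selection=sub)
        assert r1.rmsd == pytest.approx(r2.rmsd, abs=1e-8)

    def test_superposition_never_increases_rmsd(self, helix20, rng):
        jittered = helix20.with_coords(helix20.flat_coords() + rng.normal(0, 0.4, helix20.flat_coords().shape))
        moved = jittered.transformed(Rotation.random(random_state=5).as_matrix(), np.array([3.0, -2, 1]))
        before = np.sqrt(np.mean(np.sum((moved.coords() - helix20.coords()) ** 2, axis=1)))
        assert cmp.superpose(moved, helix20).rmsd <= before + 1e-12

    def test_unmatched_selection_raises_mapping_error(self, helix20):
        with pytest.raises(MappingError, match="99"):
            cmp.superpose(helix20, helix20, selection={1, 2, 3, 99})

    def test_collinear_atoms_are_degenerate(self):
        line = st.Structure({"A": [
            st.Residue(i + 1, "GLY", {"CA": st.Atom("CA", "C", np.array([float(i), 0, 0]))})
            for i in range(5)
        ]})
        with pytest.raises(DegenerateGeometryError):
            cmp.superpose(line, line)


class TestDisplacement:
    def test_identical_structures_have_zero_displacement(self, helix20):
        assert all(d == 0 for _, d in cmp.per_residue_displacement(helix20, helix20))

    def test_hinged_segment_moves_more_than_anchor(self, mixed_structure):
        moved = syn.apply_hinge(mixed_structure, (16, 23), (0, 1, 0), 20.0)
        disp = dict(cmp.per_residue_displacement(mixed_structure, moved))
        anchor_max = max(d for sid, d in disp.items() if sid < 16)
        moving = [d for sid, d in disp.items() if sid >= 17]
        assert all(d > anchor_max for d in moving)


class TestScrewAxis:
    def test_planted_rotation_recovered(self, mixed_structure):
        axis = np.array([0.2, 1.0, 0.3])
        axis /= np.linalg.norm(axis)
        moved = syn.apply_hinge(mixed_structure, (13, 23), axis, 10.0)
        sa = cmp.screw_axis(mixed_structure, moved, set(range(13, 24)))
        assert sa.angle_deg == pytest.approx(10.0, abs=0.1)
        assert abs(float(sa.axis @ axis)) > 0.999
        assert sa.reliable

    def test_identity_transform_is_flagged(self, mixed_structure):
        sa = cmp.screw_axis(mixed_structure, mixed_structure, set(range(5, 20)))
        assert sa.angle_deg <= 0.5 and not sa.reliable

    def test_composed_transform_reproduces_target_selection(self, mixed_structure):
        moved = syn.apply_hinge(mixed_structure, (13, 23), (0, 0, 1), 17.0)
        sel = set(range(13, 24))
        sa = cmp.screw_axis(mixed_structure, moved, sel)
        rot = Rotation.from_rotvec(np.deg2rad(sa.angle_deg) * sa.axis).as_matrix()
        p = mixed_structure.coords(sel, ("CA",))
        q = moved.coords(sel, ("CA",))
        mapped = (p - sa.pivot) @ rot.T + sa.pivot + sa.translation_along_axis * sa.axis
        assert np.abs(mapped - q).max() <= 1e-6

    def test_pivot_lies_near_hinge_point(self, mixed_structure):
        moved = syn.apply_hinge(mixed_structure, (13, 23), (0, 1, 0), 15.0)
        sa = cmp.screw_axis(mixed_structure, moved, set(range(13, 24)))
        hinge_ca = mixed_structure.get_residue(13).coord("CA")
        # distance from the hinge CA to the recovered axis line
        delta = hinge_ca - sa.pivot
        dist = np.linalg.norm(delta - (delta @ sa.axis) * sa.axis)
        assert dist <= 1.0


class TestHelixAxisRotation:
    def test_identical_structures_give_zero(self, helix20):
        assert cmp.helix_axis_rotation(helix20, helix20, (1, 20)) == pytest.approx(0.0, abs=0.01)

    def test_planted_axial_reorientation_recovered_with_sign(self, helix20):
        # crankshaft-style change: every residue's atoms rotate about the
        # helix-axis direction through its own CA, so the CA trace is
        # unchanged (a rigid whole-helix rotation would be cancelled by
        # the local superposition) while all carbonyls reorient by 15 deg
        ca = helix20.coords(range(1, 21), ("CA",))
        axis = cmp._helix_axis(ca)
        rot = Rotation.from_rotvec(np.deg2rad(15.0) * axis).as_matrix()
        rotated = helix20.copy()
        for res in rotated.residues():
            pivot = res.coord("CA")
            for name, atom in list(res.atoms.items()):
                res.atoms[name] = st.Atom(atom.name, atom.element,
                                          rot @ (atom.coord - pivot) + pivot)
        angle = cmp.helix_axis_rotation(helix20, rotated, (1, 20))
        assert abs(angle) == pytest.approx(15.0, abs=0.5)
        reverse = cmp.helix_axis_rotation(rotated, helix20, (1, 20))
        assert np.sign(reverse) == -np.sign(angle)

    def test_short_range_rejected(self, helix20):
        with pytest.raises(ValidationError):
            cmp.helix_axis_rotation(helix20, helix20, (1, 6))


class TestHBondPatterns:
    def test_rigid_motion_invariance(self, helix20, rng):
        rot = Rotation.random(random_state=8).as_matrix()
        moved = helix20.transformed(rot, rng.normal(size=3) * 20)
        c0 = cmp.hbond_patterns(helix20, (1, 20))
        c1 = cmp.hbond_patterns(moved, (1, 20))
        assert [(c.donor, c.pattern) for c in c0] == [(c.donor, c.pattern) for c in c1]

    def test_broken_bond_reported_absent_with_distance(self, helix20):
        # displace one amide far from its acceptor
        broken = helix20.copy()
        res = broken.get_residue(10)
        for name in ("N", "H"):
            atom = res.atoms[name]
            res.atoms[name] = st.Atom(atom.name, atom.element, atom.coord + np.array([0, 0, 8.0]))
        call = next(c for c in cmp.hbond_patterns(broken, (1, 20)) if c.donor == 10)
        assert call.pattern == "absent"
        assert call.candidates["i_i4"] > cmp.HBOND_DMAX


class TestIdentity:
    def test_identical_sequences_are_100_percent(self):
        rep = cmp.sequence_identity("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY", mode="global")
        assert rep.percent_identity == 100.0

    def test_matches_exhaustive_dp_oracle_on_4mer(self):
        # brute force over all monotone alignments of ACDE vs EDCA with
        # affine gaps (open 11, extend 1), BLOSUM62
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        a, b = "ACDE", "EDCA"
        best = (-1e9, 0, 0)
        # enumerate all alignments as monotone pairings of indices
        from itertools import combinations
        n, m = len(a), len(b)
        for k in range(1, min(n, m) + 1):
            for ia in combinations(range(n), k):
                for ib in combinations(range(m), k):
                    score = sum(blosum[a[x]][b[y]] for x, y in zip(ia, ib))
                    # affine gap cost: each maximal run of skipped residues
                    # in either sequence costs 11 + len
                    def gapcost(idx, length):
                        cost = 0
                        prev = -1
                        for i in idx:
                            gap = i - prev - 1
                            if gap:
                                cost += 10 + gap
                            prev = i
                        tail = length - 1 - idx[-1]
                        if tail:
                            cost += 10 + tail
                        return cost
                    score -= gapcost(ia, n) + gapcost(ib, m)
                    ident = sum(a[x] == b[y] for x, y in zip(ia, ib))
                    if score > best[0]:
                        best = (score, ident, k)
        rep = cmp.sequence_identity(a, b, mode="global")
        expected = round(100.0 * best[1] / best[2], 1)
        assert rep.percent_identity == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            cmp.sequence_identity("", "ACD")

    def test_positional_identity_counts_matching_names(self, helix20, helix310):
        pairs = [(i, i) for i in range(1, 11)]
        rep = cmp.positional_identity(helix20, helix310, pairs)
        assert rep.mode == "positional"
        assert rep.percent_identity == 100.0  # both generators emit ALA
        with pytest.raises(MappingError):
            cmp.positional_identity(helix20, helix310, [(1, 99)])

    def test_positional_identity_arithmetic(self, helix20):
        other = helix20.copy()
        for sid in (1, 2, 3, 4, 5, 6, 7):
            other.get_residue(sid).name = "GLY"
        rep = cmp.positional_identity(helix20, other, [(i, i) for i in range(1, 11)])
        assert rep.percent_identity == 30.0


class TestMorph:
    def test_two_frames_are_the_inputs(self, helix20, mixed_structure):
        sub20 = syn.make_structure(syn.SyntheticSpec(segments=(("alpha", 20),)))
        frames = cmp.write_morph(helix20, sub20, 2)
        np.testing.assert_array_equal(frames[0].flat_coords(), helix20.flat_coords())
        np.testing.assert_array_equal(frames[1].flat_coords(), sub20.flat_coords())

    def test_midpoint_is_the_coordinate_average(self, helix20):
        shifted = helix20.transformed(np.eye(3), np.array([2.0, 0, 0]))
        frames = cmp.write_morph(helix20, shifted, 3)
        mid = 0.5 * (helix20.flat_coords() + shifted.flat_coords())
        np.testing.assert_allclose(frames[1].flat_coords(), mid, atol=1e-12)

    def test_displacement_is_monotone_along_frames(self, helix20):
        shifted = helix20.transformed(np.eye(3), np.array([0, 3.0, 0]))
        frames = cmp.write_morph(helix20, shifted, 40)
        start = helix20.flat_coords()
        d = [np.linalg.norm(f.flat_coords() - start, axis=1).mean() for f in frames]
        assert all(b >= a for a, b in zip(d, d[1:]))

    def test_too_few_frames_rejected(self, helix20):
        with pytest.raises(ValidationError):
            cmp.write_morph(helix20, helix20, 1)
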