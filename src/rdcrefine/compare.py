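"""Conformational-change analytics between two structures.

Covers the quantities used to describe a substrate-dependent conformational
change in a single fold: least-squares Calpha superposition (Kabsch),
per-residue displacement profiles, rigid-body screw-axis decomposition of a
domain motion, rotation of a helix about its own long axis, backbone
hydrogen-bond pattern classification (alpha i,i+4 versus 3-10 i,i+3), and
pairwise sequence / positional identity for cross-enzyme comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DegenerateGeometryError, MappingError, ValidationError
from .structure import Structure

__all__ = [
    "SuperpositionResult",
    "ScrewAxis",
    "HBondCall",
    "IdentityReport",
    "superpose",
    "per_residue_displacement",
    "screw_axis",
    "helix_axis_rotation",
    "hbond_patterns",
    "sequence_identity",
    "positional_identity",
    "write_morph",
]

#: Default backbone H-bond geometry: O...N cutoff (A) and N-H...O angle floor (deg).
HBOND_DMAX = 3.5
HBOND_ANGLE_MIN = 120.0


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto target, and its RMSD."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, A
    rmsd: float
    n_atoms: int
    transformed: Structure  # mobile after the transform (mobile itself untouched)


def _paired_coords(mobile: Structure, target: Structure, selection, atom_names):
    sel = None if selection is None else set(selection)
    p_rows, q_rows, missing = [], [], []
    target_map = {r.seq_id: r for r in target.residues()}
    for res in mobile.residues():
        if sel is not None and res.seq_id not in sel:
            continue
        other = target_map.get(res.seq_id)
        for name in atom_names:
            a = res.get(name)
            b = other.get(name) if other is not None else None
            if a is not None and b is not None:
                p_rows.append(a.coord)
                q_rows.append(b.coord)
            elif sel is not None:
                missing.append(res.seq_id)
    if sel is not None:
        present = {r.seq_id for r in mobile.residues()}
        missing.extend(sorted(sel - present))
    return np.array(p_rows), np.array(q_rows), sorted(set(missing))


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rotation/translation mapping point set p onto q."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = qc - rot @ pc
    resid = q0 - p0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return rot, t, rmsd


def superpose(
    mobile: Structure,
    target: Structure,
    selection=None,
    atom_names=("CA",),
) -> SuperpositionResult:
    """Optimal least-squares (Kabsch) superposition over matched atoms.

    ``selection`` is a set of residue seq_ids (author numbering); ``None``
    uses every residue shared by both structures.  The mobile structure is
    not mutated; the transformed copy is returned in the result.
    """
    p, q, missing = _paired_coords(mobile, target, selection, atom_names)
    if selection is not None and missing:
        raise MappingError("selection could not be fully matched", missing)
    if len(p) < 3:
        raise DegenerateGeometryError(f"need >= 3 matched atoms, found {len(p)}")
    spread = np.linalg.svd(p - p.mean(axis=0), compute_uv=False)
    if spread[1] <= 1e-8 * max(spread[0], 1.0):
        raise DegenerateGeometryError("matched atoms are collinear")
    rot, t, rmsd = _kabsch(p, q)
    return SuperpositionResult(rot, t, rmsd, len(p), mobile.transformed(rot, t))


def per_residue_displacement(a: Structure, b: Structure, selection=None) -> list[tuple[int, float]]:
    """Calpha-Calpha distance per shared residue (structures pre-superposed).

    Residues missing a Calpha in either structure are omitted.
    """
    sel = None if selection is None else set(selection)
    b_map = {r.seq_id: r for r in b.residues()}
    out = []
    for res in a.residues():
        if sel is not None and res.seq_id not in sel:
            continue
        other = b_map.get(res.seq_id)
        if other is None or res.get("CA") is None or other.get("CA") is None:
            continue
        out.append((res.seq_id, float(np.linalg.norm(res.coord("CA") - other.coord("CA")))))
    if not out:
        raise MappingError("no shared residues with Calpha atoms")
    return out


# ---------------------------------------------------------------------------
# Screw-axis decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScrewAxis:
    """Axis/angle/pivot/translation decomposition of a rigid-body motion."""

    axis: np.ndarray  # unit vector
    angle_deg: float  # in (-180, 180]
    pivot: np.ndarray  # point on the axis closest to the moving body's centroid, A
    translation_along_axis: float  # A
    reliable: bool  # False when the rotation is below 0.5 degrees


def screw_axis(a: Structure, b: Structure, selection, atom_names=("CA",)) -> ScrewAxis:
    """Screw decomposition of the rigid transform carrying ``selection``
    from state a to state b.

    The caller superposes the anchor (non-moving) region first so that the
    residual transform of the selection is the domain motion itself.
    """
    p, q, missing = _paired_coords(a, b, set(selection), atom_names)
    if missing:
        raise MappingError("selection could not be fully matched", missing)
    if len(p) < 3:
        raise DegenerateGeometryError(f"need >= 3 matched atoms, found {len(p)}")
    rot, t, _ = _kabsch(p, q)
    rotvec = Rotation.from_matrix(rot).as_rotvec()
    angle = float(np.rad2deg(np.linalg.norm(rotvec)))
    reliable = angle >= 0.5
    axis = rotvec / np.linalg.norm(rotvec) if reliable else np.array([0.0, 0.0, 1.0])
    d_along = float(axis @ t)
    # point on the axis: solve (I - R) p0 = t_perp in the plane normal to the axis
    t_perp = t - d_along * axis
    p0, *_ = np.linalg.lstsq(np.eye(3) - rot, t_perp, rcond=None)
    # remove any component along the axis (the solution is only defined up to it)
    p0 = p0 - (axis @ p0) * axis
    centroid = p.mean(axis=0)
    pivot = p0 + (axis @ (centroid - p0)) * axis
    return ScrewAxis(axis, angle, pivot, d_along, reliable)


# ---------------------------------------------------------------------------
# Helix-axis rotation
# ---------------------------------------------------------------------------

def _helix_axis(ca: np.ndarray) -> np.ndarray:
    """Principal inertia axis of the Calpha trace, oriented N- to C-terminus."""
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis


def helix_axis_rotation(a: Structure, b: Structure, helix_range: tuple[int, int]) -> float:
    """Mean rotation (degrees, signed) of a helix about its own long axis
    between states a and b.

    The helix in b is first locally superposed onto the helix in a; the
    residual reorientation of the Calpha->O carbonyl vectors about the
    helix axis is then averaged over residues.  Sign convention: positive
    means clockwise when viewed from the helix N-terminus looking toward
    the C-terminus.
    """
    start, end = helix_range
    seq_ids = list(range(start, end + 1))
    if len(seq_ids) < 7:
        raise ValidationError("helix range must span at least 7 residues")
    sup = superpose(b, a, selection=seq_ids, atom_names=("CA",))
    b_local = sup.transformed
    ca_a = a.coords(seq_ids, ("CA",))
    if len(ca_a) != len(seq_ids):
        raise MappingError("helix range missing Calpha atoms in first structure")
    axis = _helix_axis(ca_a)
    angles = []
    b_map = {r.seq_id: r for r in b_local.residues()}
    for res in a.residues():
        if not start <= res.seq_id <= end:
            continue
        other = b_map.get(res.seq_id)
        if other is None:
            continue
        try:
            va = res.coord("O") - res.coord("CA")
            vb = other.coord("O") - other.coord("CA")
        except ValidationError:
            continue
        # project onto the plane normal to the helix axis
        va = va - (va @ axis) * axis
        vb = vb - (vb @ axis) * axis
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na < 1e-6 or nb < 1e-6:
            continue
        va, vb = va / na, vb / nb
        ccw = float(np.arctan2(axis @ np.cross(va, vb), va @ vb))
        angles.append(-np.rad2deg(ccw))  # positive = clockwise viewed from N-terminus
    if not angles:
        raise MappingError("no carbonyl vectors available in helix range")
    return float(np.mean(angles))


# ---------------------------------------------------------------------------
# Hydrogen-bond pattern classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCall:
    """Backbone H-bond assignment for one donor amide."""

    donor: int  # seq_id of the NH residue
    acceptor: int | None  # seq_id of the C=O residue (None when absent)
    distance: float  # O...N distance of the assigned (or closest) candidate, A
    pattern: str  # "alpha_i_i4" | "three10_i_i3" | "absent"
    candidates: dict  # {"i_i3": O...N A or None, "i_i4": ...} keyed from the donor side


def _hbond_geometry(acc, don, angle_min):
    """(O...N distance, qualifies?) for acceptor C=O -> donor N-H."""
    o = acc.get("O")
    n = don.get("N")
    if o is None or n is None:
        return None, False
    dist = float(np.linalg.norm(o.coord - n.coord))
    h = don.amide_h
    if h is not None:
        v1 = n.coord - h.coord
        v2 = o.coord - h.coord
        cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return dist, angle >= angle_min
    return dist, True


def hbond_patterns(
    s: Structure,
    residue_range: tuple[int, int],
    d_max: float = HBOND_DMAX,
    angle_min: float = HBOND_ANGLE_MIN,
) -> list[HBondCall]:
    """Classify each donor amide in the range as alpha (i,i+4), 3-10 (i,i+3)
    or absent.

    For every acceptor residue i the candidates are C=O(i) -> NH(i+3) and
    C=O(i) -> NH(i+4); a candidate qualifies when O...N <= d_max and, if an
    amide proton is present, the N-H...O angle >= angle_min.  Each donor is
    classified by its shortest qualifying candidate; both candidate
    distances are reported regardless of qualification.
    """
    start, end = residue_range
    res_map = {r.seq_id: r for r in s.residues()}
    calls = []
    for donor_id in range(start, end + 1):
        don = res_map.get(donor_id)
        if don is None or don.get("N") is None:
            continue
        cands = {}
        best = None  # (distance, acceptor_id, offset)
        for offset, key in ((3, "i_i3"), (4, "i_i4")):
            acc = res_map.get(donor_id - offset)
            if acc is None:
                cands[key] = None
                continue
            dist, ok = _hbond_geometry(acc, don, angle_min)
            cands[key] = dist
            if dist is not None and dist <= d_max and ok:
                if best is None or dist < best[0]:
                    best = (dist, donor_id - offset, offset)
        if best is None:
            closest = min(
                (d for d in cands.values() if d is not None), default=float("nan")
            )
            calls.append(HBondCall(donor_id, None, closest, "absent", cands))
        else:
            pattern = "alpha_i_i4" if best[2] == 4 else "three10_i_i3"
            calls.append(HBondCall(donor_id, best[1], best[0], pattern, cands))
    return calls


# ---------------------------------------------------------------------------
# Sequence / positional identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentityReport:
    """Percent identity over aligned (non-gap) columns."""

    percent_identity: float
    aligned_length: int
    mode: str  # "sequence" or "positional"


def sequence_identity(
    seq_a: str,
    seq_b: str,
    mode: str = "local",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> IdentityReport:
    """Pairwise identity from a BLOSUM62 affine-gap alignment.

    Identity = identical positions / aligned positions, gap columns
    excluded from the denominator, reported to one decimal.
    """
    if not seq_a or not seq_b:
        raise ValidationError("sequences must be non-empty")
    if mode not in ("global", "local"):
        raise ValidationError(f"mode must be global or local, got {mode!r}")
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    ident = 0
    aligned = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            aligned += 1
            if seq_a[i].upper() == seq_b[j].upper():
                ident += 1
    if aligned == 0:
        return IdentityReport(0.0, 0, "sequence")
    return IdentityReport(round(100.0 * ident / aligned, 1), aligned, "sequence")


def positional_identity(a: Structure, b: Structure, correspondence) -> IdentityReport:
    """Identity over an explicit list of (seq_id_a, seq_id_b) residue pairs.

    The correspondence comes from an external structural alignment; it is
    never inferred here.
    """
    pairs = list(correspondence)
    if not pairs:
        raise ValidationError("correspondence must be non-empty")
    a_map = {r.seq_id: r for r in a.residues()}
    b_map = {r.seq_id: r for r in b.residues()}
    missing = [p for p in pairs if p[0] not in a_map or p[1] not in b_map]
    if missing:
        raise MappingError("correspondence references missing residues", missing)
    ident = sum(1 for ia, ib in pairs if a_map[ia].name == b_map[ib].name)
    return IdentityReport(round(100.0 * ident / len(pairs), 1), len(pairs), "positional")


# ---------------------------------------------------------------------------
# Morph export
# ---------------------------------------------------------------------------

def write_morph(a: Structure, b: Structure, n_frames: int) -> list[Structure]:
    """Linear Cartesian interpolation from a to b in ``n_frames`` models.

    Frame 1 is a, frame ``n_frames`` is b; the caller superposes a onto b
    first.  Both structures must share their full atom complement.
    """
    if n_frames < 2:
        raise ValidationError("a morph needs at least 2 frames")
    xa = a.flat_coords()
    xb = b.flat_coords()
    if xa.shape != xb.shape:
        raise MappingError(
            f"structures differ in atom count ({len(xa)} vs {len(xb)})"
        )
    frames = []
    for i in range(n_frames):
        f = i / (n_frames - 1)
        frames.append(a.with_coords((1 - f) * xa + f * xb))
    return frames
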