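"""Desk-scale restrained annealing with RDC flat-bottom penalties.

This is an intentionally simplified surrogate for solvent-phase restrained
molecular dynamics: each increment perturbs the coordinates with seeded
Gaussian noise, minimizes the sum of the RDC flat-bottom penalties (one
alignment tensor per medium, held fixed during the minimization) and a
harmonic stereochemical reference term, then refits each medium's tensor to
the relaxed coordinates and records a snapshot.  The RDC force constant
ramps geometrically across increments (defaults 0.001 -> 0.01
kcal mol^-1 Hz^-1), so early increments let the restraints identify
problem records gently while late increments enforce them.

The stereochemical term restrains, harmonically, the reference bond
lengths, the 1-3 distances standing in for bond angles, the backbone
hydrogen-bond O...N distances of the start structure, the peptide-plane
out-of-plane coordinates of the amide H and carbonyl O, and — weakly —
the backbone 1-4 distances.  There are no hard torsional terms:
hinge-like motions that preserve local geometry and the hydrogen-bond
network remain soft modes the RDC restraints can drive.

Records that violate their flat bottom persistently across late increments
are flagged as persistent violators; flagged records stay in every report
but contribute zero restraint energy, mirroring the iterative-correction
bookkeeping used when refining against measured couplings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import RefinementError, ValidationError
from .rdc import (
    RDCSet,
    RDCStatus,
    RestraintResult,
    SaupeTensor,
    back_calc,
    fit_tensor_svd,
    restraint_energy,
)
from .structure import BondVectorSet, Structure, extract_nh_vectors
from . import compare as _compare

__all__ = [
    "RestraintSchedule",
    "StereoModel",
    "Snapshot",
    "Trajectory",
    "Ensemble",
    "build_stereo_model",
    "run_soft_annealing",
    "detect_persistent_violators",
    "iterative_violator_correction",
    "select_ensemble",
    "representative",
]


@dataclass(frozen=True)
class RestraintSchedule:
    """Parameters of one annealing run.

    k ramps geometrically from ``k_initial`` to ``k_final`` (kcal/mol per
    Hz of violation); ``tolerance`` is the flat-bottom half width in Hz;
    ``anneal_noise`` is the Gaussian coordinate perturbation amplitude of
    the first increment, in Angstroms.  The amplitude cools geometrically
    to ``anneal_noise_final`` (default ``anneal_noise / 20``) across the
    run, so early increments search while late increments settle.

    ``centering_weight`` scales a weak harmonic data term,
    ``w * k * dD^2 / (2 * tolerance)`` per active record, that the
    minimizer feels everywhere including inside the flat bottom.  The
    flat bottom alone leaves a force-free plateau whose width is the
    method's angular resolution limit; the centering term gives that
    plateau a gentle slope toward the least-squares optimum without
    changing any reported violation energy (reports and violator
    detection use the exact flat-bottom form).  At the tolerance edge
    the centering force is ``w * k`` — one tenth of the violation force
    at the default — so it never competes with the restraints proper.
    Set it to 0 to recover a pure flat-bottom drive.
    """

    n_increments: int = 20
    steps_per_increment: int = 100
    k_initial: float = 0.001
    k_final: float = 0.01
    tolerance: float = 3.0
    anneal_noise: float = 0.05
    anneal_noise_final: float | None = None
    centering_weight: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.k_initial > self.k_final:
            raise ValidationError("k_initial must not exceed k_final")
        if self.n_increments < 1:
            raise ValidationError("n_increments must be >= 1")
        if self.k_initial < 0 or self.tolerance < 0 or self.anneal_noise < 0:
            raise ValidationError("schedule parameters must be non-negative")
        if self.anneal_noise_final is not None and self.anneal_noise_final < 0:
            raise ValidationError("schedule parameters must be non-negative")
        if self.centering_weight < 0:
            raise ValidationError("schedule parameters must be non-negative")

    @staticmethod
    def _geometric(v0: float, v1: float, i: int, n: int) -> float:
        if n == 1:
            return v1
        if v0 == v1 or v0 == 0:
            # geometric interpolation undefined from zero; fall back
            return v0 + (v1 - v0) * i / (n - 1)
        return v0 * (v1 / v0) ** (i / (n - 1))

    def k_at(self, increment: int) -> float:
        """Force constant at a 0-based increment (geometric ramp)."""
        return self._geometric(self.k_initial, self.k_final, increment, self.n_increments)

    def noise_at(self, increment: int) -> float:
        """Perturbation amplitude at a 0-based increment (geometric cooling)."""
        final = self.anneal_noise_final
        if final is None:
            final = self.anneal_noise / 20.0
        return self._geometric(self.anneal_noise, final, increment, self.n_increments)


@dataclass
class StereoModel:
    """Harmonic reference-geometry restraints extracted from a structure.

    Two term types: pairwise distances (bonds, 1-3 angle proxies, 1-4
    torsion regularizers, hydrogen bonds) and out-of-plane coordinates for
    the peptide-plane substituents (amide H, carbonyl O), whose positions
    are second-order in every pairwise distance and would otherwise drift.
    """

    pairs: np.ndarray  # (n, 2) atom indices into the flat coordinate array
    d0: np.ndarray  # reference distances, A
    kf: np.ndarray  # force constants, kcal/mol/A^2
    planar: np.ndarray  # (m, 4) indices (apex, origin, a, b); plane at origin
    h0: np.ndarray  # reference out-of-plane heights of the apex, A
    kp: np.ndarray  # planar force constants, kcal/mol/A^2

    def energy_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        d = x[self.pairs[:, 0]] - x[self.pairs[:, 1]]
        r = np.linalg.norm(d, axis=1)
        dr = r - self.d0
        e = float(np.sum(self.kf * dr**2))
        g = np.zeros_like(x)
        coef = (2 * self.kf * dr / np.maximum(r, 1e-12))[:, None] * d
        np.add.at(g, self.pairs[:, 0], coef)
        np.add.at(g, self.pairs[:, 1], -coef)
        if len(self.planar):
            apex, orig, ia, ib = (self.planar[:, j] for j in range(4))
            a = x[ia] - x[orig]
            b = x[ib] - x[orig]
            v = x[apex] - x[orig]
            w = np.cross(a, b)
            wn = np.linalg.norm(w, axis=1)
            n = w / wn[:, None]
            h = np.einsum("ij,ij->i", n, v) - self.h0
            e += float(np.sum(self.kp * h**2))
            pref = (2 * self.kp * h)[:, None]
            # dh/dv = n ; dh/dw = (I - n n^T) v / |w| ; dw via cross products
            gdir = (v - np.einsum("ij,ij->i", n, v)[:, None] * n) / wn[:, None]
            da = np.cross(b, gdir)
            db = np.cross(gdir, a)
            np.add.at(g, apex, pref * n)
            np.add.at(g, ia, pref * da)
            np.add.at(g, ib, pref * db)
            np.add.at(g, orig, pref * (-n - da - db))
        return e, g


#: Stereochemical force constants (kcal/mol/A^2): bonds stiff, angles (1-3
#: distances) firm, hydrogen bonds soft enough to stretch but not break,
#: and a weak 1-4 term that regularizes torsional drift without locking
#: hinge motions out.
K_BOND = 100.0
K_ANGLE = 30.0
K_HBOND = 10.0
K_TORSION = 2.0
K_PLANAR = 30.0


def build_stereo_model(start: Structure, hbond_dmax: float = _compare.HBOND_DMAX) -> StereoModel:
    """Reference-geometry restraints for a backbone structure.

    Restrained pairs: covalent backbone bonds (N-H, N-CA, CA-C, C-O and the
    peptide C-N), the 1-3 distances across each backbone angle, and every
    backbone O(i)...N(i+3/i+4) pair within ``hbond_dmax`` in the start
    structure.
    """
    index: dict[tuple[int, str], int] = {}
    i = 0
    residues = list(start.residues())
    for res in residues:
        for name in res.atoms:
            index[(res.seq_id, name)] = i
            i += 1
    x = start.flat_coords()

    def idx(seq_id, name):
        return index.get((seq_id, name))

    pairs, kf = [], []
    bonded = [("N", "CA"), ("CA", "C"), ("C", "O"), ("N", "H"), ("N", "HN")]
    angle_13 = [("N", "C"), ("CA", "O"), ("H", "CA"), ("HN", "CA")]
    for res in residues:
        for a, b in bonded:
            ia, ib = idx(res.seq_id, a), idx(res.seq_id, b)
            if ia is not None and ib is not None:
                pairs.append((ia, ib))
                kf.append(K_BOND)
        for a, b in angle_13:
            ia, ib = idx(res.seq_id, a), idx(res.seq_id, b)
            if ia is not None and ib is not None:
                pairs.append((ia, ib))
                kf.append(K_ANGLE)
    for prev, res in zip(residues, residues[1:]):
        links = [("C", "N", K_BOND), ("CA", "N", K_ANGLE), ("C", "CA", K_ANGLE),
                 ("O", "N", K_ANGLE), ("C", "H", K_ANGLE), ("C", "HN", K_ANGLE),
                 # 1-4 distances across phi, psi and omega
                 ("C", "C", K_TORSION), ("N", "N", K_TORSION), ("CA", "CA", K_TORSION)]
        for a, b, k in links:
            ia, ib = idx(prev.seq_id, a), idx(res.seq_id, b)
            if ia is not None and ib is not None:
                pairs.append((ia, ib))
                kf.append(k)
    # backbone hydrogen-bond distances present in the start structure
    res_map = {r.seq_id: r for r in residues}
    for res in residues:
        for offset in (3, 4):
            acc = res_map.get(res.seq_id - offset)
            if acc is None:
                continue
            ia, ib = idx(acc.seq_id, "O"), idx(res.seq_id, "N")
            if ia is None or ib is None:
                continue
            d = np.linalg.norm(x[ia] - x[ib])
            if d <= hbond_dmax:
                pairs.append((ia, ib))
                kf.append(K_HBOND)
    # peptide-plane out-of-plane restraints: amide H against the
    # (C_prev, N, CA) plane and carbonyl O against the (CA, C, N_next) plane
    planar, kp = [], []
    for prev, res in zip(residues, residues[1:]):
        hname = "H" if idx(res.seq_id, "H") is not None else "HN"
        quad = (idx(res.seq_id, hname), idx(res.seq_id, "N"),
                idx(prev.seq_id, "C"), idx(res.seq_id, "CA"))
        if all(q is not None for q in quad):
            planar.append(quad)
            kp.append(K_PLANAR)
        quad = (idx(prev.seq_id, "O"), idx(prev.seq_id, "C"),
                idx(prev.seq_id, "CA"), idx(res.seq_id, "N"))
        if all(q is not None for q in quad):
            planar.append(quad)
            kp.append(K_PLANAR)
    pairs_arr = np.array(pairs, dtype=int).reshape(-1, 2)
    d = np.linalg.norm(x[pairs_arr[:, 0]] - x[pairs_arr[:, 1]], axis=1)
    planar_arr = np.array(planar, dtype=int).reshape(-1, 4)
    model = StereoModel(
        pairs_arr, d, np.array(kf, float),
        planar_arr, np.zeros(len(planar)), np.array(kp, float),
    )
    if len(planar_arr):
        apex, orig, ia, ib = (planar_arr[:, j] for j in range(4))
        w = np.cross(x[ia] - x[orig], x[ib] - x[orig])
        n = w / np.linalg.norm(w, axis=1)[:, None]
        model.h0 = np.einsum("ij,ij->i", n, x[apex] - x[orig])
    return model


# ---------------------------------------------------------------------------
# Trajectory containers
# ---------------------------------------------------------------------------

@dataclass
class Snapshot:
    """State recorded at the end of one increment."""

    increment: int
    structure: Structure
    tensors: dict[str, SaupeTensor]
    restraints: dict[str, RestraintResult]
    q_factors: dict[str, float]
    k: float
    violation_energy: float  # summed over media


@dataclass
class Trajectory:
    snapshots: list[Snapshot]
    schedule: RestraintSchedule
    rdc_sets: list[RDCSet] = field(default_factory=list)

    def log_table(self) -> str:
        """Tab-delimited per-increment log."""
        lines = ["increment\tk\t" + "\t".join(
            f"Q_{s.medium}\tE_{s.medium}" for s in self.rdc_sets
        ) + "\tE_total"]
        for snap in self.snapshots:
            cells = [str(snap.increment), f"{snap.k:.6g}"]
            for s in self.rdc_sets:
                cells.append(f"{snap.q_factors[s.medium]:.4f}")
                cells.append(f"{snap.restraints[s.medium].energy:.6g}")
            cells.append(f"{snap.violation_energy:.6g}")
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


@dataclass
class Ensemble:
    """Low-violation conformers sorted ascending by violation energy."""

    members: list[Structure]
    violation_energies: list[float]
    source_increments: list[int]

    def __post_init__(self):
        if sorted(self.violation_energies) != self.violation_energies:
            raise ValidationError("ensemble members must be sorted by violation energy")


# ---------------------------------------------------------------------------
# The annealing loop
# ---------------------------------------------------------------------------

def _nh_indices(start: Structure, rdc_sets):
    """Per medium: (record row indices into rdcs.records, N indices, H indices)."""
    index: dict[tuple[int, str], int] = {}
    i = 0
    for res in start.residues():
        for name in res.atoms:
            index[(res.seq_id, name)] = i
            i += 1
    plans = []
    for rdcs in rdc_sets:
        rows, ns, hs = [], [], []
        for row, rec in enumerate(rdcs.records):
            ni = index.get((rec.seq_id, "N"))
            hi = index.get((rec.seq_id, "H"), index.get((rec.seq_id, "HN")))
            if ni is None or hi is None:
                continue
            rows.append(row)
            ns.append(ni)
            hs.append(hi)
        plans.append((np.array(rows, int), np.array(ns, int), np.array(hs, int)))
    return plans


def _rdc_energy_grad(x, rdcs, plan, tensor, k, tolerance, centering_weight=0.0):
    """Flat-bottom (plus optional centering) RDC energy and coordinate gradient."""
    rows, ns, hs = plan
    g = np.zeros_like(x)
    if len(rows) == 0:
        return 0.0, g
    rvec = x[hs] - x[ns]
    norms = np.linalg.norm(rvec, axis=1)
    u = rvec / norms[:, None]
    a = tensor.components
    au = u @ a
    d_pred = np.einsum("ij,ij->i", u, au)
    obs = np.array([rdcs.records[r].observed for r in rows])
    active = np.array([rdcs.records[r].status == RDCStatus.ACTIVE for r in rows])
    dd = obs - d_pred
    viol = np.maximum(0.0, np.abs(dd) - tolerance)
    viol[~active] = 0.0
    e = float(k * viol.sum())
    # dE/dD per record: -k sign(dd) on violations, plus the centering slope
    dE_dD = np.zeros(len(rows))
    live = viol > 0
    dE_dD[live] = -k * np.sign(dd[live])
    if centering_weight > 0 and tolerance > 0:
        wc = centering_weight * k / tolerance
        e += float(0.5 * wc * np.sum(dd[active] ** 2))
        dE_dD[active] += -wc * dd[active]
    if np.any(dE_dD != 0):
        # dD/du = 2 A u; du/dr = (I - uu^T)/|r|
        du = dE_dD[:, None] * (2.0 * au)
        proj = du - np.einsum("ij,ij->i", du, u)[:, None] * u
        dr = proj / norms[:, None]
        np.add.at(g, hs, dr)
        np.add.at(g, ns, -dr)
    return e, g


def run_soft_annealing(
    start: Structure,
    rdc_sets: list[RDCSet],
    schedule: RestraintSchedule,
    stereo_model: StereoModel | None = None,
) -> Trajectory:
    """Incremental restrained optimization against one or more RDC sets.

    Per increment: seeded Gaussian coordinate perturbation, L-BFGS
    minimization of (sum of per-medium flat-bottom RDC energies at the
    current tensors) + (harmonic stereochemical reference energy), tensor
    refit per medium on the relaxed coordinates, snapshot.  All media are
    restrained simultaneously with equal weight, one tensor each.
    """
    if not rdc_sets:
        raise ValidationError("at least one RDC set is required")
    vectors = extract_nh_vectors(start)
    have = {seq_id for seq_id, _ in vectors.entries}
    for rdcs in rdc_sets:
        covered = sum(1 for r in rdcs.records if r.seq_id in have)
        if covered < 0.5 * len(rdcs.records):
            raise ValidationError(
                f"medium {rdcs.medium!r}: N-H vectors cover only {covered}/{len(rdcs.records)} records"
            )
    stereo = stereo_model if stereo_model is not None else build_stereo_model(start)
    plans = _nh_indices(start, rdc_sets)
    rng = np.random.default_rng(schedule.seed)
    x = start.flat_coords()
    n_atoms = len(x)

    tensors: dict[str, SaupeTensor] = {}
    try:
        for rdcs in rdc_sets:
            tensors[rdcs.medium], _ = fit_tensor_svd(vectors, rdcs)
    except ValidationError as exc:
        raise RefinementError(f"initial tensor fit failed: {exc}", increment=0) from exc

    snapshots: list[Snapshot] = []
    for inc in range(schedule.n_increments):
        k = schedule.k_at(inc)
        x = x + rng.normal(0.0, schedule.noise_at(inc), size=x.shape)

        def objective(flat):
            pos = flat.reshape(n_atoms, 3)
            e, g = stereo.energy_grad(pos)
            for rdcs, plan in zip(rdc_sets, plans):
                er, gr = _rdc_energy_grad(
                    pos, rdcs, plan, tensors[rdcs.medium], k,
                    schedule.tolerance, schedule.centering_weight,
                )
                e += er
                g = g + gr
            return e, g.ravel()

        result = minimize(
            objective,
            x.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": schedule.steps_per_increment},
        )
        if not np.all(np.isfinite(result.x)):
            raise RefinementError("non-finite coordinates after minimization", increment=inc)
        x = result.x.reshape(n_atoms, 3)

        current = start.with_coords(x)
        cur_vectors = extract_nh_vectors(current)
        restraints: dict[str, RestraintResult] = {}
        qs: dict[str, float] = {}
        total = 0.0
        for rdcs in rdc_sets:
            try:
                tensors[rdcs.medium], report = fit_tensor_svd(cur_vectors, rdcs)
            except ValidationError as exc:
                raise RefinementError(
                    f"tensor fit failed for medium {rdcs.medium!r}: {exc}", increment=inc
                ) from exc
            pred = dict(back_calc(tensors[rdcs.medium], cur_vectors))
            matched = [r for r in rdcs.records if r.seq_id in pred]
            res = restraint_energy(
                RDCSet(rdcs.medium, matched),
                [pred[r.seq_id] for r in matched],
                k=k,
                tolerance=schedule.tolerance,
            )
            if not np.isfinite(res.energy):
                raise RefinementError("non-finite restraint energy", increment=inc)
            restraints[rdcs.medium] = res
            qs[rdcs.medium] = report.q
            total += res.energy
        snapshots.append(
            Snapshot(inc, current, dict(tensors), restraints, qs, k, total)
        )
    return Trajectory(snapshots, schedule, list(rdc_sets))


# ---------------------------------------------------------------------------
# Violator detection and ensemble selection
# ---------------------------------------------------------------------------

def detect_persistent_violators(
    traj: Trajectory, fraction: float = 0.8, window: int = 10
) -> list[tuple[str, int]]:
    """Records whose flat bottom is violated in >= ``fraction`` of the last
    ``window`` increments.

    Returns (medium, seq_id) pairs; flagging (status flip) is left to the
    caller so the decision stays auditable.
    """
    if not traj.snapshots:
        raise ValidationError("trajectory is empty")
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    if window < 1 or len(traj.snapshots) < window:
        raise ValidationError(
            f"window {window} exceeds trajectory length {len(traj.snapshots)}"
        )
    tail = traj.snapshots[-window:]
    flagged = []
    for rdcs in traj.rdc_sets:
        counts: dict[int, int] = {}
        for snap in tail:
            for seq_id, _, viol, _ in snap.restraints[rdcs.medium].per_record:
                if viol > 0:
                    counts[seq_id] = counts.get(seq_id, 0) + 1
        for seq_id, c in sorted(counts.items()):
            if c >= fraction * window:
                flagged.append((rdcs.medium, seq_id))
    return flagged


def iterative_violator_correction(
    start: Structure,
    rdc_sets: list[RDCSet],
    schedule: RestraintSchedule,
    fraction: float = 0.8,
    window: int = 10,
    rounds: int = 2,
) -> tuple[Trajectory, list[tuple[str, int]]]:
    """Annealing with iterative persistent-violator correction.

    Runs the annealing protocol, flags persistent violators, re-flags the
    sets (flagged records keep reporting but stop contributing energy and
    leave the tensor fits), and repeats.  A record flagged in an earlier
    round is dropped from the final list if, once the fit is no longer
    dragged by the true offenders, it stops violating persistently —
    one-round detection otherwise inherits false positives from the
    outliers' own distortion of the tensor.  Returns the last trajectory
    and the final flagged (medium, seq_id) list.
    """
    if rounds < 1:
        raise ValidationError("rounds must be >= 1")
    sets = list(rdc_sets)
    traj = run_soft_annealing(start, sets, schedule)
    win = min(window, len(traj.snapshots))
    flagged = detect_persistent_violators(traj, fraction=fraction, window=win)
    for _ in range(rounds - 1):
        if not flagged:
            break
        by_medium: dict[str, set[int]] = {}
        for medium, seq_id in flagged:
            by_medium.setdefault(medium, set()).add(seq_id)
        sets = [
            rs.with_status(by_medium.get(rs.medium, ()), RDCStatus.PERSISTENT_VIOLATOR)
            for rs in rdc_sets
        ]
        traj = run_soft_annealing(start, sets, schedule)
        flagged = detect_persistent_violators(traj, fraction=fraction, window=win)
    return traj, sorted(flagged)


def select_ensemble(traj: Trajectory, n: int) -> Ensemble:
    """The ``n`` snapshots of lowest total violation energy, ascending;
    ties break toward the earlier increment."""
    if n <= 0:
        raise ValidationError("ensemble size must be positive")
    if n > len(traj.snapshots):
        raise ValidationError(
            f"requested {n} members from {len(traj.snapshots)} snapshots"
        )
    ranked = sorted(traj.snapshots, key=lambda s: (s.violation_energy, s.increment))[:n]
    return Ensemble(
        [s.structure for s in ranked],
        [s.violation_energy for s in ranked],
        [s.increment for s in ranked],
    )


def representative(ens: Ensemble, selection=None) -> tuple[Structure, int]:
    """The member closest (Calpha RMSD) to the ensemble-average coordinates.

    All members are first superposed onto the first member over the
    selection's Calpha atoms; the average is taken over those atoms.
    """
    if not ens.members:
        raise ValidationError("ensemble is empty")
    ref = ens.members[0]
    if selection is not None and not set(selection):
        raise ValidationError("selection is empty")
    sel = set(selection) if selection is not None else None
    coords = []
    for member in ens.members:
        sup = _compare.superpose(member, ref, selection=sel, atom_names=("CA",))
        coords.append(sup.transformed.coords(sel, ("CA",)))
    stack = np.array(coords)
    mean = stack.mean(axis=0)
    rmsds = np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2), axis=1))
    best = int(np.argmin(rmsds))
    return ens.members[best], best
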