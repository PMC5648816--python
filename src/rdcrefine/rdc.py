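"""Alignment-tensor mathematics for residual dipolar couplings.

An N-H residual dipolar coupling (RDC) reports on the orientation of the
amide bond vector relative to the molecular alignment frame:

    D(u) = u^T A u

where ``u`` is the unit N->H vector and ``A`` the Saupe alignment tensor, a
symmetric traceless 3x3 matrix expressed directly in Hz (the dipolar
prefactor is absorbed into the tensor, so no gyromagnetic constants appear
anywhere).  In its principal frame the same coupling reads

    D = Da * [ (3 cos^2 theta - 1) + (3/2) R sin^2 theta cos 2 phi ]

with axial magnitude Da = Szz / 2 and rhombicity R = (Sxx - Syy) / Szz,
0 <= R <= 2/3 under the eigenvalue ordering |Szz| >= |Syy| >= |Sxx|.

The tensor has five independent elements, so five or more couplings with
sufficiently diverse bond orientations determine it linearly; the fit here
is the standard singular-value-decomposition least squares.

The restraint energy used in refinement is a linear flat-bottom well: a
record contributes ``k * max(0, |dD| - tolerance)`` with dD the observed
minus back-calculated coupling.  The linear (not harmonic) form follows the
units of the force constant, kcal mol^-1 per Hz of violation; a harmonic
variant is available behind a switch for sensitivity checks.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    ParseError,
    ValidationError,
)
from .structure import BondVectorSet

__all__ = [
    "RDCStatus",
    "RDCRecord",
    "RDCSet",
    "SaupeTensor",
    "TensorParams",
    "FitReport",
    "RestraintResult",
    "back_calc",
    "fit_tensor_svd",
    "q_factor",
    "restraint_energy",
    "tensor_params",
    "read_rdc_tables",
    "write_rdc_tables",
    "DEFAULT_UNCERTAINTY_HZ",
]

#: Global per-record uncertainty applied when a table supplies none, in Hz.
DEFAULT_UNCERTAINTY_HZ = 3.0

#: Minimum number of active records required to determine the five tensor elements.
MIN_RECORDS = 5


class RDCStatus(str, Enum):
    ACTIVE = "active"
    PERSISTENT_VIOLATOR = "persistent_violator"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class RDCRecord:
    """One measured coupling: residue, value in Hz, medium, bookkeeping status."""

    seq_id: int
    observed: float
    medium: str
    uncertainty: float = DEFAULT_UNCERTAINTY_HZ
    atom_pair: str = "N-H"
    status: RDCStatus = RDCStatus.ACTIVE

    def __post_init__(self):
        if self.uncertainty <= 0:
            raise ValidationError(f"residue {self.seq_id}: uncertainty must be positive")
        if not self.medium:
            raise ValidationError(f"residue {self.seq_id}: medium label must be non-empty")


@dataclass
class RDCSet:
    """All records measured in one alignment medium."""

    medium: str
    records: list[RDCRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if rec.medium != self.medium:
                raise ValidationError(
                    f"record for residue {rec.seq_id} carries medium {rec.medium!r}, "
                    f"set is {self.medium!r}"
                )
            if rec.seq_id in seen:
                raise ValidationError(f"duplicate record for residue {rec.seq_id}")
            seen.add(rec.seq_id)

    def __len__(self):
        return len(self.records)

    @property
    def active(self) -> list[RDCRecord]:
        return [r for r in self.records if r.status == RDCStatus.ACTIVE]

    def by_status(self, status: RDCStatus) -> list[RDCRecord]:
        return [r for r in self.records if r.status == status]

    def with_status(self, seq_ids, status: RDCStatus) -> "RDCSet":
        """A copy with the given residues' records re-flagged."""
        wanted = set(seq_ids)
        return RDCSet(
            self.medium,
            [replace(r, status=status) if r.seq_id in wanted else r for r in self.records],
        )


# ---------------------------------------------------------------------------
# Saupe tensor
# ---------------------------------------------------------------------------

def _sym_traceless(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValidationError("Saupe tensor must be a 3x3 matrix")
    if not np.allclose(m, m.T, atol=1e-9 * max(1.0, np.abs(m).max())):
        raise ValidationError("Saupe tensor must be symmetric")
    scale = max(np.abs(m).max(), 1e-30)
    if abs(np.trace(m)) > 1e-10 * scale * 3:
        raise ValidationError("Saupe tensor must be traceless")
    m = 0.5 * (m + m.T)
    return m - np.eye(3) * (np.trace(m) / 3.0)


@dataclass(frozen=True)
class SaupeTensor:
    """Symmetric traceless 3x3 alignment tensor, in Hz."""

    components: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "components", _sym_traceless(self.components))

    @classmethod
    def from_independent(cls, v: np.ndarray) -> "SaupeTensor":
        """Build from the 5 independent elements (Axx, Ayy, Axy, Axz, Ayz)."""
        axx, ayy, axy, axz, ayz = np.asarray(v, float)
        return cls(np.array([
            [axx, axy, axz],
            [axy, ayy, ayz],
            [axz, ayz, -axx - ayy],
        ]))

    @classmethod
    def from_params(cls, da: float, r: float, euler_deg=(0.0, 0.0, 0.0)) -> "SaupeTensor":
        """Build from axial magnitude Da (Hz), rhombicity R and z-y-z Euler angles."""
        if not 0 <= r <= 2.0 / 3.0 + 1e-12:
            raise ValidationError(f"rhombicity {r} outside [0, 2/3]")
        szz = 2.0 * da
        sxx = -da + 1.5 * da * r
        syy = -da - 1.5 * da * r
        principal = np.diag([sxx, syy, szz])
        rot = Rotation.from_euler("ZYZ", euler_deg, degrees=True).as_matrix()
        return cls(rot @ principal @ rot.T)

    @property
    def independent(self) -> np.ndarray:
        m = self.components
        return np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]])


@dataclass(frozen=True)
class TensorParams:
    """Principal-frame description: Da (Hz), rhombicity, z-y-z Euler angles (deg)."""

    da: float
    r: float
    euler_deg: tuple[float, float, float]

    def __post_init__(self):
        if not 0 <= self.r <= 2.0 / 3.0 + 1e-9:
            raise ValidationError(f"rhombicity {self.r} outside [0, 2/3]")


def tensor_params(tensor: SaupeTensor) -> TensorParams:
    """Eigendecompose the tensor into (Da, R, Euler angles).

    Eigenvalues are ordered |Szz| >= |Syy| >= |Sxx|; the x/y labels of the
    two smaller-magnitude eigenvalues are chosen so that R >= 0.  On exact
    degeneracy the ordering falls back to a deterministic lexicographic
    comparison of the eigenvectors, with the sign convention that each
    eigenvector's largest-magnitude component is positive.
    """
    vals, vecs = np.linalg.eigh(tensor.components)
    order = sorted(
        range(3),
        key=lambda i: (-abs(vals[i]), tuple(-_canonical(vecs[:, i]))),
    )
    zz, b, c = order  # zz: largest magnitude
    # assign x (larger eigenvalue under R >= 0) vs y among the remaining two
    szz = vals[zz]
    # R = (Sxx - Syy)/Szz >= 0  =>  sign(Sxx - Syy) == sign(Szz)
    if (vals[b] - vals[c]) * szz >= 0:
        xx, yy = b, c
    else:
        xx, yy = c, b
    frame = np.column_stack([
        _canonical(vecs[:, xx]),
        _canonical(vecs[:, yy]),
        _canonical(vecs[:, zz]),
    ])
    if np.linalg.det(frame) < 0:
        frame[:, 1] = -frame[:, 1]
    da = szz / 2.0
    # R such that D = Da[(3cos^2 t - 1) + (3/2) R sin^2 t cos 2p]:
    # Sxx - Syy = 3 Da R = (3/2) Szz R
    r = (2.0 / 3.0) * (vals[xx] - vals[yy]) / szz if szz != 0 else 0.0
    r = min(max(r, 0.0), 2.0 / 3.0)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        euler = Rotation.from_matrix(frame).as_euler("ZYZ", degrees=True)
    return TensorParams(da, r, tuple(euler))


def _canonical(v: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v.copy()


# ---------------------------------------------------------------------------
# Back-calculation and fitting
# ---------------------------------------------------------------------------

def back_calc(tensor: SaupeTensor, vectors: BondVectorSet) -> list[tuple[int, float]]:
    """Predicted couplings D = u^T A u for every bond vector, in Hz."""
    if len(vectors) == 0:
        raise ValidationError("bond vector set is empty")
    a = tensor.components
    return [(seq_id, float(u @ a @ u)) for seq_id, u in vectors.entries]


def _design_row(u: np.ndarray) -> np.ndarray:
    # D = Axx(ux^2 - uz^2) + Ayy(uy^2 - uz^2) + 2 Axy ux uy + 2 Axz ux uz + 2 Ayz uy uz
    ux, uy, uz = u
    return np.array([
        ux * ux - uz * uz,
        uy * uy - uz * uz,
        2 * ux * uy,
        2 * ux * uz,
        2 * uy * uz,
    ])


@dataclass(frozen=True)
class FitReport:
    """Quality summary of a tensor fit."""

    q: float
    rms_hz: float
    n_used: int
    residuals: tuple[tuple[int, float], ...]  # (seq_id, observed - predicted)
    condition_number: float


def fit_tensor_svd(vectors: BondVectorSet, rdcs: RDCSet) -> tuple[SaupeTensor, FitReport]:
    """Least-squares Saupe tensor from couplings and bond vectors.

    Only records with status ``active`` and a matching bond vector enter the
    fit.  Raises :class:`InsufficientDataError` below five usable records and
    :class:`DegenerateGeometryError` when the bond orientations do not span
    the five tensor degrees of freedom (e.g. all vectors parallel).
    """
    vec_map = vectors.as_dict()
    usable = [r for r in rdcs.active if r.seq_id in vec_map]
    if len(usable) < MIN_RECORDS:
        raise InsufficientDataError(
            f"medium {rdcs.medium!r}: {len(usable)} usable records, need >= {MIN_RECORDS}"
        )
    design = np.array([_design_row(vec_map[r.seq_id]) for r in usable])
    obs = np.array([r.observed for r in usable])
    # SVD solve; rank check on the singular values of the design matrix
    u_svd, s_svd, vt_svd = np.linalg.svd(design, full_matrices=False)
    if s_svd[-1] <= 1e-8 * s_svd[0]:
        raise DegenerateGeometryError(
            f"medium {rdcs.medium!r}: bond orientations are rank-deficient for tensor fitting"
        )
    coeffs = vt_svd.T @ ((u_svd.T @ obs) / s_svd)
    tensor = SaupeTensor.from_independent(coeffs)
    pred = design @ coeffs
    resid = obs - pred
    rms = float(np.sqrt(np.mean(resid**2)))
    report = FitReport(
        q=q_factor(obs, pred),
        rms_hz=rms,
        n_used=len(usable),
        residuals=tuple((r.seq_id, float(d)) for r, d in zip(usable, resid)),
        condition_number=float(s_svd[0] / s_svd[-1]),
    )
    return tensor, report


def q_factor(observed, predicted) -> float:
    """Q = rms(D_obs - D_pred) / rms(D_obs); 0 is a perfect fit."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.size == 0 or observed.shape != predicted.shape:
        raise ValidationError("observed and predicted must be equal-length, non-empty")
    denom = np.sqrt(np.mean(observed**2))
    if denom == 0:
        raise ValidationError("Q-factor undefined: all observed couplings are zero")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)) / denom)


# ---------------------------------------------------------------------------
# Flat-bottom restraint energy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RestraintResult:
    """Energy of one medium's restraints at one set of predicted couplings.

    ``per_record`` rows are (seq_id, dD, violation, contribution); the
    subgradient dE/dD_pred per record is available for minimizers.
    """

    energy: float
    per_record: tuple[tuple[int, float, float, float], ...]
    grad_dpred: tuple[float, ...]
    gradient_available: bool = True


def restraint_energy(
    rdcs: RDCSet,
    predicted,
    k: float,
    tolerance: float = DEFAULT_UNCERTAINTY_HZ,
    form: str = "linear",
) -> RestraintResult:
    """Flat-bottom restraint energy over one medium's records.

    Records flagged ``excluded`` or ``persistent_violator`` contribute zero
    energy (they remain in the per-record report with zero contribution).

    ``predicted`` is either a sequence parallel to ``rdcs.records`` or a
    mapping seq_id -> predicted Hz covering every record.
    """
    if k < 0 or tolerance < 0:
        raise ValidationError("force constant and tolerance must be non-negative")
    if form not in ("linear", "harmonic"):
        raise ValidationError(f"unknown restraint form {form!r}")
    if isinstance(predicted, dict):
        try:
            pred = [predicted[r.seq_id] for r in rdcs.records]
        except KeyError as exc:
            raise ValidationError(f"no predicted coupling for residue {exc.args[0]}") from None
    else:
        pred = list(predicted)
        if len(pred) != len(rdcs.records):
            raise ValidationError(
                f"{len(pred)} predicted couplings for {len(rdcs.records)} records"
            )
    rows = []
    grads = []
    total = 0.0
    for rec, d_pred in zip(rdcs.records, pred):
        dd = rec.observed - float(d_pred)
        viol = max(0.0, abs(dd) - tolerance)
        if rec.status != RDCStatus.ACTIVE:
            rows.append((rec.seq_id, dd, viol, 0.0))
            grads.append(0.0)
            continue
        if form == "linear":
            contrib = k * viol
            g = -k * np.sign(dd) if viol > 0 else 0.0
        else:
            contrib = k * viol**2
            g = -2 * k * viol * np.sign(dd) if viol > 0 else 0.0
        rows.append((rec.seq_id, dd, viol, contrib))
        grads.append(float(g))
        total += contrib
    return RestraintResult(total, tuple(rows), tuple(grads))


# ---------------------------------------------------------------------------
# RDC table input/output
# ---------------------------------------------------------------------------

_COLUMNS = ["medium", "residue", "atom_pair", "observed_hz", "uncertainty_hz"]


def read_rdc_tables(text_or_path) -> list[RDCSet]:
    """Read a whitespace-delimited RDC table into per-medium sets.

    Columns: medium, residue seq_id, atom pair, observed (Hz) and an
    optional per-record uncertainty (Hz, default 3.0).  Lines starting with
    '#' are comments; a header row naming the columns is accepted.
    """
    if hasattr(text_or_path, "read"):
        buf = text_or_path
    else:
        text = str(text_or_path)
        if "\n" not in text and len(text) < 4096:
            try:
                with open(text) as fh:
                    text = fh.read()
            except OSError:
                pass
        buf = io.StringIO(text)
    try:
        df = pd.read_csv(buf, sep=r"\s+", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError("RDC table contains no records") from None
    if df.shape[1] not in (4, 5):
        raise ParseError(f"RDC table must have 4 or 5 columns, found {df.shape[1]}")
    # tolerate a header row naming the columns
    first = str(df.iloc[0, 0]).lower()
    if first in ("medium", "media"):
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise ParseError("RDC table contains no records")
    df.columns = _COLUMNS[: df.shape[1]]
    sets: dict[str, list[RDCRecord]] = {}
    for i, row in df.iterrows():
        try:
            seq_id = int(row["residue"])
            observed = float(row["observed_hz"])
            unc = (
                float(row["uncertainty_hz"])
                if "uncertainty_hz" in df.columns and pd.notna(row["uncertainty_hz"])
                else DEFAULT_UNCERTAINTY_HZ
            )
        except (TypeError, ValueError):
            raise ParseError(f"record {i + 1}: unparsable residue/coupling field") from None
        rec = RDCRecord(seq_id, observed, str(row["medium"]), unc, str(row["atom_pair"]))
        sets.setdefault(rec.medium, []).append(rec)
    return [RDCSet(m, recs) for m, recs in sets.items()]


def write_rdc_tables(sets, status: bool = False) -> str:
    """Serialize RDC sets back to the table format (optionally with status)."""
    lines = ["# medium residue atom_pair observed_hz uncertainty_hz" + (" status" if status else "")]
    for rdcset in sets:
        for r in rdcset.records:
            row = f"{r.medium}\t{r.seq_id}\t{r.atom_pair}\t{r.observed:.3f}\t{r.uncertainty:.3f}"
            if status:
                row += f"\t{r.status.value}"
            lines.append(row)
    return "\n".join(lines) + "\n"
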