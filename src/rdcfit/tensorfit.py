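"""Saupe alignment-tensor representation, back-calculation and SVD fitting.

The residual dipolar coupling of a unit internuclear vector b under
alignment described by a traceless symmetric order tensor S is

    D = D_max · bᵀ S b

with D_max the dipolar interaction constant (default 21.7 kHz for an N-H
pair at r = 1.04 Å; all validation statistics, angles and magnitude ratios
are invariant to this constant). With five independent tensor components the
relation is linear in S, so a set of measured couplings on known vectors is
fitted by linear least squares via singular-value decomposition.

In the tensor's principal frame the same coupling reads

    D = Da [ (3cos²θ − 1) + (3/2) R sin²θ cos 2φ ]

with axial magnitude Da = D_max·A_zz/2 and rhombicity
R = (2/3)(A_xx − A_yy)/A_zz ∈ [0, 2/3] under the eigenvalue ordering
|A_zz| ≥ |A_yy| ≥ |A_xx|.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .measurement import RdcDataset
from .structure import BondVectorSet

__all__ = [
    "DMAX_NH_HZ",
    "AlignmentTensor",
    "TensorParameters",
    "FitResult",
    "TensorFitError",
    "back_calculate",
    "design_matrix",
    "svd_fit",
    "q_factor",
    "tensor_parameters",
    "tensor_from_parameters",
    "equivalent_euler_frames",
    "saupe_from_components",
    "saupe_components",
]

#: Dipolar interaction constant |D_max| for an amide N-H pair, in Hz,
#: using an effective bond length r_NH = 1.04 Å.
DMAX_NH_HZ = 21_700.0

_COND_MAX = 1e8


class TensorFitError(ValueError):
    pass


def saupe_from_components(s: np.ndarray) -> np.ndarray:
    """Build the symmetric traceless 3×3 matrix from (S_xx, S_yy, S_xy, S_xz, S_yz)."""
    sxx, syy, sxy, sxz, syz = np.asarray(s, dtype=float)
    return np.array(
        [
            [sxx, sxy, sxz],
            [sxy, syy, syz],
            [sxz, syz, -sxx - syy],
        ]
    )


def saupe_components(saupe: np.ndarray) -> np.ndarray:
    """Inverse of :func:`saupe_from_components`."""
    m = np.asarray(saupe, dtype=float)
    return np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]])


@dataclass(frozen=True)
class AlignmentTensor:
    """Traceless symmetric order tensor plus the dipolar scale in Hz."""

    saupe: np.ndarray
    scale: float = DMAX_NH_HZ

    def __post_init__(self) -> None:
        m = np.asarray(self.saupe, dtype=float)
        if m.shape != (3, 3):
            raise TensorFitError("saupe must be 3x3")
        if not np.allclose(m, m.T, atol=1e-12):
            raise TensorFitError("saupe must be symmetric")
        if abs(np.trace(m)) > 1e-12 * max(1.0, np.abs(m).max()):
            raise TensorFitError("saupe must be traceless")
        object.__setattr__(self, "saupe", m)

    @classmethod
    def from_eigenvalues(
        cls,
        eigenvalues,
        rotation: Rotation | None = None,
        scale: float = DMAX_NH_HZ,
    ) -> "AlignmentTensor":
        """Tensor with given principal values, optionally rotated into the lab frame."""
        lam = np.asarray(eigenvalues, dtype=float)
        if abs(lam.sum()) > 1e-12 * max(1.0, np.abs(lam).max()):
            raise TensorFitError("eigenvalues must sum to zero")
        m = np.diag(lam)
        if rotation is not None:
            rm = rotation.as_matrix()
            m = rm @ m @ rm.T
        m = 0.5 * (m + m.T)
        m -= np.eye(3) * (np.trace(m) / 3.0)
        return cls(saupe=m, scale=scale)

    def rotated(self, rotation: Rotation) -> "AlignmentTensor":
        rm = rotation.as_matrix()
        m = rm @ self.saupe @ rm.T
        m = 0.5 * (m + m.T)
        m -= np.eye(3) * (np.trace(m) / 3.0)
        return AlignmentTensor(saupe=m, scale=self.scale)

    @property
    def magnitude(self) -> float:
        """Generalized degree of order, GDO = √(2/3 · Σ_kl S_kl²)."""
        return math.sqrt(2.0 / 3.0 * float(np.sum(self.saupe**2)))

    def is_zero(self, tol: float = 0.0) -> bool:
        return bool(np.abs(self.saupe).max() <= tol)


@dataclass(frozen=True)
class TensorParameters:
    """Principal-frame description: Da (Hz), rhombicity, orientation, magnitude."""

    Da: float
    R: float
    euler_zyz: tuple[float, float, float]  # degrees, PDB frame -> principal frame
    magnitude: float
    eigenvalues: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (A_xx, A_yy, A_zz)
    degenerate: bool = False


@dataclass
class FitResult:
    """Outcome of a least-squares tensor fit."""

    tensor: AlignmentTensor
    parameters: TensorParameters
    back_calculated: dict[int, float]
    Q: float
    rmsd: float
    n_used: int
    condition_number: float
    residues: list[int] = field(default_factory=list)
    observed: dict[int, float] = field(default_factory=dict)


def design_matrix(vectors: np.ndarray) -> np.ndarray:
    """Rows [x²−z², y²−z², 2xy, 2xz, 2yz] mapping the 5 free components to bᵀSb."""
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    return np.column_stack([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z])


def back_calculate(tensor: AlignmentTensor, vectors: BondVectorSet) -> dict[int, float]:
    """D = scale · bᵀ S b for every residue in the vector set."""
    residues = vectors.residues()
    arr = vectors.as_array(residues)
    d = tensor.scale * np.einsum("ij,jk,ik->i", arr, tensor.saupe, arr)
    return dict(zip(residues, d.tolist()))


def svd_fit(
    dataset: RdcDataset,
    vectors: BondVectorSet,
    scale: float = DMAX_NH_HZ,
    weighted: bool = False,
) -> FitResult:
    """Fit the alignment tensor to measured couplings by SVD least squares.

    Only included records with a matching bond vector enter the fit. The
    default is unweighted least squares; ``weighted=True`` applies 1/sigma_D²
    row weights.
    """
    obs = dataset.by_residue()
    residues = [r for r in vectors.residues() if r in obs]
    if len(residues) < 5:
        raise TensorFitError(
            f"need at least 5 usable records with bond vectors, have {len(residues)}"
        )
    arr = vectors.as_array(residues)
    d_obs = np.array([obs[r].D for r in residues])
    a = design_matrix(arr)
    b = d_obs / scale
    if weighted:
        w = np.array([1.0 / max(obs[r].sigma_D, 1e-12) for r in residues])
        a = a * w[:, None]
        b = b * w
    u, sv, vt = np.linalg.svd(a, full_matrices=False)
    if sv[0] == 0.0 or sv[-1] == 0.0 or sv[0] / sv[-1] > _COND_MAX:
        raise TensorFitError(
            "rank-deficient design matrix: the bond-vector geometry does not "
            "determine all 5 tensor components (e.g. parallel or coplanar vectors); "
            f"singular values {sv}"
        )
    cond = float(sv[0] / sv[-1])
    s5 = vt.T @ ((u.T @ b) / sv)
    tensor = AlignmentTensor(saupe=saupe_from_components(s5), scale=scale)
    calc = back_calculate(tensor, vectors.subset(residues))
    observed = {r: obs[r].D for r in residues}
    resid = np.array([calc[r] - observed[r] for r in residues])
    rmsd = float(np.sqrt(np.mean(resid**2)))
    q = q_factor(observed, calc)
    return FitResult(
        tensor=tensor,
        parameters=tensor_parameters(tensor),
        back_calculated=calc,
        Q=q,
        rmsd=rmsd,
        n_used=len(residues),
        condition_number=cond,
        residues=residues,
        observed=observed,
    )


def q_factor(
    observed: dict[int, float],
    calculated: dict[int, float],
    normalization: str = "rms",
    Da: float | None = None,
    R: float | None = None,
) -> float:
    """Q = rms(D_calc − D_obs) / rms(D_obs) over the shared residues.

    ``normalization="da"`` uses the alternative denominator
    √(2 Da² (4 + 3R²) / 5) computed from the supplied tensor parameters.
    """
    shared = sorted(set(observed) & set(calculated))
    if not shared:
        raise TensorFitError("no shared residues between observed and calculated")
    d_obs = np.array([observed[r] for r in shared])
    d_calc = np.array([calculated[r] for r in shared])
    num = math.sqrt(float(np.mean((d_calc - d_obs) ** 2)))
    if normalization == "rms":
        den = math.sqrt(float(np.mean(d_obs**2)))
        if den == 0.0:
            raise TensorFitError("rms of observed couplings is zero")
    elif normalization == "da":
        if Da is None or R is None:
            raise TensorFitError("Da and R required for the Da normalization")
        den = math.sqrt(2.0 * Da**2 * (4.0 + 3.0 * R**2) / 5.0)
        if den == 0.0:
            raise TensorFitError("zero Da in the Da normalization")
    else:
        raise TensorFitError(f"unknown normalization {normalization!r}")
    return num / den


def _principal_axes(saupe: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues/vectors ordered |A_xx| ≤ |A_yy| ≤ |A_zz|, right-handed frame."""
    lam, vec = np.linalg.eigh(saupe)
    order = np.argsort(np.abs(lam), kind="stable")
    lam = lam[order]
    vec = vec[:, order]
    if np.linalg.det(vec) < 0:
        vec[:, 0] = -vec[:, 0]
    return lam, vec


def tensor_parameters(tensor: AlignmentTensor) -> TensorParameters:
    """Extract Da, rhombicity, zyz Euler angles and the generalized magnitude.

    The orientation is the rotation taking PDB-frame coordinates into the
    principal-axis frame, reported as intrinsic zyz Euler angles in degrees
    with the canonical representative of the 4-fold tensor-frame degeneracy
    (β ∈ [0°, 90°] preferred, then lexicographically smallest angles).
    For a zero tensor the orientation is undefined and flagged degenerate.
    """
    if tensor.is_zero(tol=0.0):
        return TensorParameters(
            Da=0.0,
            R=0.0,
            euler_zyz=(0.0, 0.0, 0.0),
            magnitude=0.0,
            degenerate=True,
        )
    lam, vec = _principal_axes(tensor.saupe)
    a_xx, a_yy, a_zz = lam
    da = tensor.scale * a_zz / 2.0
    rhomb = (2.0 / 3.0) * (a_xx - a_yy) / a_zz
    # clip tiny numerical excursions outside [0, 2/3]
    rhomb = min(max(rhomb, 0.0), 2.0 / 3.0)
    degenerate = bool(np.isclose(a_xx, a_yy, rtol=1e-9, atol=1e-15))
    # rotation mapping lab coordinates into the principal frame: rows = axes
    rot = Rotation.from_matrix(vec.T)
    euler = _canonical_euler(rot)
    return TensorParameters(
        Da=float(da),
        R=float(rhomb),
        euler_zyz=euler,
        magnitude=tensor.magnitude,
        eigenvalues=(float(a_xx), float(a_yy), float(a_zz)),
        degenerate=degenerate,
    )


def tensor_from_parameters(
    Da: float,
    R: float,
    euler_zyz=(0.0, 0.0, 0.0),
    scale: float = DMAX_NH_HZ,
) -> AlignmentTensor:
    """Build a tensor from axial magnitude, rhombicity and orientation."""
    a_zz = 2.0 * Da / scale
    a_xx = -a_zz * (1.0 - 1.5 * R) / 2.0
    a_yy = -a_zz * (1.0 + 1.5 * R) / 2.0
    rot = Rotation.from_euler("ZYZ", euler_zyz, degrees=True)
    # principal frame -> lab: conjugate the diagonal by the inverse rotation
    return AlignmentTensor.from_eigenvalues(
        [a_xx, a_yy, a_zz], rotation=rot.inv(), scale=scale
    )


_FLIPS = (
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
)


def equivalent_euler_frames(rot: Rotation) -> list[tuple[float, float, float]]:
    """All four zyz Euler-angle triples describing the same tensor frame.

    A symmetric tensor cannot distinguish a principal frame from the same
    frame with two axes negated, so four proper rotations are equivalent.
    """
    out = []
    with warnings.catch_warnings():
        # gimbal lock at b = 0 or 180 is expected for axial tensors; the
        # convention of folding the spare angle into alpha is fine here
        warnings.simplefilter("ignore", UserWarning)
        for flip in _FLIPS:
            r = Rotation.from_matrix(flip @ rot.as_matrix())
            a, b, g = r.as_euler("ZYZ", degrees=True)  # scipy: b in [0, 180]
            out.append((a % 360.0, float(b), g % 360.0))
    return out


def _canonical_euler(rot: Rotation) -> tuple[float, float, float]:
    frames = equivalent_euler_frames(rot)
    eligible = [f for f in frames if f[1] <= 90.0 + 1e-9] or frames
    best = min(eligible, key=lambda f: (round(f[1], 9), round(f[0], 9), round(f[2], 9)))
    return (float(best[0]), float(best[1]), float(best[2]))
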