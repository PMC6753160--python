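"""Alignment-tensor comparison: irreducible 5-vectors, 5D angles, axis projections.

Two alignment tensors are compared as points in the 5-dimensional space of
traceless symmetric matrices. The 5-vector basis is scaled so that the
Euclidean inner product of two 5-vectors equals the Frobenius inner product
of the corresponding matrices; the 5D angle between tensors is then the
matrix-level angle cos θ = ⟨S₁,S₂⟩_F / (‖S₁‖_F ‖S₂‖_F), independent of any
component convention. Principal axes are visualised on the sphere with the
equal-area sinusoidal (Sanson-Flamsteed) projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tensorfit import AlignmentTensor, TensorFitError, _principal_axes

__all__ = [
    "Irreducible5Vector",
    "AxisProjection",
    "to_5vector",
    "from_5vector",
    "five_d_angle",
    "project_axes",
    "project_point",
    "plot_axes",
]

_SQRT32 = math.sqrt(1.5)
_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class Irreducible5Vector:
    """(√(3/2)·s_zz, (s_xx−s_yy)/√2, √2·s_xy, √2·s_xz, √2·s_yz).

    With this scaling ‖v‖² = Σ_kl s_kl² (the Frobenius norm squared), so the
    norm is invariant under rotation of the tensor and inner products of
    5-vectors equal Frobenius inner products of the matrices.
    """

    components: tuple[float, float, float, float, float]

    @property
    def norm(self) -> float:
        return math.sqrt(sum(c * c for c in self.components))

    def as_array(self) -> np.ndarray:
        return np.array(self.components)


def to_5vector(tensor: AlignmentTensor) -> Irreducible5Vector:
    s = tensor.saupe
    return Irreducible5Vector(
        components=(
            _SQRT32 * float(s[2, 2]),
            _INV_SQRT2 * float(s[0, 0] - s[1, 1]),
            _SQRT2 * float(s[0, 1]),
            _SQRT2 * float(s[0, 2]),
            _SQRT2 * float(s[1, 2]),
        )
    )


def from_5vector(
    v: Irreducible5Vector, scale: float | None = None
) -> AlignmentTensor:
    """Invert :func:`to_5vector`."""
    c0, c1, c2, c3, c4 = v.components
    szz = c0 / _SQRT32
    diff = c1 * _SQRT2  # s_xx − s_yy
    sxx = (-szz + diff) / 2.0
    syy = (-szz - diff) / 2.0
    m = np.array(
        [
            [sxx, c2 / _SQRT2, c3 / _SQRT2],
            [c2 / _SQRT2, syy, c4 / _SQRT2],
            [c3 / _SQRT2, c4 / _SQRT2, szz],
        ]
    )
    kwargs = {} if scale is None else {"scale": scale}
    return AlignmentTensor(saupe=m, **kwargs)


def five_d_angle(t1: AlignmentTensor, t2: AlignmentTensor) -> float:
    """Angle in degrees between two tensors in their 5-vector representation.

    Equals arccos of the normalized Frobenius inner product of the Saupe
    matrices; magnitude differences drop out of the normalisation.
    """
    v1 = to_5vector(t1).as_array()
    v2 = to_5vector(t2).as_array()
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise TensorFitError("5D angle undefined for a zero tensor")
    c = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


@dataclass(frozen=True)
class AxisProjection:
    """Sanson-Flamsteed coordinates of the three principal axes.

    Each axis (an unsigned direction) is reduced to the hemisphere
    representative with z ≥ 0 (ties: y ≥ 0, then x ≥ 0), expressed as
    longitude λ ∈ (−180°, 180°] and latitude φ ∈ [−90°, 90°], and projected
    to (x, y) = (λ·cos φ, φ).
    """

    axes: dict[str, tuple[float, float, float]]  # axis -> unit vector
    lonlat: dict[str, tuple[float, float]]  # axis -> (λ, φ) degrees
    projected: dict[str, tuple[float, float]]  # axis -> (x, y)
    degenerate: bool = False


def _antipode_representative(v: np.ndarray) -> np.ndarray:
    for i in (2, 1, 0):
        if abs(v[i]) > 1e-12:
            return v if v[i] > 0 else -v
    return v


def project_point(v) -> tuple[float, float, tuple[float, float]]:
    """(λ, φ) in degrees and sinusoidal (x, y) for one unsigned axis."""
    v = _antipode_representative(np.asarray(v, dtype=float))
    v = v / np.linalg.norm(v)
    phi = math.degrees(math.asin(max(-1.0, min(1.0, float(v[2])))))
    lam = math.degrees(math.atan2(float(v[1]), float(v[0])))
    if lam <= -180.0:
        lam += 360.0
    return lam, phi, (lam * math.cos(math.radians(phi)), phi)


def project_axes(tensor: AlignmentTensor) -> AxisProjection:
    """Project the three principal axes of a tensor onto the sinusoidal map.

    An axially symmetric tensor (degenerate xx/yy eigenvalues) is flagged:
    its xx and yy axes are an arbitrary basis of the degenerate plane.
    """
    lam_eig, vec = _principal_axes(tensor.saupe)
    degenerate = bool(
        np.isclose(lam_eig[0], lam_eig[1], rtol=1e-9, atol=1e-15)
        or np.isclose(lam_eig[1], lam_eig[2], rtol=1e-9, atol=1e-15)
    )
    axes: dict[str, tuple[float, float, float]] = {}
    lonlat: dict[str, tuple[float, float]] = {}
    projected: dict[str, tuple[float, float]] = {}
    for name, col in zip(("xx", "yy", "zz"), (0, 1, 2)):
        v = _antipode_representative(vec[:, col].copy())
        lon, lat, xy = project_point(v)
        axes[name] = tuple(float(c) for c in v)
        lonlat[name] = (lon, lat)
        projected[name] = xy
    return AxisProjection(
        axes=axes, lonlat=lonlat, projected=projected, degenerate=degenerate
    )


def plot_axes(projections, labels=None, ax=None):
    """Scatter principal-axis projections on a sinusoidal-map outline.

    ``projections`` is one :class:`AxisProjection` or a sequence of them;
    returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    if isinstance(projections, AxisProjection):
        projections = [projections]
    if labels is None:
        labels = [f"tensor {i + 1}" for i in range(len(projections))]
    # graticule
    lat = np.linspace(-90, 90, 181)
    for lon in range(-180, 181, 30):
        ax.plot(lon * np.cos(np.radians(lat)), lat, lw=0.3, color="0.8", zorder=0)
    for latline in range(-60, 61, 30):
        lon = np.linspace(-180, 180, 361)
        ax.plot(lon * math.cos(math.radians(latline)), [latline] * len(lon),
                lw=0.3, color="0.8", zorder=0)
    markers = {"xx": "s", "yy": "^", "zz": "o"}
    for proj, label in zip(projections, labels):
        for axis, (x, y) in proj.projected.items():
            ax.scatter([x], [y], marker=markers[axis], label=f"{label} A{axis}")
    ax.set_xlabel("longitude · cos(latitude) (deg)")
    ax.set_ylabel("latitude (deg)")
    ax.legend(fontsize=7, loc="upper right")
    return ax
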