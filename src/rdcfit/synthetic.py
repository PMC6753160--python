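"""Synthetic fixtures with known ground truth: structures, RDC datasets, peak lists.

Everything the analysis pipeline consumes can be generated here from a known
alignment tensor, so parameter recovery is testable end to end without any
external files. The defaults emulate the data regime of weakly aligned
proteins measured on large complexes: couplings spanning roughly ±30 Hz,
RDC uncertainties near 1.8 Hz RMS, ¹⁵N linewidths of 11 ± 2 Hz, and a
one-bond ¹J_NH of −93 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .measurement import Peak, PeakList, RdcDataset, RdcRecord
from .structure import Atom, BondVectorSet, SseDefinition, SseElement, Structure
from .tensorfit import AlignmentTensor, back_calculate, tensor_from_parameters
from . import structure as _structure

__all__ = [
    "FixtureSpec",
    "SyntheticError",
    "make_structure",
    "simulate_rdcs",
    "simulate_peak_lists",
    "default_tensor",
]

J_NH_DEFAULT = -93.0  # Hz, one-bond amide coupling
SIGMA_FLOOR = 0.1  # Hz, nominal uncertainty attached to noiseless data

# backbone geometry (Å, degrees) used by the ideal builders
_B_CN, _B_NCA, _B_CAC, _B_CO, _B_NH = 1.329, 1.458, 1.525, 1.231, 1.02
_A_CACN, _A_CNCA, _A_NCAC, _A_CACO = 116.2, 121.7, 111.2, 120.8
_HELIX_PHI, _HELIX_PSI = -57.0, -47.0
_STRAND_PHI, _STRAND_PSI = -120.0, 130.0


class SyntheticError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Ground-truth recipe for one synthetic dataset."""

    kind: str = "two_helix"  # ideal_helix | two_helix | strand
    n_residues: int = 12  # per element
    tensor: AlignmentTensor | None = None
    noise: float = 0.0  # Hz; also switches peak-position noise on
    J_NH: float = J_NH_DEFAULT
    SN: float | dict[int, float] = 50.0
    LW_mean: float = 11.0  # Hz
    LW_sd: float = 2.0  # Hz, truncated at zero
    trosy_sign: int = 1  # TROSY line displaced by +(J+D)/2 when +1
    seed: int = 0
    chain: str = "A"
    linker_gap: int = 4  # unbuilt residues between the two helices

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise SyntheticError("need at least 5 residues per fitted unit")
        if self.tensor is None:
            self.tensor = default_tensor()


def default_tensor(Da: float = -15.0, R: float = 0.3,
                   euler_zyz=(41.0, 36.0, 186.0)) -> AlignmentTensor:
    """A generic tensor whose couplings span roughly ±20–30 Hz on the toy helices."""
    return tensor_from_parameters(Da=Da, R=R, euler_zyz=euler_zyz)


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension placement of atom d bonded to c, given a-b-c."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_segment(n_residues: int, phi: float, psi: float,
                   start_resnum: int, chain: str) -> list[Atom]:
    """Ideal backbone (N, CA, C, O, H) with fixed dihedrals; ω = 180°.

    The first residue carries no amide proton (it has no preceding carbonyl
    to define the peptide plane).
    """
    coords: dict[tuple[int, str], np.ndarray] = {}
    r0 = start_resnum
    coords[(r0, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(r0, "CA")] = np.array([_B_NCA, 0.0, 0.0])
    ang = np.radians(_A_NCAC)
    coords[(r0, "C")] = coords[(r0, "CA")] + _B_CAC * np.array(
        [-np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(1, n_residues):
        r, p = r0 + i, r0 + i - 1
        coords[(r, "N")] = _place_atom(
            coords[(p, "N")], coords[(p, "CA")], coords[(p, "C")], _B_CN, _A_CACN, psi
        )
        coords[(r, "CA")] = _place_atom(
            coords[(p, "CA")], coords[(p, "C")], coords[(r, "N")],
            _B_NCA, _A_CNCA, 180.0,
        )
        coords[(r, "C")] = _place_atom(
            coords[(p, "C")], coords[(r, "N")], coords[(r, "CA")],
            _B_CAC, _A_NCAC, phi,
        )
        # carbonyl O of the previous residue, anti to the new N
        coords[(p, "O")] = _place_atom(
            coords[(p, "N")], coords[(p, "CA")], coords[(p, "C")],
            _B_CO, _A_CACO, psi + 180.0,
        )
        # amide H: in-plane, opposite the bisector of the two N bonds
        u1 = coords[(p, "C")] - coords[(r, "N")]
        u2 = coords[(r, "CA")] - coords[(r, "N")]
        h_dir = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
        h_dir /= np.linalg.norm(h_dir)
        coords[(r, "H")] = coords[(r, "N")] + _B_NH * h_dir
    rl = r0 + n_residues - 1
    coords[(rl, "O")] = _place_atom(
        coords[(rl, "N")], coords[(rl, "CA")], coords[(rl, "C")],
        _B_CO, _A_CACO, psi + 180.0,
    )
    atoms = []
    for (resnum, name), xyz in sorted(coords.items()):
        atoms.append(Atom(chain, resnum, "ALA", name, *map(float, xyz)))
    return atoms


def _transform_atoms(atoms: list[Atom], rotation: Rotation,
                     translation: np.ndarray) -> list[Atom]:
    rm = rotation.as_matrix()
    out = []
    for a in atoms:
        xyz = rm @ a.pos + translation
        out.append(Atom(a.chain, a.resnum, a.resname, a.name, *map(float, xyz)))
    return out


def make_structure(spec: FixtureSpec) -> tuple[Structure, SseDefinition]:
    """Build a toy structure with its secondary-structure definition.

    ``two_helix`` places a second ideal helix in a generic orientation
    (rotated well away from the first) so the combined N-H vector set spans
    all five tensor degrees of freedom.
    """
    n = spec.n_residues
    if spec.kind == "ideal_helix":
        atoms = _build_segment(n, _HELIX_PHI, _HELIX_PSI, 1, spec.chain)
        sses = SseDefinition([SseElement("H1", 1, n, "helix")])
    elif spec.kind == "strand":
        atoms = _build_segment(n, _STRAND_PHI, _STRAND_PSI, 1, spec.chain)
        sses = SseDefinition([SseElement("S1", 1, n, "strand")])
    elif spec.kind == "two_helix":
        a1 = _build_segment(n, _HELIX_PHI, _HELIX_PSI, 1, spec.chain)
        start2 = n + spec.linker_gap + 1
        a2 = _build_segment(n, _HELIX_PHI, _HELIX_PSI, start2, spec.chain)
        rot = Rotation.from_euler("zyx", [40.0, 75.0, 20.0], degrees=True)
        a2 = _transform_atoms(a2, rot, np.array([25.0, 0.0, 0.0]))
        atoms = a1 + a2
        sses = SseDefinition(
            [
                SseElement("H1", 1, n, "helix"),
                SseElement("H2", start2, start2 + n - 1, "helix"),
            ]
        )
    else:
        raise SyntheticError(f"unsupported structure kind {spec.kind!r}")
    return Structure(atoms=atoms, model_id=1), sses


def simulate_rdcs(
    structure: Structure,
    tensor: AlignmentTensor,
    noise: float = 0.0,
    seed: int = 0,
    chain: str = "A",
) -> RdcDataset:
    """Couplings back-calculated from the structure plus Gaussian noise.

    ``sigma_D`` is set to ``noise``, with a floor of 0.1 Hz when noiseless so
    downstream weighting and soft wells stay well defined.
    """
    vectors = _structure.extract_nh_vectors(structure, chain)
    clean = back_calculate(tensor, vectors)
    rng = np.random.default_rng(seed)
    sigma = noise if noise > 0 else SIGMA_FLOOR
    records = []
    for res in sorted(clean):
        d = clean[res] + (rng.normal(0.0, noise) if noise > 0 else 0.0)
        records.append(RdcRecord(residue=res, D=float(d), sigma_D=float(sigma)))
    return RdcDataset(records=records)


def _draw_lw(rng: np.random.Generator, spec: FixtureSpec) -> float:
    for _ in range(100):
        lw = rng.normal(spec.LW_mean, spec.LW_sd)
        if lw > 0:
            return float(lw)
    return spec.LW_mean


def _sn_for(spec: FixtureSpec, residue: int) -> float:
    if isinstance(spec.SN, dict):
        return float(spec.SN[residue])
    return float(spec.SN)


def simulate_peak_lists(
    structure: Structure,
    tensor: AlignmentTensor,
    spec: FixtureSpec,
    method: str = "hsqc_trosy",
) -> dict[tuple[str, str], PeakList]:
    """Peak-list quadruple consistent with a chosen ¹J_NH and tensor.

    For ``hsqc_trosy`` the keys are (hsqc|trosy, iso|aniso): the decoupled
    HSQC sits at the multiplet centre and the TROSY line is displaced by
    ``trosy_sign·(J+D)/2``. For ``ipap`` the keys are (upfield|downfield,
    iso|aniso) with components at centre ∓ (J+D)/2 so the signed splitting
    is J+D. With ``spec.noise > 0`` every position receives Gaussian error
    of its own sigma_v = LW/(2·SN); at zero noise positions are exact and the
    measurement pipeline returns the generating couplings identically.
    """
    vectors = _structure.extract_nh_vectors(structure, spec.chain)
    clean = back_calculate(tensor, vectors)
    rng = np.random.default_rng(spec.seed)
    centres = {res: float(rng.uniform(-500.0, 500.0)) for res in sorted(clean)}
    lw = {res: _draw_lw(rng, spec) for res in sorted(clean)}
    if method == "hsqc_trosy":
        names = ("hsqc", "trosy")
    elif method == "ipap":
        names = ("upfield", "downfield")
    else:
        raise SyntheticError(f"unsupported method {method!r}")
    lists: dict[tuple[str, str], PeakList] = {}
    for cond in ("iso", "aniso"):
        peaks_a, peaks_b = [], []
        for res in sorted(clean):
            d = clean[res] if cond == "aniso" else 0.0
            half = (spec.J_NH + d) / 2.0
            if method == "hsqc_trosy":
                pos_a = centres[res]
                pos_b = centres[res] + spec.trosy_sign * half
            else:
                pos_a = centres[res] - half
                pos_b = centres[res] + half
            sn = _sn_for(spec, res)
            if spec.noise > 0:
                sv = lw[res] / (2.0 * sn)
                pos_a += rng.normal(0.0, sv)
                pos_b += rng.normal(0.0, sv)
            peaks_a.append(Peak(res, float(pos_a), sn, lw[res]))
            peaks_b.append(Peak(res, float(pos_b), sn, lw[res]))
        lists[(names[0], cond)] = PeakList(peaks_a)
        lists[(names[1], cond)] = PeakList(peaks_b)
    return lists
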