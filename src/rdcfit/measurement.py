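"""RDC measurement from peak positions and dataset-quality filtering.

A coupling is the difference between the anisotropic and isotropic ¹⁵N
splittings. Peak-position uncertainty follows sigma_v = LW / (2 SN) from the
signal-to-noise ratio and linewidth; uncertainties propagate in quadrature
through each splitting arithmetic. Quality filters exclude residues with
local flexibility (order parameter S² < 0.85), conformational exchange,
spectral overlap, or sigma_D > 5 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import pandas as pd

__all__ = [
    "Condition",
    "Method",
    "ExclusionReason",
    "Peak",
    "PeakList",
    "SplittingMeasurement",
    "RdcRecord",
    "RdcDataset",
    "MeasurementError",
    "peak_position_uncertainty",
    "splitting_from_hsqc_trosy",
    "splitting_from_ipap",
    "rdc_from_splittings",
    "filter_rdcs",
    "rdcs_from_peak_lists",
    "read_peak_list",
    "write_peak_list",
    "read_rdc_table",
    "write_rdc_table",
    "read_pales_table",
    "S2_MIN_DEFAULT",
    "SIGMA_MAX_DEFAULT",
]

#: Exclusion thresholds: local order parameter below this, or sigma_D above
#: 5 Hz, disqualifies a residue from tensor analysis.
S2_MIN_DEFAULT = 0.85
SIGMA_MAX_DEFAULT = 5.0  # Hz


class MeasurementError(ValueError):
    pass


class Condition(str, Enum):
    ISOTROPIC = "isotropic"
    ANISOTROPIC = "anisotropic"


class Method(str, Enum):
    HSQC_TROSY = "hsqc_trosy"
    IPAP = "ipap"


class ExclusionReason(str, Enum):
    NONE = "none"
    FLEXIBLE = "flexible"
    EXCHANGE = "exchange"
    OVERLAP = "overlap"
    SIGMA_TOO_LARGE = "sigma_too_large"


@dataclass(frozen=True)
class Peak:
    """One ¹⁵N-dimension resonance: position (Hz), signal-to-noise, linewidth (Hz)."""

    residue: int
    nu15N: float
    SN: float
    LW: float
    overlapped: bool = False

    def __post_init__(self) -> None:
        if self.SN <= 0 or self.LW <= 0:
            raise MeasurementError(
                f"residue {self.residue}: SN and LW must be positive"
            )

    @property
    def sigma_v(self) -> float:
        return peak_position_uncertainty(self.LW, self.SN)


@dataclass
class PeakList:
    peaks: list[Peak]

    def by_residue(self) -> dict[int, Peak]:
        return {p.residue: p for p in self.peaks}

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class SplittingMeasurement:
    residue: int
    splitting: float  # Hz
    sigma: float  # Hz
    condition: Condition
    method: Method
    overlapped: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise MeasurementError("sigma must be non-negative")


@dataclass(frozen=True)
class RdcRecord:
    residue: int
    D: float  # Hz
    sigma_D: float  # Hz
    excluded: bool = False
    reason: ExclusionReason = ExclusionReason.NONE
    overlapped: bool = False

    def __post_init__(self) -> None:
        if self.sigma_D < 0:
            raise MeasurementError("sigma_D must be non-negative")
        if self.excluded != (self.reason is not ExclusionReason.NONE):
            raise MeasurementError("excluded flag inconsistent with reason")


@dataclass
class RdcDataset:
    """A set of per-residue couplings with uncertainties and QC flags."""

    records: list[RdcRecord] = field(default_factory=list)

    @property
    def included(self) -> list[RdcRecord]:
        return [r for r in self.records if not r.excluded]

    @property
    def rms_sigma(self) -> float:
        """RMS uncertainty ⟨sigma_D²⟩^½ over included records."""
        inc = self.included
        if not inc:
            return float("nan")
        return math.sqrt(sum(r.sigma_D**2 for r in inc) / len(inc))

    def by_residue(self, include_excluded: bool = False) -> dict[int, RdcRecord]:
        return {
            r.residue: r for r in self.records if include_excluded or not r.excluded
        }

    def observed(self) -> dict[int, float]:
        return {r.residue: r.D for r in self.included}

    def sigmas(self) -> dict[int, float]:
        return {r.residue: r.sigma_D for r in self.included}

    def __len__(self) -> int:
        return len(self.records)


def peak_position_uncertainty(LW: float, SN: float) -> float:
    """sigma_v = LW / (2 SN): positional uncertainty of a peak in Hz."""
    if LW <= 0 or SN <= 0:
        raise MeasurementError("LW and SN must be positive")
    return LW / (2.0 * SN)


def splitting_from_hsqc_trosy(
    peak_hsqc: Peak, peak_trosy: Peak, condition: Condition
) -> SplittingMeasurement:
    """Splitting from the decoupled-HSQC centre and one TROSY multiplet component.

    The TROSY line sits half a splitting from the multiplet centre, so the
    full splitting is twice the HSQC→TROSY displacement and the positional
    uncertainties enter with that same factor of two.
    """
    if peak_hsqc.residue != peak_trosy.residue:
        raise MeasurementError(
            f"residue mismatch: {peak_hsqc.residue} vs {peak_trosy.residue}"
        )
    splitting = 2.0 * (peak_trosy.nu15N - peak_hsqc.nu15N)
    sigma = 2.0 * math.hypot(peak_hsqc.sigma_v, peak_trosy.sigma_v)
    return SplittingMeasurement(
        residue=peak_hsqc.residue,
        splitting=splitting,
        sigma=sigma,
        condition=Condition(condition),
        method=Method.HSQC_TROSY,
        overlapped=peak_hsqc.overlapped or peak_trosy.overlapped,
    )


def splitting_from_ipap(
    peak_upfield: Peak, peak_downfield: Peak, condition: Condition
) -> SplittingMeasurement:
    """Splitting as the separation of the IPAP doublet components."""
    if peak_upfield.residue != peak_downfield.residue:
        raise MeasurementError(
            f"residue mismatch: {peak_upfield.residue} vs {peak_downfield.residue}"
        )
    splitting = peak_downfield.nu15N - peak_upfield.nu15N
    sigma = math.hypot(peak_upfield.sigma_v, peak_downfield.sigma_v)
    return SplittingMeasurement(
        residue=peak_upfield.residue,
        splitting=splitting,
        sigma=sigma,
        condition=Condition(condition),
        method=Method.IPAP,
        overlapped=peak_upfield.overlapped or peak_downfield.overlapped,
    )


def rdc_from_splittings(
    iso: SplittingMeasurement, aniso: SplittingMeasurement
) -> RdcRecord:
    """D = anisotropic splitting − isotropic splitting, uncertainties in quadrature."""
    if iso.residue != aniso.residue:
        raise MeasurementError(f"residue mismatch: {iso.residue} vs {aniso.residue}")
    if iso.method != aniso.method:
        raise MeasurementError(f"method mismatch: {iso.method} vs {aniso.method}")
    if iso.condition is not Condition.ISOTROPIC:
        raise MeasurementError("first argument must be the isotropic splitting")
    if aniso.condition is not Condition.ANISOTROPIC:
        raise MeasurementError("second argument must be the anisotropic splitting")
    return RdcRecord(
        residue=iso.residue,
        D=aniso.splitting - iso.splitting,
        sigma_D=math.hypot(iso.sigma, aniso.sigma),
        overlapped=iso.overlapped or aniso.overlapped,
    )


def filter_rdcs(
    dataset: RdcDataset,
    s2_by_residue: dict[int, float] | None = None,
    exchange_residues: set[int] | None = None,
    s2_min: float = S2_MIN_DEFAULT,
    sigma_max: float = SIGMA_MAX_DEFAULT,
) -> RdcDataset:
    """Apply the dataset-quality exclusion rules.

    A record is excluded, with the first matching reason in the priority
    order flexible > exchange > overlap > sigma_too_large, if its residue has
    S² < ``s2_min``, is in ``exchange_residues``, is flagged overlapped, or
    has sigma_D > ``sigma_max``. Both thresholds are strict inequalities, so
    records exactly at S² = 0.85 or sigma_D = 5 Hz survive. Idempotent:
    previously assigned reasons are recomputed from scratch.
    """
    s2_by_residue = s2_by_residue or {}
    exchange_residues = exchange_residues or set()
    out: list[RdcRecord] = []
    for rec in dataset.records:
        s2 = s2_by_residue.get(rec.residue)
        reason = ExclusionReason.NONE
        if s2 is not None and s2 < s2_min:
            reason = ExclusionReason.FLEXIBLE
        elif rec.residue in exchange_residues:
            reason = ExclusionReason.EXCHANGE
        elif rec.overlapped:
            reason = ExclusionReason.OVERLAP
        elif rec.sigma_D > sigma_max:
            reason = ExclusionReason.SIGMA_TOO_LARGE
        out.append(
            replace(rec, excluded=reason is not ExclusionReason.NONE, reason=reason)
        )
    return RdcDataset(records=out)


def rdcs_from_peak_lists(
    iso_a: PeakList,
    iso_b: PeakList,
    aniso_a: PeakList,
    aniso_b: PeakList,
    method: Method = Method.HSQC_TROSY,
) -> RdcDataset:
    """Pair up peak lists into a coupling table.

    For ``hsqc_trosy`` the (a, b) pair is (HSQC, TROSY); for ``ipap`` it is
    (upfield, downfield). Residues present in all four lists are measured.
    """
    method = Method(method)
    split = (
        splitting_from_hsqc_trosy if method is Method.HSQC_TROSY else splitting_from_ipap
    )
    ia, ib = iso_a.by_residue(), iso_b.by_residue()
    aa, ab = aniso_a.by_residue(), aniso_b.by_residue()
    residues = sorted(set(ia) & set(ib) & set(aa) & set(ab))
    records = []
    for res in residues:
        iso = split(ia[res], ib[res], Condition.ISOTROPIC)
        aniso = split(aa[res], ab[res], Condition.ANISOTROPIC)
        records.append(rdc_from_splittings(iso, aniso))
    return RdcDataset(records=records)


# ---------------------------------------------------------------------------
# text I/O


def read_peak_list(path, spectrometer_freq_mhz: float | None = None) -> PeakList:
    """Read a whitespace-delimited peak list.

    Columns: ``residue nu15N SN LW_Hz overlapped``. Positions are in Hz
    unless ``spectrometer_freq_mhz`` (the ¹⁵N Larmor frequency) is given, in
    which case they are read as ppm and converted.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        names=["residue", "nu15N", "SN", "LW", "overlapped"],
        header=None,
    )
    factor = spectrometer_freq_mhz if spectrometer_freq_mhz else 1.0
    peaks = [
        Peak(
            residue=int(row.residue),
            nu15N=float(row.nu15N) * factor,
            SN=float(row.SN),
            LW=float(row.LW),
            overlapped=bool(int(row.overlapped)),
        )
        for row in df.itertuples()
    ]
    return PeakList(peaks=peaks)


def write_peak_list(peaks: PeakList, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("# residue nu15N_Hz SN LW_Hz overlapped\n")
        if comment:
            fh.write(f"# {comment}\n")
        for p in peaks.peaks:
            fh.write(
                f"{p.residue}\t{p.nu15N:.6f}\t{p.SN:.3f}\t{p.LW:.4f}\t"
                f"{int(p.overlapped)}\n"
            )


def read_rdc_table(path) -> RdcDataset:
    """Read a tab-delimited RDC table: ``residue D_Hz sigma_Hz excluded reason``."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        names=["residue", "D", "sigma", "excluded", "reason"],
        header=None,
    )
    records = [
        RdcRecord(
            residue=int(row.residue),
            D=float(row.D),
            sigma_D=float(row.sigma),
            excluded=bool(int(row.excluded)),
            reason=ExclusionReason(str(row.reason)),
        )
        for row in df.itertuples()
    ]
    return RdcDataset(records=records)


def write_rdc_table(dataset: RdcDataset, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("# residue D_Hz sigma_Hz excluded reason\n")
        if comment:
            fh.write(f"# {comment}\n")
        for r in dataset.records:
            fh.write(
                f"{r.residue}\t{r.D:.6f}\t{r.sigma_D:.6f}\t{int(r.excluded)}\t"
                f"{r.reason.value}\n"
            )


def read_pales_table(path) -> RdcDataset:
    """Read a PALES-style DC table (VARS/FORMAT header, one row per coupling).

    Expected VARS include RESID_I, RESID_J, D, DD and optionally W; the row
    is keyed on the amide nitrogen residue number (RESID_I) and W = 0 marks
    an excluded record (reason left as overlap, the closest QC analogue).
    """
    vars_line = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("REMARK", "#", "DATA", "FORMAT")):
                continue
            if line.startswith("VARS"):
                vars_line = line.split()[1:]
                continue
            if vars_line is None:
                continue
            rows.append(line.split())
    if vars_line is None:
        raise MeasurementError(f"no VARS header found in {path}")
    cols = {name: i for i, name in enumerate(vars_line)}
    for needed in ("RESID_I", "D", "DD"):
        if needed not in cols:
            raise MeasurementError(f"missing column {needed} in {path}")
    records = []
    for row in rows:
        w = float(row[cols["W"]]) if "W" in cols else 1.0
        excluded = w == 0.0
        records.append(
            RdcRecord(
                residue=int(row[cols["RESID_I"]]),
                D=float(row[cols["D"]]),
                sigma_D=float(row[cols["DD"]]),
                excluded=excluded,
                reason=ExclusionReason.OVERLAP if excluded else ExclusionReason.NONE,
            )
        )
    return RdcDataset(records=records)
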