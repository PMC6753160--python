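"""Model/Results interface for alignment-tensor fitting.

:class:`RdcTensorModel` binds a measured RDC dataset to the bond vectors of
a structure; :meth:`RdcTensorModel.fit` performs the SVD least-squares fit
and returns an :class:`RdcTensorResults` carrying the tensor, its
principal-frame parameters, validation statistics (Q, rmsd), and methods for
Monte-Carlo uncertainty, tensor comparison and axis projection.

    >>> model = RdcTensorModel(dataset, vectors)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> mc = res.monte_carlo(n_iterations=1000, seed=1)
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .compare import AxisProjection, five_d_angle, project_axes, to_5vector
from .measurement import RdcDataset, filter_rdcs, read_rdc_table
from .montecarlo import McResult, McSpec, mc_tensor_uncertainty
from .structure import (
    BondVectorSet,
    SseDefinition,
    extract_nh_vectors,
    load_structure,
    read_sse_config,
    select_sse_vectors,
)
from .tensorfit import (
    DMAX_NH_HZ,
    AlignmentTensor,
    FitResult,
    q_factor,
    svd_fit,
)

__all__ = ["RdcTensorModel", "RdcTensorResults"]


class RdcTensorModel:
    """Alignment-tensor model: couplings regressed on bond-vector geometry.

    Parameters
    ----------
    dataset : RdcDataset
        Measured couplings; excluded records are ignored by the fit.
    vectors : BondVectorSet
        Unit N-H vectors in the PDB frame of the template structure.
    scale : float
        Dipolar interaction constant in Hz (default 21.7 kHz for N-H).
    weighted : bool
        Apply 1/sigma_D² weights (default off, matching the plain SVD
        convention so Q values are comparable across datasets).
    scoring_vectors : BondVectorSet, optional
        Separate selection used for Q scoring (e.g. secondary-structure
        residues only) when it should differ from the fitting selection.
    """

    def __init__(
        self,
        dataset: RdcDataset,
        vectors: BondVectorSet,
        scale: float = DMAX_NH_HZ,
        weighted: bool = False,
        scoring_vectors: BondVectorSet | None = None,
    ) -> None:
        self.dataset = dataset
        self.vectors = vectors
        self.scale = scale
        self.weighted = weighted
        self.scoring_vectors = scoring_vectors

    @classmethod
    def from_files(
        cls,
        pdb_path,
        rdc_path,
        chain: str = "A",
        model: int = 1,
        sse_path=None,
        fit_sse_only: bool = False,
        **kwargs,
    ) -> "RdcTensorModel":
        """Build from a PDB file and an RDC table.

        With an SSE config, Q is always scored on secondary-structure
        residues; ``fit_sse_only`` additionally restricts the fit itself.
        """
        structure = load_structure(pdb_path, model=model)
        vectors = extract_nh_vectors(structure, chain)
        dataset = read_rdc_table(rdc_path)
        scoring = None
        if sse_path is not None:
            sses = read_sse_config(sse_path)
            scoring = select_sse_vectors(vectors, sses)
            if fit_sse_only:
                vectors = scoring
        return cls(dataset, vectors, scoring_vectors=scoring, **kwargs)

    def filter(self, s2_by_residue=None, exchange_residues=None,
               **kwargs) -> "RdcTensorModel":
        """Return a model with the quality filters applied to the dataset."""
        filtered = filter_rdcs(self.dataset, s2_by_residue, exchange_residues,
                               **kwargs)
        return RdcTensorModel(
            filtered, self.vectors, scale=self.scale, weighted=self.weighted,
            scoring_vectors=self.scoring_vectors,
        )

    def fit(self) -> "RdcTensorResults":
        fit = svd_fit(self.dataset, self.vectors, scale=self.scale,
                      weighted=self.weighted)
        return RdcTensorResults(model=self, _fit=fit)


@dataclass
class RdcTensorResults:
    """Fitted alignment tensor with uncertainties, diagnostics and summaries."""

    model: RdcTensorModel
    _fit: FitResult

    # -- estimates ---------------------------------------------------------
    @property
    def tensor(self) -> AlignmentTensor:
        return self._fit.tensor

    @property
    def Da(self) -> float:
        return self._fit.parameters.Da

    @property
    def rhombicity(self) -> float:
        return self._fit.parameters.R

    @property
    def euler_zyz(self) -> tuple[float, float, float]:
        return self._fit.parameters.euler_zyz

    @property
    def magnitude(self) -> float:
        return self._fit.parameters.magnitude

    @property
    def back_calculated(self) -> dict[int, float]:
        return self._fit.back_calculated

    @property
    def Q(self) -> float:
        """Q on the scoring selection when one was given, else on the fit set."""
        scoring = self.model.scoring_vectors
        if scoring is None:
            return self._fit.Q
        obs = {r: v for r, v in self._fit.observed.items() if r in scoring}
        calc = {r: v for r, v in self._fit.back_calculated.items() if r in scoring}
        return q_factor(obs, calc)

    @property
    def rmsd(self) -> float:
        return self._fit.rmsd

    @property
    def nobs(self) -> int:
        return self._fit.n_used

    @property
    def condition_number(self) -> float:
        return self._fit.condition_number

    @property
    def rms_sigma(self) -> float:
        return self.model.dataset.rms_sigma

    # -- uncertainty and comparison ---------------------------------------
    def monte_carlo(
        self,
        spec: McSpec | None = None,
        reference: AlignmentTensor | None = None,
        **kwargs,
    ) -> McResult:
        """Monte-Carlo uncertainty on all tensor parameters.

        Either pass an :class:`McSpec` or keyword arguments for one
        (``n_iterations``, ``rdc_noise_scale``, ``structural_noise_angle``,
        ``seed``).
        """
        if spec is None:
            spec = McSpec(**kwargs)
        return mc_tensor_uncertainty(
            self.model.dataset,
            self.model.vectors,
            spec,
            reference=reference,
            scale=self.model.scale,
            weighted=self.model.weighted,
        )

    def angle_to(self, other) -> float:
        """5D inter-tensor angle (degrees) to another results object or tensor."""
        tensor = other.tensor if isinstance(other, RdcTensorResults) else other
        return five_d_angle(self.tensor, tensor)

    def project_axes(self) -> AxisProjection:
        return project_axes(self.tensor)

    def plot_axes(self, ax=None):
        from .compare import plot_axes as _plot

        return _plot(self.project_axes(), labels=["fit"], ax=ax)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        p = self._fit.parameters
        a, b, g = p.euler_zyz
        five = to_5vector(self.tensor).components
        lines = [
            "            Alignment tensor fit (SVD least squares)",
            "=" * 64,
            f"No. couplings:      {self.nobs:10d}    Q factor:      {self.Q:10.4f}",
            f"Condition number:   {self.condition_number:10.2f}    rmsd (Hz):     {self.rmsd:10.4f}",
            f"RMS sigma_D (Hz):   {self.rms_sigma:10.4f}    scale (Hz):    {self.model.scale:10.1f}",
            "-" * 64,
            f"Da (Hz):            {p.Da:10.4f}    rhombicity R:  {p.R:10.4f}",
            f"GDO magnitude:      {p.magnitude:10.3e}",
            f"Euler zyz (deg):    alpha {a:8.2f}  beta {b:8.2f}  gamma {g:8.2f}",
            f"5-vector:           " + "  ".join(f"{c: .3e}" for c in five),
            "=" * 64,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p = self._fit.parameters
        return {
            "saupe": self.tensor.saupe.tolist(),
            "scale_hz": self.model.scale,
            "Da_hz": p.Da,
            "rhombicity": p.R,
            "euler_zyz_deg": list(p.euler_zyz),
            "magnitude": p.magnitude,
            "Q": self.Q,
            "rmsd_hz": self.rmsd,
            "n_used": self.nobs,
            "condition_number": self.condition_number,
            "observed": {str(k): v for k, v in self._fit.observed.items()},
            "back_calculated": {
                str(k): v for k, v in self._fit.back_calculated.items()
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @staticmethod
    def load_tensor(path) -> AlignmentTensor:
        """Reload the tensor stored by :meth:`save`."""
        with open(path) as fh:
            d = json.load(fh)
        return AlignmentTensor(saupe=np.array(d["saupe"]), scale=d["scale_hz"])
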