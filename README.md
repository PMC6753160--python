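# rdcfit

Analysis of residual dipolar couplings (RDCs) for weakly aligned proteins:
coupling measurement from peak lists, Saupe alignment-tensor fitting with
Monte-Carlo uncertainties, tensor comparison, rigid-body refinement of
secondary-structure orientations, and interdomain alignment-propagation
order parameters.

## Who this is for

Solution-NMR structural biologists working with amide ¹⁵N–¹H RDCs measured
in a weakly aligning medium (filamentous phage, paramagnetic tags, …) —
including the hard regime of very large complexes, where couplings for a
flexible domain carry uncertainties comparable to the couplings themselves
and conclusions must rest on global fits with honest error propagation. The
motivating system is a two-domain ribosomal stalk protein whose C-terminal
domain is tethered to the particle by a flexible linker; the package
quantifies both the orientation of such a domain and the degree of
orientational coupling transmitted through the linker.

## The model

Under weak alignment, the residual dipolar coupling of a unit bond vector
**b** is a quadratic form in the traceless symmetric 3×3 Saupe order tensor
**S**:

    D = D_max · bᵀ S b ,

linear in the five independent components of **S**, so a set of measured
couplings on known N–H vectors determines the tensor by linear least
squares (solved by SVD). In the principal frame the same coupling reads
`D = Da[(3cos²θ − 1) + (3/2)R sin²θ cos2φ]` with axial magnitude `Da`,
rhombicity `R ∈ [0, 2/3]`, and orientation given by zyz Euler angles.
Agreement between measured and back-calculated couplings is scored by the
Q factor `Q = rms(D_calc − D_obs)/rms(D_obs)`.

On top of the fit the package provides:

- **Measurement**: couplings as anisotropic-minus-isotropic ¹⁵N splittings
  from HSQC/TROSY or IPAP peak pairs, with positional uncertainties
  σ_v = LW/(2·SN) propagated in quadrature, and the standard quality
  filters (local order parameter S² < 0.85, conformational exchange,
  overlap, σ_D > 5 Hz).
- **Uncertainty**: Monte-Carlo perturbation of both the couplings (per-record
  Gaussian noise of σ_D) and the bond vectors (small random reorientations)
  with refitting, giving empirical distributions of all tensor parameters.
- **Comparison**: tensors as norm-preserving irreducible 5-vectors, the 5D
  inter-tensor angle, and Sanson–Flamsteed projections of principal axes.
- **Refinement**: simulated-annealing rigid-body reorientation of
  α-helices/β-strands against soft square-well RDC restraints with a
  floating tensor orientation and fixed Da, R.
- **Propagation**: the effective tensor of an indirectly aligned domain as a
  conjugation average over a linker conformer ensemble, and the interdomain
  order parameter S² = |S_indirect| / |S_direct| (1 = rigid linker, 0 =
  fully flexible).

A synthetic-data generator builds ideal helix/strand structures, simulated
RDC datasets and peak lists from known ground truth, so every stage is
testable end to end with no external data.

## Worked example

```python
from rdcfit import (FixtureSpec, RdcTensorModel, extract_nh_vectors,
                    make_structure, simulate_rdcs)

spec = FixtureSpec(kind="two_helix", n_residues=15, noise=1.8, seed=42)
structure, sses = make_structure(spec)
vectors = extract_nh_vectors(structure, "A")
dataset = simulate_rdcs(structure, spec.tensor, noise=1.8, seed=42)

results = RdcTensorModel(dataset, vectors).fit()
print(results.summary())
mc = results.monte_carlo(n_iterations=1000, structural_noise_angle=0.0, seed=1)
print(f"Da = {mc.mean('Da'):.2f} +/- {mc.sd('Da'):.2f} Hz")
```

prints

```
            Alignment tensor fit (SVD least squares)
================================================================
No. couplings:              28    Q factor:          0.0981
Condition number:        18.15    rmsd (Hz):         1.1386
RMS sigma_D (Hz):       1.8000    scale (Hz):       21700.0
----------------------------------------------------------------
Da (Hz):              -13.4834    rhombicity R:      0.6293
GDO magnitude:       1.415e-03
Euler zyz (deg):    alpha    36.13  beta    46.31  gamma   184.86
5-vector:           -4.426e-04  -7.712e-04   6.857e-04  -1.235e-03  -4.684e-04
================================================================
Da = -13.85 +/- 1.30 Hz
```

Here 28 couplings with 1.8 Hz RMS uncertainty were simulated from a tensor
with Da = −15 Hz, R = 0.3, and refit. The Q factor of 0.10 reflects the
noise level relative to the ±20 Hz coupling range; the Monte-Carlo run
(coupling noise only) puts the fitted axial magnitude within one standard
deviation of the truth. Note the large uncertainty on the rhombicity — at
this noise level R drifts toward its upper bound of 2/3, which is why the
Monte-Carlo machinery resolves the principal-axis assignment against the
point estimate before summarising.

The same steps are available from the shell:

```sh
rdcfit simulate --kind two_helix --n 15 --noise 1.8 --seed 42 --outdir fx/
rdcfit fit --pdb fx/structure.pdb --rdc fx/rdc.tsv --sse fx/sse.cfg --out fit.json
rdcfit mc  --pdb fx/structure.pdb --rdc fx/rdc.tsv --n 1000 --seed 1 --out mc.json
```

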