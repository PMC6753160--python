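import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from rdcfit import (
    AlignmentTensor,
    RdcDataset,
    back_calculate,
    q_factor,
    simulate_rdcs,
    svd_fit,
    tensor_from_parameters,
    tensor_parameters,
)
from rdcfit.measurement import RdcRecord
from rdcfit.structure import BondVectorSet
from rdcfit.tensorfit import (
    TensorFitError,
    design_matrix,
    equivalent_euler_frames,
    saupe_components,
    saupe_from_components,
)


def vector_set(arr):
    arr = np.asarray(arr, dtype=float)
    arr = arr / np.linalg.norm(arr, axis=1, keepdims=True)
    return BondVectorSet(entries={i + 1: v for i, v in enumerate(arr)})


def random_vectors(n, seed):
    rng = np.random.default_rng(seed)
    return vector_set(rng.normal(size=(n, 3)))


def dataset_from(values, sigma=0.5):
    return RdcDataset(
        records=[
            RdcRecord(residue=r, D=float(d), sigma_D=sigma)
            for r, d in sorted(values.items())
        ]
    )


class TestBackCalculate:
    def test_zero_tensor_gives_zero(self):
        t = AlignmentTensor(saupe=np.zeros((3, 3)))
        out = back_calculate(t, random_vectors(10, 0))
        assert all(v == 0.0 for v in out.values())

    def test_axial_tensor_along_z(self):
        t = tensor_from_parameters(Da=10.0, R=0.0)
        out = back_calculate(t, vector_set([[0, 0, 1]]))
        assert out[1] == pytest.approx(20.0)  # theta=0: D = 2 Da

    def test_axial_tensor_perpendicular(self):
        t = tensor_from_parameters(Da=10.0, R=0.0)
        out = back_calculate(t, vector_set([[1, 0, 0]]))
        assert out[1] == pytest.approx(-10.0)  # theta=90, R=0: D = -Da

    def test_principal_frame_formula(self):
        # D = Da[(3cos^2 t - 1) + 1.5 R sin^2 t cos 2p] for a generic vector
        da, rhomb = -8.0, 0.4
        t = tensor_from_parameters(Da=da, R=rhomb)
        theta, phi = np.radians(50.0), np.radians(25.0)
        v = [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        expected = da * (
            (3 * np.cos(theta) ** 2 - 1)
            + 1.5 * rhomb * np.sin(theta) ** 2 * np.cos(2 * phi)
        )
        out = back_calculate(t, vector_set([v]))
        assert out[1] == pytest.approx(expected, abs=1e-9)


class TestSvdFit:
    def test_recovers_generating_tensor_exactly(self, two_helix, noiseless_dataset):
        fit = svd_fit(noiseless_dataset, two_helix["vectors"])
        assert np.abs(fit.tensor.saupe - two_helix["tensor"].saupe).max() < 1e-10
        assert fit.Q < 1e-10

    def test_unbiased_under_noise(self, two_helix):
        # mean fitted Da over repeats within 3 sem of the truth
        spec = two_helix["spec"]
        truth = tensor_parameters(two_helix["tensor"]).Da
        das = []
        for rep in range(60):
            ds = simulate_rdcs(two_helix["structure"], two_helix["tensor"],
                               noise=1.0, seed=1000 + rep)
            das.append(svd_fit(ds, two_helix["vectors"]).parameters.Da)
        das = np.array(das)
        sem = das.std(ddof=1) / np.sqrt(len(das))
        assert abs(das.mean() - truth) < 3 * max(sem, 1e-6)

    def test_coplanar_parallel_vectors_rank_deficient(self):
        vecs = vector_set([[1, 0, 0], [1, 0, 0], [1, 0, 0], [1, 0, 0], [1, 0, 0]])
        ds = dataset_from({i: 1.0 for i in range(1, 6)})
        with pytest.raises(TensorFitError, match="rank-deficient"):
            svd_fit(ds, vecs)

    def test_too_few_records_errors(self):
        vecs = random_vectors(4, 1)
        ds = dataset_from({i: 1.0 for i in range(1, 5)})
        with pytest.raises(TensorFitError, match="at least 5"):
            svd_fit(ds, vecs)

    def test_rotation_equivariance(self, two_helix, noiseless_dataset):
        rot = Rotation.from_euler("ZYZ", [33.0, 55.0, 77.0], degrees=True)
        fit0 = svd_fit(noiseless_dataset, two_helix["vectors"])
        rotated = BondVectorSet(
            entries={
                r: rot.as_matrix() @ v
                for r, v in two_helix["vectors"].entries.items()
            }
        )
        fit1 = svd_fit(noiseless_dataset, rotated)
        conj = rot.as_matrix() @ fit0.tensor.saupe @ rot.as_matrix().T
        assert np.abs(fit1.tensor.saupe - conj).max() < 1e-9
        assert fit1.Q == pytest.approx(fit0.Q, abs=1e-9)

    def test_agrees_with_normal_equations(self):
        # independent oracle: solve A^T A s = A^T b directly
        rng = np.random.default_rng(7)
        vecs = random_vectors(40, 11)
        t = tensor_from_parameters(Da=-9.0, R=0.35, euler_zyz=(10, 40, 80))
        clean = back_calculate(t, vecs)
        noisy = {r: v + rng.normal(0, 2.0) for r, v in clean.items()}
        fit = svd_fit(dataset_from(noisy), vecs)
        a = design_matrix(vecs.as_array())
        b = np.array([noisy[r] for r in vecs.residues()]) / fit.tensor.scale
        s_oracle = np.linalg.solve(a.T @ a, a.T @ b)
        assert np.abs(saupe_components(fit.tensor.saupe) - s_oracle).max() < 1e-9

    def test_residuals_orthogonal_to_design_columns(self, two_helix):
        ds = simulate_rdcs(two_helix["structure"], two_helix["tensor"],
                           noise=2.0, seed=5)
        fit = svd_fit(ds, two_helix["vectors"])
        residues = fit.residues
        a = design_matrix(two_helix["vectors"].as_array(residues))
        resid = np.array(
            [fit.back_calculated[r] - fit.observed[r] for r in residues]
        )
        assert np.abs(a.T @ resid).max() < 1e-8


class TestQFactor:
    def test_identity_gives_zero(self):
        obs = {1: 5.0, 2: -3.0}
        assert q_factor(obs, obs) == 0.0

    def test_null_model_gives_one(self):
        obs = {1: 5.0, 2: -3.0}
        assert q_factor(obs, {1: 0.0, 2: 0.0}) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert q_factor({1: 10.0, 2: -10.0}, {1: 8.0, 2: -8.0}) == pytest.approx(0.2)

    def test_scale_invariance(self):
        obs = {1: 10.0, 2: -4.0, 3: 7.0}
        calc = {1: 9.0, 2: -6.0, 3: 8.0}
        q = q_factor(obs, calc)
        for alpha in (2.0, -3.0, 0.1):
            scaled = q_factor(
                {k: alpha * v for k, v in obs.items()},
                {k: alpha * v for k, v in calc.items()},
            )
            assert scaled == pytest.approx(q)

    def test_zero_observed_errors(self):
        with pytest.raises(TensorFitError):
            q_factor({1: 0.0}, {1: 1.0})

    def test_empty_intersection_errors(self):
        with pytest.raises(TensorFitError):
            q_factor({1: 1.0}, {2: 1.0})

    def test_da_normalization_option(self):
        obs = {1: 10.0, 2: -10.0}
        calc = {1: 8.0, 2: -8.0}
        q = q_factor(obs, calc, normalization="da", Da=5.0, R=0.2)
        expected = 2.0 / np.sqrt(2 * 25.0 * (4 + 3 * 0.04) / 5)
        assert q == pytest.approx(expected)


class TestTensorParameters:
    def test_axially_symmetric_rhombicity_zero(self):
        t = AlignmentTensor(saupe=1e-3 * np.diag([-1.0, -1.0, 2.0]))
        assert tensor_parameters(t).R == pytest.approx(0.0, abs=1e-12)

    def test_maximal_rhombicity(self):
        t = AlignmentTensor(saupe=1e-3 * np.diag([0.0, -1.5, 1.5]))
        assert tensor_parameters(t).R == pytest.approx(2.0 / 3.0)

    def test_euler_recovery_up_to_degeneracy(self):
        rot = Rotation.from_euler("ZYZ", [20.0, 30.0, 40.0], degrees=True)
        t = tensor_from_parameters(Da=-10.0, R=0.3, euler_zyz=(20.0, 30.0, 40.0))
        p = tensor_parameters(t)
        frames = equivalent_euler_frames(rot)
        best = min(
            max(abs((np.array(f) - (20, 30, 40) + 180) % 360 - 180))
            for f in [p.euler_zyz, *frames]
        )
        assert best < 1e-6

    def test_four_equivalent_frames_reproduce_tensor(self):
        t = tensor_from_parameters(Da=-10.0, R=0.3, euler_zyz=(20.0, 30.0, 40.0))
        for frame in equivalent_euler_frames(
            Rotation.from_euler("ZYZ", tensor_parameters(t).euler_zyz, degrees=True)
        ):
            rebuilt = tensor_from_parameters(
                Da=tensor_parameters(t).Da, R=tensor_parameters(t).R, euler_zyz=frame
            )
            assert np.abs(rebuilt.saupe - t.saupe).max() < 1e-12

    def test_zero_tensor_flagged_degenerate(self):
        p = tensor_parameters(AlignmentTensor(saupe=np.zeros((3, 3))))
        assert p.degenerate and p.magnitude == 0.0

    @settings(max_examples=40, deadline=None)
    @given(
        da=st.floats(min_value=-20, max_value=20).filter(lambda x: abs(x) > 0.5),
        rhomb=st.floats(min_value=0.0, max_value=2.0 / 3.0),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_parameter_round_trip(self, da, rhomb, seed):
        rng = np.random.default_rng(seed)
        euler = tuple(rng.uniform([0, 5, 0], [360, 175, 360]))
        t = tensor_from_parameters(Da=da, R=rhomb, euler_zyz=euler)
        p = tensor_parameters(t)
        rebuilt = tensor_from_parameters(Da=p.Da, R=p.R, euler_zyz=p.euler_zyz)
        assert np.abs(rebuilt.saupe - t.saupe).max() < 1e-12
        assert 0.0 <= p.R <= 2.0 / 3.0 + 1e-12

    def test_component_round_trip(self):
        s = np.array([1.0, -2.0, 0.5, 0.3, -0.7])
        assert np.allclose(saupe_components(saupe_from_components(s)), s)
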