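"""Shell selection, tensor fitting, scalar metrics, and the color map."""

import numpy as np
import pytest

from dtialps import (
    AcquisitionScheme,
    TensorField,
    color_fa,
    compute_metrics,
    fit_tensor,
    select_shells,
    synthesize_signals,
)
from dtialps.phantom import DWIDataset
from dtialps.tensor import _design_matrix

from conftest import random_spd_tensors


def _field_from_tensors(tensors: np.ndarray, s0: float = 1.0) -> TensorField:
    grid = tensors.shape[:3]
    return TensorField(
        tensors=tensors,
        s0_map=np.full(grid, s0),
        mask=np.ones(grid, dtype=bool),
    )


def _diag_field(dxx, dyy, dzz) -> TensorField:
    t = np.zeros((1, 1, 1, 3, 3))
    t[..., 0, 0], t[..., 1, 1], t[..., 2, 2] = dxx, dyy, dzz
    return _field_from_tensors(t)


@pytest.fixture(scope="module")
def fit_scheme(scheme):
    """Default scheme already restricted to the DTI shells (b ≤ 1,150)."""
    keep = scheme.b_values <= 1150
    return scheme.subset(keep)


class TestSelectShells:
    def test_keeps_only_low_b(self, small_dataset):
        sub = select_shells(small_dataset, b_max=1150)
        assert sub.scheme.b_values.max() <= 1150
        assert np.any(sub.scheme.b_values == 0)
        # order preserved
        orig = small_dataset.scheme.b_values
        np.testing.assert_array_equal(
            sub.scheme.b_values, orig[orig <= 1150]
        )

    def test_identity_when_all_below_cutoff(self, small_dataset):
        sub = select_shells(small_dataset, b_max=1150)
        again = select_shells(sub, b_max=1150)
        np.testing.assert_array_equal(again.volumes, sub.volumes)

    def test_bmax_zero_unfittable(self, small_dataset):
        with pytest.raises(ValueError, match="direction"):
            select_shells(small_dataset, b_max=0)


class TestFitTensor:
    def test_exact_recovery_anisotropic(self, fit_scheme):
        truth = _diag_field(1.7e-3, 0.4e-3, 0.3e-3)
        data = synthesize_signals(truth, fit_scheme)
        fitted = fit_tensor(data)
        np.testing.assert_allclose(fitted.tensors, truth.tensors, atol=1e-10)
        np.testing.assert_allclose(fitted.s0_map, 1.0, rtol=1e-10)

    def test_exact_recovery_isotropic(self, fit_scheme):
        truth = _diag_field(0.7e-3, 0.7e-3, 0.7e-3)
        fitted = fit_tensor(synthesize_signals(truth, fit_scheme))
        np.testing.assert_allclose(fitted.tensors, truth.tensors, atol=1e-10)

    def test_recovery_of_random_full_tensors(self, fit_scheme):
        """1,000 random SPD tensors, noise-free: every element within 1e-8."""
        rng = np.random.default_rng(11)
        tensors = random_spd_tensors(1000, rng).reshape(10, 10, 10, 3, 3)
        truth = _field_from_tensors(tensors, s0=100.0)
        fitted = fit_tensor(synthesize_signals(truth, fit_scheme))
        assert np.abs(fitted.tensors - truth.tensors).max() < 1e-8

    def test_oracle_equivalence_pervoxel_normal_equations(self, fit_scheme):
        """Pooled lstsq path matches an independently built per-voxel solve."""
        rng = np.random.default_rng(5)
        tensors = random_spd_tensors(8, rng).reshape(2, 2, 2, 3, 3)
        truth = _field_from_tensors(tensors, s0=50.0)
        data = synthesize_signals(truth, fit_scheme)
        noisy = np.maximum(
            data.volumes + rng.normal(0, 0.5, data.volumes.shape), 1e-10
        )
        data_noisy = DWIDataset(
            volumes=noisy, scheme=fit_scheme, mask=data.mask, affine=data.affine
        )
        fitted = fit_tensor(data_noisy)

        # oracle: explicit per-voxel normal equations built element by element
        b, g = fit_scheme.b_values, fit_scheme.directions
        for ix in np.ndindex(2, 2, 2):
            rows = []
            for i in range(len(b)):
                gx, gy, gz = g[i]
                rows.append(
                    [1.0, -b[i] * gx * gx, -b[i] * gy * gy, -b[i] * gz * gz,
                     -2 * b[i] * gx * gy, -2 * b[i] * gx * gz, -2 * b[i] * gy * gz]
                )
            A = np.array(rows)
            y = np.log(noisy[ix])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            expect = np.array(
                [[beta[1], beta[4], beta[5]],
                 [beta[4], beta[2], beta[6]],
                 [beta[5], beta[6], beta[3]]]
            )
            np.testing.assert_allclose(fitted.tensors[ix], expect, atol=1e-12)

    def test_wls_matches_ols_noise_free(self, fit_scheme):
        truth = _diag_field(1.2e-3, 0.5e-3, 0.4e-3)
        data = synthesize_signals(truth, fit_scheme)
        ols = fit_tensor(data, method="ols")
        wls = fit_tensor(data, method="wls")
        np.testing.assert_allclose(wls.tensors, ols.tensors, atol=1e-12)

    def test_refit_reproduces_signals(self, fit_scheme):
        rng = np.random.default_rng(3)
        tensors = random_spd_tensors(27, rng).reshape(3, 3, 3, 3, 3)
        truth = _field_from_tensors(tensors, s0=10.0)
        data = synthesize_signals(truth, fit_scheme)
        fitted = fit_tensor(data)
        fitted.s0_map = truth.s0_map  # same S0; compare signal predictions
        resynth = synthesize_signals(fitted, fit_scheme)
        np.testing.assert_allclose(resynth.volumes, data.volumes, rtol=1e-9)

    def test_noisy_fa_recovery_within_tolerance(self, fit_scheme):
        """Rician noise at SNR 30: median recovered FA within 0.03 of truth."""
        from dtialps import add_rician_noise

        s0 = 1000.0
        t = np.zeros((500, 1, 1, 3, 3))
        t[..., 0, 0], t[..., 1, 1], t[..., 2, 2] = 1.4e-3, 0.4e-3, 0.4e-3
        truth = _field_from_tensors(t, s0=s0)
        fa_true = compute_metrics(truth).fa[0, 0, 0]
        data = synthesize_signals(truth, fit_scheme)
        noisy = add_rician_noise(data, s0 / 30, seed=21)
        fa_fit = compute_metrics(fit_tensor(noisy)).fa
        assert abs(np.median(fa_fit) - fa_true) < 0.03

    def test_coplanar_directions_rejected(self):
        n = 12
        ang = np.linspace(0, np.pi, n, endpoint=False)
        dirs = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])
        sch = AcquisitionScheme(
            np.r_[0.0, np.full(n, 1000.0)], np.vstack([np.zeros(3), dirs])
        )
        data = DWIDataset(
            volumes=np.ones((1, 1, 1, n + 1)),
            scheme=sch,
            mask=np.ones((1, 1, 1), dtype=bool),
        )
        with pytest.raises(ValueError, match="rank"):
            fit_tensor(data)


class TestMetrics:
    def test_fa_md_closed_form(self):
        lam = np.array([1.7e-3, 0.2e-3, 0.2e-3])
        m = compute_metrics(_diag_field(*lam))
        md = lam.mean()
        fa = np.sqrt(1.5 * ((lam - md) ** 2).sum() / (lam**2).sum())
        np.testing.assert_allclose(m.md[0, 0, 0], md, rtol=1e-12)
        np.testing.assert_allclose(m.fa[0, 0, 0], fa, rtol=1e-12)
        assert abs(m.fa[0, 0, 0] - 0.8704) < 5e-4

    def test_fa_extremes(self):
        iso = compute_metrics(_diag_field(1e-3, 1e-3, 1e-3))
        assert iso.fa[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        single = compute_metrics(_diag_field(1e-3, 0.0, 0.0))
        assert single.fa[0, 0, 0] == pytest.approx(1.0, abs=1e-5)

    def test_all_zero_tensor_fa_zero(self):
        m = compute_metrics(_field_from_tensors(np.zeros((1, 1, 1, 3, 3))))
        assert m.fa[0, 0, 0] == 0.0
        assert np.isfinite(m.md).all()

    def test_rotation_invariance(self):
        """FA and MD are invariant under rotation of the tensor."""
        from scipy.stats import ortho_group

        rng = np.random.RandomState(17)
        lam = np.diag([1.6e-3, 0.5e-3, 0.3e-3])
        base = compute_metrics(_field_from_tensors(lam[None, None, None]))
        for _ in range(20):
            r = ortho_group.rvs(3, random_state=rng)
            rot = r @ lam @ r.T
            rot = 0.5 * (rot + rot.T)
            m = compute_metrics(_field_from_tensors(rot[None, None, None]))
            np.testing.assert_allclose(m.fa, base.fa, atol=1e-10)
            np.testing.assert_allclose(m.md, base.md, atol=1e-15)

    def test_eigenvectors_orthonormal(self, small_truth):
        m = compute_metrics(small_truth)
        v = m.eigenvectors
        eye = np.einsum("...ij,...ik->...jk", v, v)
        np.testing.assert_allclose(eye, np.broadcast_to(np.eye(3), eye.shape), atol=1e-6)


class TestColorFA:
    def test_channel_mapping(self):
        m = compute_metrics(_diag_field(0.3e-3, 0.3e-3, 1.7e-3))
        rgb = color_fa(m)[0, 0, 0]
        assert rgb[2] > 0.5 and rgb[0] < 1e-6 and rgb[1] < 1e-6

    def test_zero_fa_is_black(self):
        m = compute_metrics(_diag_field(1e-3, 1e-3, 1e-3))
        np.testing.assert_allclose(color_fa(m)[0, 0, 0], 0.0, atol=1e-8)

    def test_x_fiber_red_dominant(self):
        m = compute_metrics(_diag_field(1.7e-3, 0.3e-3, 0.3e-3))
        rgb = color_fa(m)[0, 0, 0]
        assert rgb[0] > rgb[1] and rgb[0] > rgb[2]

    def test_design_matrix_shape(self, fit_scheme):
        assert _design_matrix(fit_scheme).shape == (fit_scheme.volume_count, 7)
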