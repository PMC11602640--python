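import numpy as np
import pytest
from scipy.stats import ortho_group

from steamdti.encoding import DiffusionScheme, DiffusionVolume, build_scheme
from steamdti.errors import ValidationError
from steamdti.synthetic_data import synthesize_series, tensor_from_fa_md
from steamdti.tensor_fit import TensorField, color_fa, fit_tensor, tensor_metrics
from conftest import RELAX, STEAM100_TIMING


def single_tensor_series(scheme, tensor, s0=1000.0, shape=(4, 4, 2)):
    att = np.exp(-np.einsum("jab,ab->j", scheme.b_matrices, tensor))
    return np.broadcast_to(s0 * att, shape + (len(scheme),)).copy()


def nominal_only(scheme):
    """Scheme stripped of background/cross terms (scalar-b approximation)."""
    vols = []
    for v in scheme.volumes:
        b = (
            np.zeros((3, 3))
            if v.is_reference
            else v.nominal_b * np.outer(v.direction, v.direction)
        )
        vols.append(DiffusionVolume(v.nominal_b, v.direction, b, v.is_reference))
    return DiffusionScheme(tuple(vols), scheme.sequence_kind,
                           scheme.encoding_time)


class TestFitTensor:
    def test_noiseless_exact_recovery(self, background_law):
        scheme = build_scheme("STEAM", 100.0, background_law)
        truth = tensor_from_fa_md(0.38, 1.33e-3, [0.0, 1.0, 0.0])
        series = single_tensor_series(scheme, truth)
        mask = np.ones(series.shape[:3], dtype=bool)
        field = fit_tensor(series, scheme, mask)
        err = np.abs(field.tensors[mask] - truth).max() / np.abs(truth).max()
        assert err < 1e-8
        assert np.allclose(field.s0[mask], 1000.0)

    def test_underdetermined_scheme_rejected(self, background_law):
        scheme = build_scheme("STEAM", 100.0, background_law, n_directions=6)
        five = DiffusionScheme(
            scheme.volumes[:8], scheme.sequence_kind, scheme.encoding_time
        )
        series = np.ones((2, 2, 1, 8))
        with pytest.raises(ValidationError, match="rank"):
            fit_tensor(series, five, np.ones((2, 2, 1), dtype=bool))

    def test_volume_count_mismatch_rejected(self, background_law):
        scheme = build_scheme("STEAM", 100.0, background_law)
        with pytest.raises(ValidationError, match="volumes"):
            fit_tensor(np.ones((2, 2, 1, 10)), scheme,
                       np.ones((2, 2, 1), dtype=bool))

    def test_nonpositive_signal_flagged_not_fitted(self, background_law):
        scheme = build_scheme("STEAM", 100.0, background_law)
        truth = tensor_from_fa_md(0.3, 1.3e-3, [0.0, 1.0, 0.0])
        series = single_tensor_series(scheme, truth, shape=(2, 1, 1))
        series[0, 0, 0, 5] = 0.0
        field = fit_tensor(series, scheme, np.ones((2, 1, 1), dtype=bool))
        assert field.flagged[0, 0, 0] and not field.mask[0, 0, 0]
        assert field.mask[1, 0, 0]

    def test_all_flagged_rejected(self, background_law):
        scheme = build_scheme("STEAM", 100.0, background_law)
        series = np.zeros((2, 1, 1, 67))
        with pytest.raises(ValidationError, match="nonpositive"):
            fit_tensor(series, scheme, np.ones((2, 1, 1), dtype=bool))

    def test_ols_and_wls_agree_on_noiseless_data(self, background_law):
        scheme = build_scheme("STEAM", 100.0, background_law)
        truth = tensor_from_fa_md(0.45, 1.2e-3, [0.6, 0.8, 0.0])
        series = single_tensor_series(scheme, truth)
        mask = np.ones(series.shape[:3], dtype=bool)
        ols = fit_tensor(series, scheme, mask, method="ols")
        wls = fit_tensor(series, scheme, mask, method="wls")
        assert np.abs(ols.tensors - wls.tensors).max() < 1e-6 * truth.max()

    def test_scaling_b_matrices_shrinks_fitted_md(self, background_law):
        scheme = build_scheme("STEAM", 100.0, background_law)
        truth = tensor_from_fa_md(0.38, 1.33e-3, [0.0, 1.0, 0.0])
        series = single_tensor_series(scheme, truth)
        mask = np.ones(series.shape[:3], dtype=bool)
        doubled = DiffusionScheme(
            tuple(
                DiffusionVolume(v.nominal_b, v.direction, 2 * v.b_matrix,
                                v.is_reference)
                for v in scheme.volumes
            ),
            scheme.sequence_kind, scheme.encoding_time,
        )
        md_orig = tensor_metrics(fit_tensor(series, scheme, mask)).md[mask].mean()
        md_doubled = tensor_metrics(
            fit_tensor(series, doubled, mask)
        ).md[mask].mean()
        assert md_doubled < md_orig

    def test_ignoring_cross_terms_biases_md(
        self, small_phantom, background_law, law
    ):
        """Data carry background encoding; fitting with the full b-matrices
        is exact, while a nominal-b-only fit leaves the reference volumes'
        attenuation unmodelled, deflating s0 and biasing MD low."""
        from steamdti import protocol

        scheme = build_scheme("STEAM", 600.0, background_law)
        timing = protocol.sequence_timing("STEAM600")
        series = synthesize_series(
            small_phantom, scheme, timing, RELAX, snr_target=1e12, seed=0,
            law=law,
        )
        mask = small_phantom.muscle_mask
        _, md_true = law.metrics("STEAM", 600.0)
        md_full = tensor_metrics(
            fit_tensor(series, scheme, mask)
        ).md[mask].mean()
        md_nominal = tensor_metrics(
            fit_tensor(series, nominal_only(scheme), mask)
        ).md[mask].mean()
        assert md_full == pytest.approx(md_true, rel=1e-8)
        assert abs(md_nominal - md_true) > 0.05 * md_true
        assert md_nominal < md_true


class TestTensorMetrics:
    def test_isotropic_tensor(self):
        field = TensorField(
            tensors=1.5e-3 * np.eye(3)[None, None, None],
            s0=np.ones((1, 1, 1)),
            mask=np.ones((1, 1, 1), dtype=bool),
            flagged=np.zeros((1, 1, 1), dtype=bool),
        )
        m = tensor_metrics(field)
        assert m.fa[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert m.md[0, 0, 0] == pytest.approx(1.5e-3)

    def test_muscle_like_eigenvalues(self):
        d = np.diag([1.9e-3, 1.0e-3, 1.0e-3])
        field = TensorField(
            tensors=d[None, None, None], s0=np.ones((1, 1, 1)),
            mask=np.ones((1, 1, 1), dtype=bool),
            flagged=np.zeros((1, 1, 1), dtype=bool),
        )
        m = tensor_metrics(field)
        assert m.fa[0, 0, 0] == pytest.approx(0.380, abs=5e-4)
        assert m.md[0, 0, 0] == pytest.approx(1.30e-3, rel=1e-12)
        assert np.all(np.diff(m.eigenvalues[0, 0, 0]) <= 0)

    @pytest.mark.parametrize("seed", range(3))
    def test_rotation_invariance(self, seed):
        d = tensor_from_fa_md(0.45, 1.3e-3, [0, 0, 1])
        r = ortho_group.rvs(3, random_state=seed)
        rotated = r @ d @ r.T
        tensors = np.stack([d, rotated])[:, None, None]
        field = TensorField(
            tensors=tensors, s0=np.ones((2, 1, 1)),
            mask=np.ones((2, 1, 1), dtype=bool),
            flagged=np.zeros((2, 1, 1), dtype=bool),
        )
        m = tensor_metrics(field)
        assert m.fa[0, 0, 0] == pytest.approx(m.fa[1, 0, 0], abs=1e-12)
        assert m.md[0, 0, 0] == pytest.approx(m.md[1, 0, 0], abs=1e-15)

    def test_negative_eigenvalue_clamped_and_flagged(self):
        d = np.diag([2e-3, 1e-3, -1e-4])
        field = TensorField(
            tensors=d[None, None, None], s0=np.ones((1, 1, 1)),
            mask=np.ones((1, 1, 1), dtype=bool),
            flagged=np.zeros((1, 1, 1), dtype=bool),
        )
        m = tensor_metrics(field)
        assert m.negative_eigenvalue[0, 0, 0]
        assert m.eigenvalues[0, 0, 0].min() == 0.0
        assert m.md[0, 0, 0] == pytest.approx(1e-3)

    def test_all_zero_tensor_has_zero_fa(self):
        field = TensorField(
            tensors=np.zeros((1, 1, 1, 3, 3)), s0=np.ones((1, 1, 1)),
            mask=np.ones((1, 1, 1), dtype=bool),
            flagged=np.zeros((1, 1, 1), dtype=bool),
        )
        assert tensor_metrics(field).fa[0, 0, 0] == 0.0


class TestColorFa:
    def test_pure_x_fiber_is_red(self):
        d = tensor_from_fa_md(0.999, 1e-3, [1.0, 0.0, 0.0])
        field = TensorField(
            tensors=d[None, None, None], s0=np.ones((1, 1, 1)),
            mask=np.ones((1, 1, 1), dtype=bool),
            flagged=np.zeros((1, 1, 1), dtype=bool),
        )
        rgb = color_fa(tensor_metrics(field))[0, 0, 0]
        assert rgb[0] > 0.99 and rgb[1] < 1e-6 and rgb[2] < 1e-6

    def test_isotropic_is_black(self):
        field = TensorField(
            tensors=(1e-3 * np.eye(3))[None, None, None],
            s0=np.ones((1, 1, 1)), mask=np.ones((1, 1, 1), dtype=bool),
            flagged=np.zeros((1, 1, 1), dtype=bool),
        )
        assert np.allclose(color_fa(tensor_metrics(field)), 0.0, atol=1e-12)

    def test_antipodal_symmetry(self):
        for sign in (1.0, -1.0):
            n = sign * np.array([0.0, 1.0, 0.0])
            d = tensor_from_fa_md(0.5, 1e-3, n)
            field = TensorField(
                tensors=d[None, None, None], s0=np.ones((1, 1, 1)),
                mask=np.ones((1, 1, 1), dtype=bool),
                flagged=np.zeros((1, 1, 1), dtype=bool),
            )
            rgb = color_fa(tensor_metrics(field))[0, 0, 0]
            if sign > 0:
                first = rgb
        assert np.allclose(first, rgb, atol=1e-12)
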