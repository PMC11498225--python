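"""PIV and traction reconstruction against known-shift and elasticity oracles."""

import numpy as np
import pytest

from mechanoquant.io import ImageStack
from mechanoquant.simulate import (
    BeadSimSpec,
    GaussianTraction,
    simulate_bead_pair,
    traction_grids,
)
from mechanoquant.traction import (
    DisplacementField,
    forward_displacement,
    fttc,
    piv,
    select_lambda,
    summed_vector_norm,
    temporal_color_code,
)


def boussinesq_realspace(tx, ty, spacing_m, E, nu):
    """Independent oracle: direct real-space convolution with the surface
    Green's tensor, with the analytic self-cell integral
    (integral of 1/r over a square cell of side d is 4 d ln(1+sqrt 2))."""
    n = tx.shape[0]
    y, x = np.mgrid[0:n, 0:n]
    pos = np.column_stack([y.ravel(), x.ravel()]).astype(float) * spacing_m
    txf, tyf = tx.ravel(), ty.ravel()
    pref = (1 + nu) / (np.pi * E)
    area = spacing_m ** 2
    self_c = pref * ((1 - nu) + nu / 2) * 4 * spacing_m * np.log(1 + np.sqrt(2))
    ux = np.zeros(n * n)
    uy = np.zeros(n * n)
    for i in range(n * n):
        d = pos[i] - pos
        r = np.hypot(d[:, 0], d[:, 1])
        r[i] = np.inf
        dx, dy = d[:, 1], d[:, 0]
        gxx = pref * ((1 - nu) / r + nu * dx ** 2 / r ** 3)
        gyy = pref * ((1 - nu) / r + nu * dy ** 2 / r ** 3)
        gxy = pref * nu * dx * dy / r ** 3
        ux[i] = area * (gxx @ txf + gxy @ tyf) + self_c * txf[i]
        uy[i] = area * (gxy @ txf + gyy @ tyf) + self_c * tyf[i]
    return ux.reshape(n, n), uy.reshape(n, n)


def dipole_spec(n=64, mag=30.0, sigma=4.0):
    return BeadSimSpec(
        n_beads=10, field_size_px=n, pixel_size_um=0.5, noise_sd=0.0,
        substrate_E_pa=200.0, substrate_nu=0.5,
        tractions=[
            GaussianTraction(n * 3 // 8, n // 2, mag, 0.0, sigma),
            GaussianTraction(n * 5 // 8, n // 2, -mag, 0.0, sigma),
        ],
    )


class TestPiv:
    @pytest.mark.parametrize("shift", [(-2.0, 3.0), (1.3, -0.7), (4.1, 2.2)])
    def test_known_shift_recovered_subpixel(self, shift):
        spec = BeadSimSpec(n_beads=900, field_size_px=256,
                           uniform_shift_px=shift, noise_sd=1.0, rng_seed=1)
        res = simulate_bead_pair(spec)
        f = piv(res.reference, res.moving, 32, 16)
        rms = np.sqrt(np.nanmean(
            (f.u - shift[1]) ** 2 + (f.v - shift[0]) ** 2
        ))
        assert rms < 0.2

    def test_identical_images_give_zero_field(self):
        res = simulate_bead_pair(
            BeadSimSpec(n_beads=400, field_size_px=128, noise_sd=0.0,
                        rng_seed=2)
        )
        f = piv(res.reference, res.reference, 32, 16)
        assert np.nanmax(np.hypot(f.u, f.v)) < 0.05

    def test_blank_windows_masked_not_zeroed(self):
        blank = np.full((64, 64), 5.0)
        f = piv(blank, blank, 32, 16)
        assert not f.mask.any()
        assert np.isnan(f.u).all()

    def test_window_larger_than_image_rejected(self):
        img = np.zeros((24, 24))
        with pytest.raises(ValueError):
            piv(img, img, 32, 16)
        with pytest.raises(ValueError):
            piv(img, img, 8, 4)  # below the 16 px minimum


class TestSummedVectorNorm:
    def _field(self, u, v, frame=0):
        u = np.asarray(u, dtype=float)
        return DisplacementField(
            x=np.arange(u.shape[1], dtype=float),
            y=np.arange(u.shape[0], dtype=float),
            u=u, v=np.asarray(v, dtype=float),
            peak=np.ones_like(u), frame=frame,
        )

    def test_pythagorean_sum(self):
        f0 = self._field([[0.0, 0.0]], [[0.0, 0.0]])
        f1 = self._field([[3.0, 0.0]], [[4.0, 0.0]], frame=1)
        s = summed_vector_norm([f0, f1], pixel_size_um=1.0,
                               frame_interval_s=1.0, stimulus_frame=0)
        assert s.summed_norm_um[1] == pytest.approx(5.0)

    def test_all_masked_frame_flagged(self):
        f0 = self._field([[1.0]], [[0.0]])
        f1 = self._field([[np.nan]], [[np.nan]], frame=1)
        with pytest.warns(UserWarning, match="no valid"):
            s = summed_vector_norm([f0, f1, f0], 1.0, 1.0, stimulus_frame=1)
        assert 1 in s.undefined_frames

    def test_doubled_contraction_rate_recovered(self):
        """Cumulative displacement growing 2x faster after the stimulus."""
        rng = np.random.default_rng(0)
        base = rng.uniform(0.5, 1.5, (6, 6))
        ang = rng.uniform(0, 2 * np.pi, (6, 6))
        fields = []
        mag = 0.0
        for t in range(20):
            mag += 0.05 if t <= 10 else 0.10
            fields.append(self._field(mag * base * np.cos(ang),
                                      mag * base * np.sin(ang), frame=t))
        s = summed_vector_norm(fields, 1.0, 1.0, stimulus_frame=10)
        assert s.speed_ratio_defined
        assert s.speed_ratio == pytest.approx(2.0, rel=0.15)


class TestFttc:
    def test_zero_displacement_gives_zero_traction(self):
        n = 32
        f = DisplacementField(
            x=np.arange(n, dtype=float), y=np.arange(n, dtype=float),
            u=np.zeros((n, n)), v=np.zeros((n, n)), peak=np.ones((n, n)),
        )
        tm = fttc(f, 0.5, 200.0, 0.5)
        assert np.allclose(tm.tx, 0) and np.allclose(tm.ty, 0)

    def test_forward_inverse_roundtrip_within_5pct_of_peak(self):
        spec = dipole_spec()
        tx, ty = traction_grids(spec)
        ux, uy = forward_displacement(tx, ty, 0.5e-6, 200.0, 0.5)
        n = 64
        f = DisplacementField(
            x=np.arange(n, dtype=float), y=np.arange(n, dtype=float),
            u=ux / 0.5e-6, v=uy / 0.5e-6, peak=np.ones((n, n)),
        )
        tm = fttc(f, 0.5, 200.0, 0.5, regularization_lambda=0.0)
        rms = np.sqrt(np.mean((tm.tx - tx) ** 2 + (tm.ty - ty) ** 2))
        assert rms < 0.05 * np.abs(tx).max()

    def test_net_force_balance(self):
        spec = dipole_spec()
        tx, ty = traction_grids(spec)
        ux, uy = forward_displacement(tx, ty, 0.5e-6, 200.0, 0.5)
        n = 64
        f = DisplacementField(
            x=np.arange(n, dtype=float), y=np.arange(n, dtype=float),
            u=ux / 0.5e-6, v=uy / 0.5e-6, peak=np.ones((n, n)),
        )
        tm = fttc(f, 0.5, 200.0, 0.5)
        fx, fy = tm.net_force()
        scale = np.abs(tm.magnitude).sum()
        assert abs(fx) < 1e-9 * scale and abs(fy) < 1e-9 * scale

    def test_fourier_forward_matches_realspace_oracle(self):
        spec = dipole_spec()
        tx, ty = traction_grids(spec)
        ux_f, uy_f = forward_displacement(tx, ty, 0.5e-6, 200.0, 0.5)
        ux_r, uy_r = boussinesq_realspace(tx, ty, 0.5e-6, 200.0, 0.5)
        num = np.sqrt(np.mean((ux_f - ux_r) ** 2 + (uy_f - uy_r) ** 2))
        den = np.sqrt(np.mean(ux_r ** 2 + uy_r ** 2))
        assert num / den < 0.02

    def test_linearity_in_displacement(self):
        spec = dipole_spec(n=32)
        tx, ty = traction_grids(spec)
        ux, uy = forward_displacement(tx, ty, 0.5e-6, 200.0, 0.5)
        n = 32
        grid = dict(x=np.arange(n, dtype=float), y=np.arange(n, dtype=float),
                    peak=np.ones((n, n)))
        t1 = fttc(DisplacementField(u=ux, v=uy, **grid), 0.5, 200.0, 0.5)
        t3 = fttc(DisplacementField(u=3 * ux, v=3 * uy, **grid),
                  0.5, 200.0, 0.5)
        assert np.allclose(t3.tx, 3 * t1.tx, atol=1e-9 * np.abs(t1.tx).max())

    def test_negative_lambda_rejected(self):
        n = 16
        f = DisplacementField(
            x=np.arange(n, dtype=float), y=np.arange(n, dtype=float),
            u=np.zeros((n, n)), v=np.zeros((n, n)), peak=np.ones((n, n)),
        )
        with pytest.raises(ValueError):
            fttc(f, 0.5, 200.0, 0.5, regularization_lambda=-1.0)

    def test_lcurve_lambda_keeps_peak_position_under_noise(self):
        spec = dipole_spec(n=32, sigma=3.0)
        tx, ty = traction_grids(spec)
        ux, uy = forward_displacement(tx, ty, 0.5e-6, 200.0, 0.5)
        rng = np.random.default_rng(0)
        noise = 0.05 * np.abs(ux).max()
        n = 32
        f = DisplacementField(
            x=np.arange(n, dtype=float), y=np.arange(n, dtype=float),
            u=(ux + rng.normal(0, noise, ux.shape)) / 0.5e-6,
            v=(uy + rng.normal(0, noise, uy.shape)) / 0.5e-6,
            peak=np.ones((n, n)),
        )
        lam = select_lambda(f, 0.5, 200.0, 0.5)
        tm = fttc(f, 0.5, 200.0, 0.5, regularization_lambda=lam)
        rec_peak = np.unravel_index(np.argmax(tm.magnitude), tm.magnitude.shape)
        # the dipole has two equal-magnitude poles; the reconstructed maximum
        # must land within one grid node of either pole centre
        poles = [(tr.y_px, tr.x_px) for tr in spec.tractions]
        dist = min(np.hypot(rec_peak[0] - py, rec_peak[1] - px_)
                   for py, px_ in poles)
        assert dist <= np.sqrt(2)

    def test_soft_substrate_micron_displacements_give_tens_of_pa(self):
        """0.2 kPa substrate with um-scale displacements lands in the
        tens-of-Pa stress regime (order-of-magnitude sanity, not equality)."""
        spec = dipole_spec(mag=30.0)
        tx, ty = traction_grids(spec)
        ux, uy = forward_displacement(tx, ty, 0.5e-6, 200.0, 0.5)
        assert 0.1e-6 < np.abs(ux).max() < 5e-6  # sub-um to um displacements
        n = 64
        f = DisplacementField(
            x=np.arange(n, dtype=float), y=np.arange(n, dtype=float),
            u=ux / 0.5e-6, v=uy / 0.5e-6, peak=np.ones((n, n)),
        )
        tm = fttc(f, 0.5, 200.0, 0.5)
        assert 8.0 < tm.magnitude.max() < 100.0


class TestTemporalColorCode:
    def test_static_stack_single_hue_blend(self):
        frames = np.tile(np.eye(16)[None, None] * 100.0, (4, 1, 1, 1))
        stack = ImageStack(frames, 1.0, 1.0)
        rgb = temporal_color_code(stack, "jet")
        lit = rgb[np.eye(16, dtype=bool)]
        # all lit pixels share the same colour
        assert np.allclose(lit, lit[0])

    def test_moving_bead_leaves_ordered_hues(self):
        frames = np.zeros((8, 1, 8, 16))
        for t in range(8):
            frames[t, 0, 4, 2 * t: 2 * t + 2] = 100.0
        stack = ImageStack(frames, 1.0, 1.0)
        rgb = temporal_color_code(stack, "jet")
        row = rgb[4]
        # jet runs blue -> red: the red channel increases along the path and
        # the blue channel decreases
        reds = row[[1, 7, 13], 0]
        blues = row[[1, 7, 13], 2]
        assert reds[0] < reds[1] < reds[2]
        assert blues[0] > blues[2]

    def test_single_frame_rejected(self):
        stack = ImageStack(np.zeros((1, 1, 8, 8)), 1.0, 1.0)
        with pytest.raises(ValueError):
            temporal_color_code(stack)
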