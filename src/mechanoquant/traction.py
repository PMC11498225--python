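"""Bead-displacement PIV and Fourier-transform traction cytometry (FTTC).

The mechanical model is a linear elastic half-space (gel much thicker than
the displacement decay length) with tangential surface tractions.  In Fourier
space the surface displacement u and traction t are related through the
Boussinesq Green's tensor

    u(k) = G(k) t(k),
    G(k) = 2 (1 + nu) / (E |k|^3) *
           [[|k|^2 - nu kx^2,  -nu kx ky],
            [-nu kx ky,        |k|^2 - nu ky^2]],

with Young's modulus E (Pa) and Poisson ratio nu.  The same tensor in real
space (used as an independent oracle in the test suite) is

    G(r) = (1 + nu) / (pi E r^3) *
           [[(1 - nu) r^2 + nu x^2,  nu x y],
            [nu x y,  (1 - nu) r^2 + nu y^2]].

Traction recovery inverts G(k) per wave vector with 0th-order Tikhonov
regularization; the zero-frequency component is nulled, which enforces global
force balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage

from .flecs import window_slopes

__all__ = [
    "DisplacementField",
    "TractionMap",
    "ContractionSummary",
    "piv",
    "summed_vector_norm",
    "fttc",
    "forward_displacement",
    "temporal_color_code",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DisplacementField:
    """Gridded displacement vectors between a reference and a moving image.

    ``x``/``y`` are 1-D node coordinates in pixels; ``u``/``v`` are the
    displacement components (px) on the ``(len(y), len(x))`` node grid, NaN at
    masked nodes; ``peak`` is the correlation peak value per node.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    peak: np.ndarray
    frame: int = 0

    @property
    def mask(self) -> np.ndarray:
        """True where the node carries a valid vector."""
        return np.isfinite(self.u) & np.isfinite(self.v)

    def norms(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class TractionMap:
    """Reconstructed surface stress on the displacement-field grid (Pa)."""

    x: np.ndarray
    y: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    substrate_E_pa: float
    substrate_nu: float
    regularization_lambda: float

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)

    def net_force(self) -> tuple[float, float]:
        """Sum of traction components over nodes; ~0 by force balance."""
        return float(np.nansum(self.tx)), float(np.nansum(self.ty))


@dataclass
class ContractionSummary:
    """Per-frame summed bead-displacement norms and kinetic slopes."""

    time_s: np.ndarray
    summed_norm_um: np.ndarray
    stimulus_frame: int
    baseline_slope: float
    post_slope: float
    speed_ratio: float
    speed_ratio_defined: bool
    max_contraction_um: float
    undefined_frames: np.ndarray


# ---------------------------------------------------------------------------
# PIV
# ---------------------------------------------------------------------------

def _subpixel_offset(c: np.ndarray, ij: tuple[int, int]) -> tuple[float, float]:
    """3-point Gaussian (fallback parabolic) peak interpolation in each axis."""
    out = []
    for axis in range(2):
        i = ij[axis]
        if i <= 0 or i >= c.shape[axis] - 1:
            out.append(0.0)
            continue
        idx = list(ij)
        idx[axis] = i - 1
        cm = c[tuple(idx)]
        idx[axis] = i + 1
        cp = c[tuple(idx)]
        c0 = c[ij]
        if cm > 0 and c0 > 0 and cp > 0:
            lm, l0, lp = np.log([cm, c0, cp])
        else:
            lm, l0, lp = cm, c0, cp
        denom = lm - 2 * l0 + lp
        out.append(0.0 if denom == 0 else 0.5 * (lm - lp) / denom)
    return out[0], out[1]


def _norm_corr(ref_w: np.ndarray, mov_w: np.ndarray) -> np.ndarray | None:
    """Normalized circular cross-correlation, peak-centred; None if textureless."""
    ref_w = ref_w - ref_w.mean()
    mov_w = mov_w - mov_w.mean()
    s_ref = np.sqrt((ref_w ** 2).sum())
    s_mov = np.sqrt((mov_w ** 2).sum())
    if s_ref == 0 or s_mov == 0:
        return None
    corr = np.fft.ifft2(
        np.fft.fft2(mov_w) * np.conj(np.fft.fft2(ref_w))
    ).real
    return np.fft.fftshift(corr) / (s_ref * s_mov)


def piv(
    reference: np.ndarray,
    moving: np.ndarray,
    window_px: int = 32,
    step_px: int = 16,
    min_corr: float = 0.3,
    frame: int = 0,
) -> DisplacementField:
    """Two-pass block cross-correlation PIV between two bead images.

    Pass 1 estimates an integer displacement per interrogation window from
    the normalized circular cross-correlation; the integer field is validated
    against a 3x3 median (outliers replaced by the local median predictor).
    Pass 2 re-correlates each reference window against the moving window
    offset by the predictor — which removes the loss-of-pairs error — and
    refines the residual peak to sub-pixel accuracy with a 3-point Gaussian
    fit.  Nodes whose peak correlation falls below ``min_corr``, or whose
    windows carry no texture (e.g. bead-free), are masked (NaN), never zeroed.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving images must have the same shape")
    if window_px < 16:
        raise ValueError("window_px must be >= 16")
    h, w = reference.shape
    if window_px > min(h, w):
        raise ValueError("window_px larger than image")

    half = window_px // 2
    ys = np.arange(half, h - half + 1, step_px)
    xs = np.arange(half, w - half + 1, step_px)
    shape = (len(ys), len(xs))
    u0 = np.full(shape, np.nan)
    v0 = np.full(shape, np.nan)

    for iy, yc in enumerate(ys):
        for ix, xc in enumerate(xs):
            corr = _norm_corr(
                reference[yc - half: yc + half, xc - half: xc + half],
                moving[yc - half: yc + half, xc - half: xc + half],
            )
            if corr is None:
                continue
            ij = np.unravel_index(np.argmax(corr), corr.shape)
            v0[iy, ix] = ij[0] - half
            u0[iy, ix] = ij[1] - half

    # universal-median validation of the integer predictor field
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        u_med = ndimage.generic_filter(u0, np.nanmedian, size=3, mode="nearest")
        v_med = ndimage.generic_filter(v0, np.nanmedian, size=3, mode="nearest")
    good = np.isfinite(u_med)
    u0 = np.where(good & (np.abs(u0 - u_med) > 2), u_med, u0)
    v0 = np.where(good & (np.abs(v0 - v_med) > 2), v_med, v0)

    u = np.full(shape, np.nan)
    v = np.full(shape, np.nan)
    peak = np.zeros(shape)
    for iy, yc in enumerate(ys):
        for ix, xc in enumerate(xs):
            if not np.isfinite(u0[iy, ix]):
                continue
            # clamp the offset window to the image; the residual peak then
            # absorbs whatever part of the predictor could not be applied
            yo = int(np.clip(yc + round(v0[iy, ix]), half, h - half))
            xo = int(np.clip(xc + round(u0[iy, ix]), half, w - half))
            dy0, dx0 = yo - yc, xo - xc
            corr = _norm_corr(
                reference[yc - half: yc + half, xc - half: xc + half],
                moving[yo - half: yo + half, xo - half: xo + half],
            )
            if corr is None:
                continue
            ij = np.unravel_index(np.argmax(corr), corr.shape)
            p = corr[ij]
            peak[iy, ix] = p
            if p < min_corr:
                continue
            ry, rx = ij[0] - half, ij[1] - half
            # a residual beyond half the predictor search range means the
            # second pass locked onto a different structure: mask, not report
            if max(abs(ry - (round(v0[iy, ix]) - dy0)),
                   abs(rx - (round(u0[iy, ix]) - dx0))) > window_px // 4:
                continue
            sy, sx = _subpixel_offset(corr, ij)
            u[iy, ix] = dx0 + rx + sx
            v[iy, ix] = dy0 + ry + sy
    return DisplacementField(
        x=xs.astype(float), y=ys.astype(float), u=u, v=v, peak=peak, frame=frame
    )


def summed_vector_norm(
    fields: list[DisplacementField],
    pixel_size_um: float,
    frame_interval_s: float,
    stimulus_frame: int,
    post_window_frames: int | None = None,
) -> ContractionSummary:
    """Summed bead-displacement vector norms per frame and kinetic slopes.

    Every field is assumed measured against the initial (pre-contraction)
    frame, so the summed norm is a cumulative contraction readout.  Slopes
    before and after the stimulus frame come from ordinary least squares on
    summed norm vs time, mirroring the micropattern kinetics.
    """
    if len(fields) < 2:
        raise ValueError("need displacement fields for at least 2 frames")
    sums = np.full(len(fields), np.nan)
    for i, f in enumerate(fields):
        m = f.mask
        if m.any():
            sums[i] = np.nansum(f.norms()[m]) * pixel_size_um
    undefined = ~np.isfinite(sums)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} frame(s) have no valid PIV vectors",
            stacklevel=2,
        )
    time_s = np.arange(len(fields)) * frame_interval_s
    baseline_slope, post_slope = window_slopes(
        time_s, sums, stimulus_frame, post_window_frames
    )
    defined = np.isfinite(baseline_slope) and baseline_slope > 0 and np.isfinite(post_slope)
    ratio = post_slope / baseline_slope if defined else np.nan
    post = sums[stimulus_frame + 1:]
    max_c = float(np.nanmax(post)) if np.isfinite(post).any() else np.nan
    return ContractionSummary(
        time_s=time_s,
        summed_norm_um=sums,
        stimulus_frame=stimulus_frame,
        baseline_slope=float(baseline_slope),
        post_slope=float(post_slope),
        speed_ratio=float(ratio),
        speed_ratio_defined=bool(defined),
        max_contraction_um=max_c,
        undefined_frames=np.flatnonzero(undefined),
    )


# ---------------------------------------------------------------------------
# elastic half-space forward / inverse
# ---------------------------------------------------------------------------

def _greens_fourier(kx: np.ndarray, ky: np.ndarray, E: float, nu: float):
    """Components (Gxx, Gyy, Gxy) of the Boussinesq tensor in Fourier space."""
    k2 = kx ** 2 + ky ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k2 ** 1.5)
        gxx = pref * (k2 - nu * kx ** 2)
        gyy = pref * (k2 - nu * ky ** 2)
        gxy = -pref * nu * kx * ky
    zero = k2 == 0
    for g in (gxx, gyy, gxy):
        g[zero] = 0.0
    return gxx, gyy, gxy


def _pad_to_pow2(field: np.ndarray, factor: int = 2) -> tuple[np.ndarray, tuple]:
    """Zero-pad a 2-D field to the next power of two times ``factor``."""
    ny, nx = field.shape
    n = int(2 ** np.ceil(np.log2(max(ny, nx) * factor)))
    out = np.zeros((n, n))
    oy, ox = (n - ny) // 2, (n - nx) // 2
    out[oy: oy + ny, ox: ox + nx] = field
    return out, (oy, ox, ny, nx)


def forward_displacement(
    tx: np.ndarray,
    ty: np.ndarray,
    spacing_m: float,
    E_pa: float,
    nu: float,
    pad_factor: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Surface displacement (m) produced by a gridded traction field (Pa).

    Solves the forward Boussinesq problem in Fourier space on a zero-padded
    grid (the traction is compactly supported, so zero padding converts the
    circular convolution into the open-domain one).
    """
    if tx.shape != ty.shape:
        raise ValueError("tx and ty must share a shape")
    if not (E_pa > 0 and 0 < nu <= 0.5):
        raise ValueError("need E > 0 and 0 < nu <= 0.5")
    txp, (oy, ox, ny, nx) = _pad_to_pow2(tx, pad_factor)
    typ, _ = _pad_to_pow2(ty, pad_factor)
    n = txp.shape[0]
    k = 2 * np.pi * np.fft.fftfreq(n, d=spacing_m)
    kx, ky = np.meshgrid(k, k)
    gxx, gyy, gxy = _greens_fourier(kx, ky, E_pa, nu)
    ftx = np.fft.fft2(txp)
    fty = np.fft.fft2(typ)
    ux = np.fft.ifft2(gxx * ftx + gxy * fty).real
    uy = np.fft.ifft2(gxy * ftx + gyy * fty).real
    return ux[oy: oy + ny, ox: ox + nx], uy[oy: oy + ny, ox: ox + nx]


def _fill_gaps(x: np.ndarray, y: np.ndarray, comp: np.ndarray) -> np.ndarray:
    """Fill NaN nodes by linear interpolation (nearest at the hull border)."""
    mask = np.isfinite(comp)
    if mask.all():
        return comp
    if not mask.any():
        return np.zeros_like(comp)
    xx, yy = np.meshgrid(x, y)
    pts = np.column_stack([yy[mask], xx[mask]])
    vals = comp[mask]
    filled = interpolate.griddata(
        pts, vals, (yy, xx), method="linear"
    )
    still = ~np.isfinite(filled)
    if still.any():
        filled[still] = interpolate.griddata(
            pts, vals, (yy[still], xx[still]), method="nearest"
        )
    return filled


def fttc(
    field: DisplacementField,
    pixel_size_um: float,
    E_pa: float,
    nu: float = 0.5,
    regularization_lambda: float = 0.0,
    pad_factor: int = 4,
) -> TractionMap:
    """Recover the traction field (Pa) from a gridded displacement field.

    Masked nodes are filled by bilinear interpolation, the field is padded to
    a power of two with a zero-displacement taper, and G(k) is inverted per
    wave vector with 0th-order Tikhonov regularization ``lambda``:

        t(k) = (G^T G + lambda^2 I)^-1 G^T u(k).

    The zero-frequency traction is set to zero (global force balance).
    """
    if regularization_lambda < 0:
        raise ValueError("regularization_lambda must be >= 0")
    if not (E_pa > 0 and 0 < nu <= 0.5):
        raise ValueError("need E > 0 and 0 < nu <= 0.5")
    if len(field.x) > 1:
        steps = np.diff(field.x)
        if not np.allclose(steps, steps[0]):
            raise ValueError("displacement field must sit on a regular grid")
        spacing_px = float(steps[0])
    else:
        spacing_px = 1.0
    spacing_m = spacing_px * pixel_size_um * 1e-6
    scale = pixel_size_um * 1e-6  # px -> m

    ux = _fill_gaps(field.x, field.y, field.u) * scale
    uy = _fill_gaps(field.x, field.y, field.v) * scale

    uxp, (oy, ox, ny, nx) = _pad_to_pow2(ux, pad_factor)
    uyp, _ = _pad_to_pow2(uy, pad_factor)
    taper = _edge_taper(ny, nx)
    uxp[oy: oy + ny, ox: ox + nx] *= taper
    uyp[oy: oy + ny, ox: ox + nx] *= taper

    n = uxp.shape[0]
    k = 2 * np.pi * np.fft.fftfreq(n, d=spacing_m)
    kx, ky = np.meshgrid(k, k)
    gxx, gyy, gxy = _greens_fourier(kx, ky, E_pa, nu)
    fux = np.fft.fft2(uxp)
    fuy = np.fft.fft2(uyp)

    # per-k inversion of the symmetric 2x2 system (G^T G + l^2 I) t = G^T u
    lam2 = regularization_lambda ** 2
    axx = gxx * gxx + gxy * gxy + lam2
    ayy = gyy * gyy + gxy * gxy + lam2
    axy = gxy * (gxx + gyy)
    bx = gxx * fux + gxy * fuy
    by = gxy * fux + gyy * fuy
    det = axx * ayy - axy * axy
    with np.errstate(divide="ignore", invalid="ignore"):
        ftx = (ayy * bx - axy * by) / det
        fty = (axx * by - axy * bx) / det
    zero = (kx == 0) & (ky == 0)
    ftx[zero] = 0.0
    fty[zero] = 0.0
    bad = ~np.isfinite(ftx) | ~np.isfinite(fty)
    ftx[bad] = 0.0
    fty[bad] = 0.0
    tx = np.fft.ifft2(ftx).real[oy: oy + ny, ox: ox + nx]
    ty = np.fft.ifft2(fty).real[oy: oy + ny, ox: ox + nx]
    # re-impose exact force balance on the cropped window
    tx = tx - tx.mean()
    ty = ty - ty.mean()
    return TractionMap(
        x=field.x,
        y=field.y,
        tx=tx,
        ty=ty,
        substrate_E_pa=E_pa,
        substrate_nu=nu,
        regularization_lambda=regularization_lambda,
    )


def _edge_taper(ny: int, nx: int, frac: float = 0.1) -> np.ndarray:
    """Cosine taper to zero over the outer ``frac`` of each axis."""
    def ramp(n):
        m = max(2, int(round(n * frac)))
        r = np.ones(n)
        t = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
        r[:m] = t
        r[n - m:] = t[::-1]
        return r

    return np.outer(ramp(ny), ramp(nx))


def select_lambda(
    field: DisplacementField,
    pixel_size_um: float,
    E_pa: float,
    nu: float = 0.5,
    lambdas: np.ndarray | None = None,
) -> float:
    """Pick a Tikhonov parameter at the corner of a coarse L-curve.

    Evaluates the residual and solution norms over a log grid of lambda values
    and returns the lambda maximising the curvature of the log-log L-curve
    (coarse corner criterion).
    """
    if lambdas is None:
        # lambda shares units with G (m/Pa); centre the grid on the typical
        # magnitude of G at the grid scale
        spacing_m = float(np.diff(field.x)[0]) * pixel_size_um * 1e-6 \
            if len(field.x) > 1 else pixel_size_um * 1e-6
        g0 = 2 * (1 + nu) / (E_pa * (2 * np.pi / (spacing_m * len(field.x))))
        lambdas = g0 * np.logspace(-4, 1, 12)
    res = []
    sol = []
    for lam in lambdas:
        tm = fttc(field, pixel_size_um, E_pa, nu, regularization_lambda=lam)
        ux_hat, uy_hat = forward_displacement(
            tm.tx, tm.ty,
            (float(np.diff(field.x)[0]) if len(field.x) > 1 else 1.0)
            * pixel_size_um * 1e-6,
            E_pa, nu,
        )
        scale = pixel_size_um * 1e-6
        u0 = _fill_gaps(field.x, field.y, field.u) * scale
        v0 = _fill_gaps(field.x, field.y, field.v) * scale
        res.append(np.sqrt(np.mean((ux_hat - u0) ** 2 + (uy_hat - v0) ** 2)))
        sol.append(np.sqrt(np.mean(tm.tx ** 2 + tm.ty ** 2)))
    lr, ls = np.log(np.maximum(res, 1e-300)), np.log(np.maximum(sol, 1e-300))
    # discrete curvature of the L-curve
    best, best_k = -np.inf, 0
    for i in range(1, len(lambdas) - 1):
        v1 = np.array([lr[i] - lr[i - 1], ls[i] - ls[i - 1]])
        v2 = np.array([lr[i + 1] - lr[i], ls[i + 1] - ls[i]])
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        norm = np.linalg.norm(v1) * np.linalg.norm(v2)
        curv = cross / norm if norm > 0 else 0.0
        if curv > best:
            best, best_k = curv, i
    return float(lambdas[best_k])


# ---------------------------------------------------------------------------
# temporal colour coding
# ---------------------------------------------------------------------------

def temporal_color_code(
    stack,
    colormap: str = "jet",
    channel: int | str = 0,
) -> np.ndarray:
    """Assign each frame a colour and composite by per-channel maximum.

    Moving objects leave ordered-hue "comet tails"; static structures appear
    in a single blended hue.  Returns an ``(y, x, 3)`` float RGB array in
    [0, 1].
    """
    import matplotlib

    frames = stack.channel(channel).astype(float)
    if frames.shape[0] < 2:
        raise ValueError("temporal color code needs at least 2 frames")
    lo, hi = frames.min(), frames.max()
    norm = (frames - lo) / (hi - lo) if hi > lo else np.zeros_like(frames)
    cmap = matplotlib.colormaps[colormap]
    colors = cmap(np.linspace(0.0, 1.0, frames.shape[0]))[:, :3]
    rgb = np.zeros(frames.shape[1:] + (3,))
    for t in range(frames.shape[0]):
        layer = norm[t][..., None] * colors[t][None, None, :]
        rgb = np.maximum(rgb, layer)
    return rgb
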