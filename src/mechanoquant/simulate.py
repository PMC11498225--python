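"""Ground-truth-known synthetic fixtures for every pipeline stage.

Each generator emulates one input modality of the assays — contracting
cross-shaped micropatterns with a nuclear channel, bead fields displaced by a
known traction field through the elastic half-space forward model, Hertzian
force curves, two-compartment translocation images, calcium traces with a
contact-triggered rise, and log-linear dye-loading standard curves — and
returns the exact ground truth alongside the rendered data, so downstream
measurements can be validated without any raw microscopy data.

All generators are deterministic given their ``rng_seed``.  Noise is additive
Gaussian clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .hertz import ForceCurve, hertz_force
from .io import ImageStack
from .traction import forward_displacement

__all__ = [
    "FlecsSimSpec",
    "GaussianTraction",
    "BeadSimSpec",
    "BeadSimResult",
    "HertzSimSpec",
    "simulate_flecs_stack",
    "simulate_bead_pair",
    "simulate_force_curve",
    "simulate_translocation_image",
    "simulate_calcium_trace",
    "simulate_standard_curve",
    "simulate_wave_stack",
    "disk_mask",
    "disk_with_wedge",
]


# ---------------------------------------------------------------------------
# FLECS micropattern stacks
# ---------------------------------------------------------------------------

@dataclass
class FlecsSimSpec:
    """Conditions for a synthetic micropattern contraction movie.

    Geometry follows the assay substrate: cross-shaped patterns of 70 um
    tip-to-tip diagonal and 10 um bar thickness.  Occupied patterns shrink
    isotropically about their centroid, losing ``contraction_rate`` of their
    area per frame before the stimulus frame and ``contraction_rate *
    stimulus_multiplier`` after it, so the ground-truth area fraction is the
    closed-form piecewise product

        s(t) = (1 - k)^min(t, t0) * (1 - k m)^max(t - t0, 0).

    The default per-frame rate (0.001/frame, i.e. ~2% area over a 15-min
    baseline at 3-min frames) keeps the movie in the gradual-contraction
    regime where the slope-ratio kinetic readout is unbiased.
    """

    n_patterns: int = 12
    pattern_diagonal_um: float = 70.0
    bar_width_um: float = 10.0
    occupancy_fraction: float = 0.7
    contraction_rate: float = 0.001            # fraction of area lost per frame
    stimulus_multiplier: float = 3.0
    stimulus_frame: int = 15
    pixel_size_um: float = 0.8
    frame_interval_s: float = 180.0
    pattern_intensity: float = 200.0
    nuclear_intensity: float = 150.0
    background: float = 10.0
    psf_sigma_px: float = 1.0           # optical blur of the rendered patterns
    noise_sd: float = 2.0
    rng_seed: int = 0

    def validate(self, n_frames: int) -> None:
        if not 0 <= self.occupancy_fraction <= 1:
            raise ValueError("occupancy_fraction must be in [0, 1]")
        if self.n_patterns < 1:
            raise ValueError("need at least one pattern")
        if self.stimulus_multiplier < 1:
            raise ValueError("stimulus_multiplier must be >= 1")
        if not 0 <= self.contraction_rate < 1:
            raise ValueError("contraction_rate must be in [0, 1)")
        if self.contraction_rate * n_frames * self.stimulus_multiplier >= 1:
            raise ValueError(
                "contraction would drive the pattern area to zero; "
                "reduce contraction_rate, stimulus_multiplier or n_frames"
            )

    def area_fraction(self, t: np.ndarray | int) -> np.ndarray:
        """Closed-form ground-truth area fraction of an occupied pattern."""
        t = np.asarray(t, dtype=float)
        k, m, t0 = self.contraction_rate, self.stimulus_multiplier, self.stimulus_frame
        pre = np.minimum(t, t0)
        post = np.maximum(t - t0, 0.0)
        return (1.0 - k) ** pre * (1.0 - k * m) ** post


def _render_cross(
    canvas: np.ndarray,
    center: tuple[float, float],
    diagonal_px: float,
    width_px: float,
    angle_rad: float,
    scale: float,
    amplitude: float,
) -> None:
    """Add a rotated, isotropically scaled cross with 2x2 antialiasing."""
    cy, cx = center
    half = int(np.ceil(diagonal_px / 2)) + 3
    y0, y1 = max(0, int(cy) - half), min(canvas.shape[0], int(cy) + half + 1)
    x0, x1 = max(0, int(cx) - half), min(canvas.shape[1], int(cx) + half + 1)
    ys = np.arange(y0, y1, dtype=float)
    xs = np.arange(x0, x1, dtype=float)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    L, w = diagonal_px / 2.0, width_px / 2.0
    sub = (np.arange(4) - 1.5) / 4.0
    coverage = np.zeros((y1 - y0, x1 - x0))
    for oy in sub:
        for ox in sub:
            dy = (ys + oy - cy)[:, None]
            dx = (xs + ox - cx)[None, :]
            u = (c * dx + s * dy) / scale
            v = (-s * dx + c * dy) / scale
            inside = ((np.abs(u) <= L) & (np.abs(v) <= w)) | (
                (np.abs(u) <= w) & (np.abs(v) <= L)
            )
            coverage += inside
    canvas[y0:y1, x0:x1] += amplitude * coverage / 16.0


def simulate_flecs_stack(
    spec: FlecsSimSpec, n_frames: int = 40
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a two-channel micropattern movie with known contraction.

    Channel 0 is the fluorescent pattern, channel 1 the nuclear stain;
    occupied patterns carry a nuclear blob at their centroid and shrink with
    the closed-form area fraction; unoccupied patterns are static and have no
    nuclear signal.

    Returns the stack and a ground-truth table with one row per
    (pattern, frame): pattern id, occupancy, centroid and exact area
    fraction.
    """
    spec.validate(n_frames)
    rng = np.random.default_rng(spec.rng_seed)
    px = spec.pixel_size_um
    diag_px = spec.pattern_diagonal_um / px
    width_px = spec.bar_width_um / px

    n_cols = int(np.ceil(np.sqrt(spec.n_patterns)))
    n_rows = int(np.ceil(spec.n_patterns / n_cols))
    spacing = diag_px * 1.35
    margin = diag_px / 2 + 8
    h = int(np.ceil(2 * margin + (n_rows - 1) * spacing))
    w = int(np.ceil(2 * margin + (n_cols - 1) * spacing))

    centers = []
    for i in range(spec.n_patterns):
        r, c = divmod(i, n_cols)
        jitter = rng.uniform(-2, 2, size=2)
        centers.append((margin + r * spacing + jitter[0],
                        margin + c * spacing + jitter[1]))
    angles = rng.uniform(0, np.pi / 2, size=spec.n_patterns)
    n_occ = int(round(spec.occupancy_fraction * spec.n_patterns))
    occupied = np.zeros(spec.n_patterns, dtype=bool)
    occupied[rng.permutation(spec.n_patterns)[:n_occ]] = True

    t_idx = np.arange(n_frames)
    s_area = spec.area_fraction(t_idx)
    s_lin = np.sqrt(s_area)

    frames = np.zeros((n_frames, 2, h, w), dtype=np.float32)
    # the nuclear channel is static: render once, add per-frame noise only
    nuc_base = np.full((h, w), spec.background / 2, dtype=float)
    for i, (cy, cx) in enumerate(centers):
        if not occupied[i]:
            continue
        half = 20
        y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        ys = np.arange(y0, y1)[:, None]
        xs = np.arange(x0, x1)[None, :]
        r2 = (ys - cy) ** 2 + (xs - cx) ** 2
        nuc_base[y0:y1, x0:x1] += spec.nuclear_intensity * np.exp(
            -r2 / (2 * 6.0 ** 2)
        )
    truth_rows = []
    for t in range(n_frames):
        pat = np.full((h, w), spec.background, dtype=float)
        for i, (cy, cx) in enumerate(centers):
            scale = s_lin[t] if occupied[i] else 1.0
            _render_cross(
                pat, (cy, cx), diag_px, width_px, angles[i], scale,
                spec.pattern_intensity - spec.background,
            )
            truth_rows.append(
                dict(
                    pattern_id=i,
                    frame=t,
                    occupied=bool(occupied[i]),
                    centroid_y=cy,
                    centroid_x=cx,
                    area_fraction=float(s_area[t]) if occupied[i] else 1.0,
                )
            )
        if spec.psf_sigma_px > 0:
            # optical blur: the 50%-intensity contour of a blurred step edge
            # sits on the true boundary, so binarized areas stay faithful
            pat = ndimage.gaussian_filter(pat, spec.psf_sigma_px)
        nuc = nuc_base
        if spec.noise_sd > 0:
            pat = pat + rng.normal(0, spec.noise_sd, pat.shape)
            nuc = nuc + rng.normal(0, spec.noise_sd, nuc.shape)
        frames[t, 0] = np.clip(pat, 0, None)
        frames[t, 1] = np.clip(nuc, 0, None)

    stack = ImageStack(
        frames=frames,
        pixel_size_um=spec.pixel_size_um,
        frame_interval_s=spec.frame_interval_s,
        channel_names=["pattern", "nuclear"],
    )
    truth = pd.DataFrame(truth_rows)
    return stack, truth


# ---------------------------------------------------------------------------
# bead fields on an elastic surface
# ---------------------------------------------------------------------------

@dataclass
class GaussianTraction:
    """A Gaussian traction patch: centre (px), peak stress (Pa), width (px)."""

    x_px: float
    y_px: float
    tx_pa: float
    ty_pa: float
    sigma_px: float = 6.0


@dataclass
class BeadSimSpec:
    """Conditions for a reference/displaced bead image pair.

    The substrate defaults mirror the soft collagen gels used for the bead
    assay (E = 200 Pa, i.e. 0.2 kPa, incompressible); displacements follow
    the Boussinesq half-space forward model from the listed traction patches,
    or a direct uniform shift when ``uniform_shift_px`` is set (bypassing
    elasticity, for calibrating the displacement estimator).
    """

    n_beads: int = 800
    field_size_px: int = 256
    bead_sigma_px: float = 1.5
    bead_amplitude: float = 120.0
    tractions: list[GaussianTraction] = field(default_factory=list)
    uniform_shift_px: tuple[float, float] | None = None   # (dy, dx)
    substrate_E_pa: float = 200.0
    substrate_nu: float = 0.5
    pixel_size_um: float = 0.5
    background: float = 5.0
    noise_sd: float = 1.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_beads < 1 or self.field_size_px < 32:
            raise ValueError("need beads and a field of at least 32 px")
        for tr in self.tractions:
            if not (0 <= tr.x_px < self.field_size_px
                    and 0 <= tr.y_px < self.field_size_px):
                raise ValueError("traction patch centre outside the field")
            if not np.isfinite([tr.tx_pa, tr.ty_pa]).all():
                raise ValueError("traction magnitudes must be finite")
        if not (self.substrate_E_pa > 0 and 0 < self.substrate_nu <= 0.5):
            raise ValueError("need E > 0 and 0 < nu <= 0.5")


@dataclass
class BeadSimResult:
    reference: np.ndarray
    moving: np.ndarray
    ux_px: np.ndarray        # displacement sampled on the pixel grid
    uy_px: np.ndarray
    tx_pa: np.ndarray
    ty_pa: np.ndarray
    bead_positions: np.ndarray       # (n, 2) as (y, x)
    spec: BeadSimSpec


def _render_beads(
    size: int, positions: np.ndarray, amplitudes: np.ndarray, sigma: float,
    background: float,
) -> np.ndarray:
    img = np.full((size, size), background, dtype=float)
    half = int(np.ceil(4 * sigma))
    for (y, x), a in zip(positions, amplitudes):
        iy, ix = int(round(y)), int(round(x))
        y0, y1 = max(0, iy - half), min(size, iy + half + 1)
        x0, x1 = max(0, ix - half), min(size, ix + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        ys = np.arange(y0, y1)[:, None]
        xs = np.arange(x0, x1)[None, :]
        img[y0:y1, x0:x1] += a * np.exp(
            -((ys - y) ** 2 + (xs - x) ** 2) / (2 * sigma ** 2)
        )
    return img


def traction_grids(spec: BeadSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the summed Gaussian traction patches on the pixel grid (Pa)."""
    n = spec.field_size_px
    tx = np.zeros((n, n))
    ty = np.zeros((n, n))
    yy, xx = np.mgrid[0:n, 0:n]
    for tr in spec.tractions:
        g = np.exp(
            -((yy - tr.y_px) ** 2 + (xx - tr.x_px) ** 2) / (2 * tr.sigma_px ** 2)
        )
        tx += tr.tx_pa * g
        ty += tr.ty_pa * g
    return tx, ty


def simulate_bead_pair(spec: BeadSimSpec) -> BeadSimResult:
    """Reference and displaced bead images with exact displacement field.

    Bead centres are displaced individually (no image warping), so any
    estimation error downstream is attributable to the displacement
    estimator, not to rendering.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.field_size_px

    if spec.uniform_shift_px is not None:
        dy, dx = spec.uniform_shift_px
        ux = np.full((n, n), float(dx))
        uy = np.full((n, n), float(dy))
        tx = np.zeros((n, n))
        ty = np.zeros((n, n))
    else:
        tx, ty = traction_grids(spec)
        ux_m, uy_m = forward_displacement(
            tx, ty, spec.pixel_size_um * 1e-6,
            spec.substrate_E_pa, spec.substrate_nu,
        )
        ux = ux_m / (spec.pixel_size_um * 1e-6)
        uy = uy_m / (spec.pixel_size_um * 1e-6)

    margin = 4.0
    positions = rng.uniform(margin, n - margin, size=(spec.n_beads, 2))
    amplitudes = spec.bead_amplitude * rng.uniform(0.7, 1.3, size=spec.n_beads)

    u_at = ndimage.map_coordinates(ux, positions.T, order=1, mode="nearest")
    v_at = ndimage.map_coordinates(uy, positions.T, order=1, mode="nearest")
    displaced = positions + np.column_stack([v_at, u_at])

    ref = _render_beads(n, positions, amplitudes, spec.bead_sigma_px,
                        spec.background)
    mov = _render_beads(n, displaced, amplitudes, spec.bead_sigma_px,
                        spec.background)
    if spec.noise_sd > 0:
        ref = ref + rng.normal(0, spec.noise_sd, ref.shape)
        mov = mov + rng.normal(0, spec.noise_sd, mov.shape)
    return BeadSimResult(
        reference=np.clip(ref, 0, None),
        moving=np.clip(mov, 0, None),
        ux_px=ux,
        uy_px=uy,
        tx_pa=tx,
        ty_pa=ty,
        bead_positions=positions,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Hertz force curves
# ---------------------------------------------------------------------------

@dataclass
class HertzSimSpec:
    """Conditions for a synthetic indentation curve.

    Defaults follow the AFM protocol scale: 0.1 N/m cantilevers indenting
    cells of a few kPa by up to ~1 um.
    """

    true_E_pa: float = 1e4
    tip_radius_m: float = 1e-6
    poisson_nu: float = 0.5
    contact_point_m: float = 1e-6
    z_range_m: tuple[float, float] = (0.0, 3e-6)
    noise_sd_n: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if not (self.true_E_pa > 0 and self.tip_radius_m > 0):
            raise ValueError("modulus and tip radius must be positive")
        if not 0 <= self.poisson_nu <= 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5]")
        if self.z_range_m[1] <= self.z_range_m[0]:
            raise ValueError("z range must be increasing")


def simulate_force_curve(spec: HertzSimSpec, n_points: int = 200) -> ForceCurve:
    """Hertzian approach curve: zero force before contact, F(delta) after."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    z = np.linspace(*spec.z_range_m, n_points)
    delta = z - spec.contact_point_m
    f = hertz_force(spec.true_E_pa, spec.tip_radius_m, spec.poisson_nu, delta)
    if spec.noise_sd_n > 0:
        f = f + rng.normal(0, spec.noise_sd_n, f.shape)
    return ForceCurve(z_m=z, force_n=f)


# ---------------------------------------------------------------------------
# translocation images
# ---------------------------------------------------------------------------

def simulate_translocation_image(
    nuclear_mfi: float,
    cyto_mfi: float,
    cell_radius_px: int = 60,
    nucleus_radius_px: int = 25,
    size_px: int = 160,
    background: float = 5.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> tuple[ImageStack, dict]:
    """Disk nucleus inside a larger disk cell with stated compartment means.

    Channel 0 carries the marker (``cyto_mfi`` in the cytoplasm ring,
    ``nuclear_mfi`` in the nucleus, ``background`` outside the cell) and
    channel 1 a DAPI-like nuclear stain.  The ground-truth dict includes the
    compartment masks and the exact nuclear/cytoplasmic ratio.
    """
    if nuclear_mfi < 0 or cyto_mfi < 0:
        raise ValueError("MFI values must be non-negative")
    if nucleus_radius_px >= cell_radius_px:
        raise ValueError("nucleus must fit inside the cell")
    rng = np.random.default_rng(rng_seed)
    c = size_px / 2.0 - 0.5
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    cell = r2 <= cell_radius_px ** 2
    nucleus = r2 <= nucleus_radius_px ** 2
    marker = np.full((size_px, size_px), background, dtype=float)
    marker[cell] = cyto_mfi
    marker[nucleus] = nuclear_mfi
    dapi = np.full((size_px, size_px), background, dtype=float)
    dapi[nucleus] = 180.0
    if noise_sd > 0:
        marker = marker + rng.normal(0, noise_sd, marker.shape)
        dapi = dapi + rng.normal(0, noise_sd, dapi.shape)
    frames = np.stack([
        np.clip(marker, 0, None), np.clip(dapi, 0, None)
    ])[np.newaxis]
    stack = ImageStack(
        frames=frames.astype(np.float32),
        pixel_size_um=0.3,
        frame_interval_s=1.0,
        channel_names=["marker", "dapi"],
    )
    truth = dict(
        cell_mask=cell,
        nuclear_mask=nucleus,
        nuclear_mfi=nuclear_mfi,
        cyto_mfi=cyto_mfi,
        ratio=np.nan if cyto_mfi == 0 else nuclear_mfi / cyto_mfi,
        background=background,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# calcium traces, standard curves, wave stacks
# ---------------------------------------------------------------------------

def simulate_calcium_trace(
    baseline: float,
    rise_frame: int,
    fold_change: float,
    n_frames: int,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    tau_frames: float = 2.0,
) -> np.ndarray:
    """Flat baseline, then a saturating rise to ``baseline * fold_change``.

    The rise is exponential-saturating with time constant ``tau_frames``,
    emulating a contact-triggered calcium transient plateau.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if fold_change < 1:
        raise ValueError("fold_change must be >= 1")
    rng = np.random.default_rng(rng_seed)
    t = np.arange(n_frames, dtype=float)
    rise = np.where(
        t < rise_frame, 0.0, 1.0 - np.exp(-(t - rise_frame) / tau_frames)
    )
    trace = baseline * (1.0 + (fold_change - 1.0) * rise)
    if noise_sd > 0:
        trace = trace + rng.normal(0, noise_sd, trace.shape)
    return np.clip(trace, 0, None)


def simulate_standard_curve(
    loadings_um,
    slope: float,
    intercept: float,
    noise_frac: float = 0.0,
    rng_seed: int = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Log-linear loading standards: MFI = intercept + slope*log10(c).

    ``noise_frac`` applies multiplicative Gaussian noise per replicate
    measurement (e.g. 0.05 for 5% CV).
    """
    loadings = np.asarray(loadings_um, dtype=float)
    if np.any(loadings <= 0):
        raise ValueError("loading concentrations must be positive")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for c in loadings:
        mfi0 = intercept + slope * np.log10(c)
        for _ in range(n_replicates):
            mfi = mfi0 * (1.0 + rng.normal(0, noise_frac)) if noise_frac > 0 else mfi0
            rows.append(dict(concentration_um=c, mfi=mfi))
    return pd.DataFrame(rows)


def simulate_wave_stack(
    n_frames: int = 30,
    size_px: int = 80,
    speed_px_per_frame: float = 2.0,
    front_sigma_px: float = 3.0,
    background: float = 5.0,
    amplitude: float = 100.0,
    frame_interval_s: float = 5.0,
) -> ImageStack:
    """A bright front sweeping along x at a known speed (kymograph fixture)."""
    frames = np.zeros((n_frames, 1, size_px, size_px), dtype=np.float32)
    xs = np.arange(size_px, dtype=float)
    for t in range(n_frames):
        x0 = 5.0 + speed_px_per_frame * t
        profile = background + amplitude * np.exp(
            -((xs - x0) ** 2) / (2 * front_sigma_px ** 2)
        )
        frames[t, 0] = profile[None, :]
    return ImageStack(
        frames=frames, pixel_size_um=0.5, frame_interval_s=frame_interval_s,
        channel_names=["gcamp"],
    )


# ---------------------------------------------------------------------------
# mask fixtures for shape metrics
# ---------------------------------------------------------------------------

def disk_mask(radius_px: int, size_px: int | None = None) -> np.ndarray:
    """Rasterized disk (pixel centres inside the circle)."""
    if size_px is None:
        size_px = 2 * radius_px + 11
    c = size_px / 2.0 - 0.5
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px ** 2


def disk_with_wedge(
    radius_px: int, wedge_angle_rad: float, wedge_depth_frac: float = 1.0,
    size_px: int | None = None, wedge_direction_rad: float = 0.0,
) -> np.ndarray:
    """Disk with a radial wedge bite removed — a local-retraction fixture."""
    if not 0 <= wedge_angle_rad < 2 * np.pi:
        raise ValueError("wedge angle must be in [0, 2*pi)")
    mask = disk_mask(radius_px, size_px)
    size = mask.shape[0]
    c = size / 2.0 - 0.5
    yy, xx = np.mgrid[0:size, 0:size]
    theta = np.mod(np.arctan2(yy - c, xx - c) - wedge_direction_rad
                   + wedge_angle_rad / 2, 2 * np.pi)
    r = np.hypot(yy - c, xx - c)
    wedge = (theta <= wedge_angle_rad) & (
        r >= (1 - wedge_depth_frac) * radius_px
    )
    return mask & ~wedge
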