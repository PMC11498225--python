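"""Hertz-model fitting of AFM indentation force curves.

For a spherical probe of radius R indenting an elastic sample with Young's
modulus E and Poisson ratio v, the normal force at indentation depth d is

    F = (4/3) * E * sqrt(R) * d^(3/2) / (1 - v^2).

Fitting jointly estimates E and the contact point from an approach force
curve; grids of curves yield a Young's-modulus map.  A four-sided-pyramid
variant (F proportional to d^2) is available behind a model flag for
pyramidal cantilever tips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "ForceCurve",
    "HertzFit",
    "ModulusMap",
    "hertz_force",
    "pyramid_force",
    "fit_hertz",
    "modulus_map",
]


def hertz_force(E_pa: float, R_m: float, nu: float, delta_m) -> np.ndarray:
    """Spherical-probe Hertz contact force (N) at indentation depth delta (m).

    Vectorized over ``delta_m``; negative depths (no contact) give zero force.
    """
    if E_pa <= 0 or R_m <= 0:
        raise ValueError("E and R must be positive")
    if not 0 <= nu < 1:
        raise ValueError("Poisson ratio must be in [0, 1)")
    delta = np.maximum(np.asarray(delta_m, dtype=float), 0.0)
    return (4.0 / 3.0) * E_pa * np.sqrt(R_m) * delta ** 1.5 / (1.0 - nu ** 2)


def pyramid_force(E_pa: float, half_angle_rad: float, nu: float, delta_m) -> np.ndarray:
    """Four-sided pyramidal indenter force (N): F = 0.7453 E tan(a) d^2 / (1-v^2)."""
    if E_pa <= 0 or not 0 < half_angle_rad < np.pi / 2:
        raise ValueError("need E > 0 and a half angle in (0, pi/2)")
    delta = np.maximum(np.asarray(delta_m, dtype=float), 0.0)
    return 0.7453 * E_pa * np.tan(half_angle_rad) * delta ** 2 / (1.0 - nu ** 2)


@dataclass
class ForceCurve:
    """Approach segment of an indentation curve: z position (m) vs force (N).

    ``z_m`` increases with indentation depth (sample-ward) and must be
    strictly monotone.
    """

    z_m: np.ndarray
    force_n: np.ndarray

    def __post_init__(self) -> None:
        self.z_m = np.asarray(self.z_m, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        if self.z_m.shape != self.force_n.shape or self.z_m.ndim != 1:
            raise ValueError("z and force must be matching 1-D arrays")
        dz = np.diff(self.z_m)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")
        if not np.all(np.isfinite(self.force_n)):
            raise ValueError("forces must be finite")

    def ascending(self) -> "ForceCurve":
        if self.z_m[0] > self.z_m[-1]:
            return ForceCurve(self.z_m[::-1].copy(), self.force_n[::-1].copy())
        return self


@dataclass
class HertzFit:
    """Result of a Hertz fit; ``summary()`` prints a compact report."""

    E_pa: float
    contact_point_m: float
    R_m: float
    nu: float
    residual_rms_n: float
    delta_m: np.ndarray = field(repr=False, default=None)
    success: bool = True
    message: str = "ok"
    model: str = "sphere"

    @property
    def E_kpa(self) -> float:
        return self.E_pa / 1e3

    def predict(self, z_m: np.ndarray) -> np.ndarray:
        delta = np.asarray(z_m, dtype=float) - self.contact_point_m
        if self.model == "sphere":
            return hertz_force(self.E_pa, self.R_m, self.nu, delta)
        return pyramid_force(self.E_pa, self.R_m, self.nu, delta)

    def summary(self) -> str:
        lines = [
            "Hertz indentation fit",
            "---------------------",
            f"model           : {self.model}",
            f"status          : {'converged' if self.success else 'FAILED'}"
            + ("" if self.success else f" ({self.message})"),
            f"Young's modulus : {self.E_pa:.4g} Pa ({self.E_kpa:.4g} kPa)",
            f"contact point   : {self.contact_point_m:.4g} m",
            f"probe radius    : {self.R_m:.4g} m",
            f"Poisson ratio   : {self.nu:.3g}",
            f"residual RMS    : {self.residual_rms_n:.4g} N",
        ]
        return "\n".join(lines)


@dataclass
class ModulusMap:
    """Grid of fitted Young's moduli (kPa); NaN where the fit failed."""

    E_kpa: np.ndarray
    failed: np.ndarray

    @property
    def n_failed(self) -> int:
        return int(self.failed.sum())


def fit_hertz(
    curve: ForceCurve,
    R_m: float,
    nu: float = 0.5,
    spring_constant_n_per_m: float | None = None,
    model: str = "sphere",
    min_points: int = 20,
    snr_gate: float = 5.0,
) -> HertzFit:
    """Joint nonlinear least-squares estimate of (E, contact point).

    The model is piecewise: zero force before contact, the Hertz (or pyramid)
    law after, with indentation depth ``delta = z - z_c``; when a cantilever
    spring constant is supplied, delta is corrected for cantilever deflection
    as ``delta = (z - z_c) - F/k``.  Curves whose maximal force never clears
    ``snr_gate`` baseline noise SDs, or whose fit residual stays at the noise
    floor, come back as failures rather than spurious moduli.
    """
    curve = curve.ascending()
    z, f = curve.z_m, curve.force_n
    if len(z) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(z)}")

    n_base = max(5, len(z) // 5)
    noise_sd = max(float(np.std(f[:n_base], ddof=1)), 1e-18)
    f_span = float(f.max() - np.median(f[:n_base]))
    if f_span < snr_gate * noise_sd:
        return HertzFit(
            E_pa=np.nan, contact_point_m=np.nan, R_m=R_m, nu=nu,
            residual_rms_n=noise_sd, delta_m=None, success=False,
            message="no indentation region above the noise floor",
            model=model,
        )

    exponent = 1.5 if model == "sphere" else 2.0

    def delta_of(zc):
        d = z - zc
        if spring_constant_n_per_m is not None:
            d = d - f / spring_constant_n_per_m
        return np.maximum(d, 0.0)

    def basis(zc):
        # force is linear in E at fixed contact point: F = E * g(delta)
        d = delta_of(zc)
        if model == "sphere":
            return (4.0 / 3.0) * np.sqrt(R_m) * d ** exponent / (1 - nu ** 2)
        return 0.7453 * np.tan(R_m) * d ** exponent / (1 - nu ** 2)

    def profile_rss(zc):
        g = basis(zc)
        gg = float(g @ g)
        if gg == 0:
            return float(f @ f), 0.0
        E = max(float(g @ f) / gg, 0.0)
        r = E * g - f
        return float(r @ r), E

    # coarse grid over candidate contact points, then local refinement;
    # the 1-D profile is far more robust than a joint 2-D descent across
    # the kink at delta = 0
    lo, hi = z[0], z[-2]
    grid = np.linspace(lo, hi, 101)
    rss = np.array([profile_rss(zc)[0] for zc in grid])
    i0 = int(np.argmin(rss))
    a = grid[max(0, i0 - 1)]
    b = grid[min(len(grid) - 1, i0 + 1)]
    res = optimize.minimize_scalar(
        lambda zc: profile_rss(zc)[0], bounds=(a, b), method="bounded",
        options={"xatol": (z[1] - z[0]) * 1e-6},
    )
    zc_hat = float(res.x)
    _, E_hat = profile_rss(zc_hat)
    rms = float(np.sqrt(res.fun / len(f)))
    success = np.isfinite(E_hat) and E_hat > 0
    msg = "ok" if success else "degenerate fit (non-positive modulus)"
    return HertzFit(
        E_pa=E_hat,
        contact_point_m=zc_hat,
        R_m=R_m,
        nu=nu,
        residual_rms_n=rms,
        delta_m=delta_of(zc_hat),
        success=success,
        message=msg,
        model=model,
    )


def modulus_map(
    curves: list[list[ForceCurve]],
    R_m: float,
    nu: float = 0.5,
    **fit_kwargs,
) -> ModulusMap:
    """Fit every curve of a rectangular scan grid; failed fits are masked."""
    ny = len(curves)
    nx = len(curves[0])
    E = np.full((ny, nx), np.nan)
    failed = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        if len(curves[i]) != nx:
            raise ValueError("scan grid rows must have equal length")
        for j in range(nx):
            fit = fit_hertz(curves[i][j], R_m, nu, **fit_kwargs)
            if fit.success:
                E[i, j] = fit.E_kpa
            else:
                failed[i, j] = True
    if failed.all():
        warnings.warn("all fits failed; modulus map fully masked", stacklevel=2)
    return ModulusMap(E_kpa=E, failed=failed)
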