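"""Brownian-dynamics simulator for line-scan carpets, 2D time series and 3D fields.

Synthetic stand-in for live-cell acquisitions, with full ground truth so
every downstream stage (correlation, FCS fitting, N&B, zoning,
segmentation) can be validated by parameter recovery:

* **Carpets** — point emitters diffuse in the scan plane (x along the
  scanned line, y lateral) with per-species diffusion coefficient,
  brightness, optional drift and an optional semi-permeable barrier (a
  nuclear-envelope stand-in) at a fixed column.  A Gaussian PSF samples
  the line once per line period; counts are Poisson.  A static Gaussian
  stripe can be rendered into one channel to emulate a lamin marker.
* **2D co-transport stacks** — two-channel image time series in which a
  configurable fraction of particles emit in both channels and share a
  trajectory, the rest being independent single-channel particles.
* **3D sphere fields** — non-overlapping solid spheres around an
  ellipsoidal nucleus mask, with a ground-truth table of voxelized
  volumes and signed distances to the nucleus surface.

Trajectories advance once per line (dwell time is negligible against the
line period, the standard line-scan FCS approximation).  Field ends wrap
periodically; when a barrier is present the x boundaries reflect instead,
since a single barrier on a periodic domain would not separate the field
into two compartments.  An expectation mode replaces Poisson sampling by
the expected rate for deterministic tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from numba import njit

from carpetfcs.carpet_io import ImageStack, ImageStack3D, LineScanCarpet

__all__ = [
    "SpeciesSpec",
    "BarrierSpec",
    "LaminaSpec",
    "SimulationConfig",
    "PlacementError",
    "simulate_carpet",
    "simulate_trajectories",
    "simulate_cotransport_stack",
    "simulate_sphere_field",
    "SphereField",
    "expected_mean_intensity",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping sphere placement fails within bounded retries."""


@dataclass
class SpeciesSpec:
    """One diffusing emitter species.

    ``brightness_cpsm`` is the mean counts per line sampling from one
    molecule sitting at the PSF center.  ``channel_weights`` splits the
    emission across the two detection channels (``(1, 0)`` single-channel,
    ``(0.5, 0.5)`` a dual-labelled, co-transported species).
    ``mobile_fraction`` < 1 leaves a subset of particles frozen in place,
    emulating arrested endosome-like aggregates.
    """

    D_um2_per_s: float
    brightness_cpsm: float
    n_particles: int
    velocity_um_per_s: float = 0.0
    channel_weights: tuple[float, float] = (1.0, 0.0)
    mobile_fraction: float = 1.0
    initial_positions_um: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.initial_positions_um is not None:
            pos = tuple((float(x), float(y)) for x, y in self.initial_positions_um)
            if len(pos) != self.n_particles:
                raise ValueError("initial_positions_um must list one (x, y) per particle")
            self.initial_positions_um = pos
        if self.D_um2_per_s < 0:
            raise ValueError(f"D must be >= 0, got {self.D_um2_per_s}")
        if self.brightness_cpsm < 0:
            raise ValueError("brightness must be >= 0")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        w = tuple(float(x) for x in self.channel_weights)
        if len(w) != 2 or min(w) < 0 or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"channel_weights must be 2 non-negative weights summing to 1, got {w}")
        self.channel_weights = w
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")


@dataclass
class BarrierSpec:
    """Semi-permeable vertical barrier at a pixel column.

    Each trajectory step that would cross (or enter) the barrier passes
    with ``crossing_probability`` (Bernoulli per encounter) and is
    mirrored back otherwise; 0 models an impermeable envelope, 1 no
    barrier.  ``thickness_um`` gives the barrier a finite
    particle-excluded slab (a nuclear envelope is a double membrane plus
    lamina meshwork, not a zero-width plane): particles reflect at the
    near face and transmitted particles emerge beyond the far face.
    """

    position_px: int
    crossing_probability: float
    thickness_um: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossing_probability <= 1.0:
            raise ValueError("crossing_probability must be in [0, 1]")
        if self.position_px < 0:
            raise ValueError("position_px must be >= 0")
        if self.thickness_um < 0:
            raise ValueError("thickness_um must be >= 0")


@dataclass
class LaminaSpec:
    """Static Gaussian stripe rendered into one channel (lamin-marker stand-in)."""

    position_px: float
    width_px: float
    amplitude: float
    channel: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.amplitude < 0:
            raise ValueError("lamina width must be > 0 and amplitude >= 0")


@dataclass
class SimulationConfig:
    """Full description of one synthetic line-scan acquisition.

    Defaults follow the acquisition regime of the study this package
    models: 41 nm pixels, 2 µs dwell, 32,000 lines at 1.5 ms per line
    (~48 s total), and a ~0.25 µm 1/e² PSF waist.
    """

    species: list[SpeciesSpec] = field(default_factory=list)
    n_pixels: int = 256
    n_lines: int = 32000
    pixel_size_nm: float = 41.0
    line_period_ms: float = 1.5
    dwell_time_us: float = 2.0
    psf_waist_nm: float = 250.0
    field_length_um: float | None = None
    field_depth_um: float = 12.0
    barrier: BarrierSpec | None = None
    background_rate: float = 0.0
    lamina_channel: LaminaSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pixels <= 0 or self.n_lines <= 0:
            raise ValueError("n_pixels and n_lines must be positive")
        if self.field_length_um is None:
            self.field_length_um = self.n_pixels * self.pixel_size_nm * 1e-3
        if self.n_pixels * self.pixel_size_nm > self.field_length_um * 1000 + 1e-6:
            raise ValueError(
                "scanned extent n_pixels*pixel_size_nm exceeds field_length_um"
            )
        for key in ("pixel_size_nm", "line_period_ms", "dwell_time_us", "psf_waist_nm",
                    "field_depth_um"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.barrier is not None and self.barrier.position_px >= self.n_pixels:
            raise ValueError("barrier position_px must lie inside the scanned line")

    @property
    def line_period_s(self) -> float:
        return self.line_period_ms * 1e-3

    @property
    def scan_extent_um(self) -> float:
        return self.n_pixels * self.pixel_size_nm * 1e-3

    @property
    def idealized_scanner(self) -> bool:
        """True when the line period is shorter than the summed pixel dwells."""
        return self.line_period_ms * 1000.0 < self.n_pixels * self.dwell_time_us

    def to_dict(self) -> dict[str, Any]:
        import dataclasses

        d = dataclasses.asdict(self)
        d["idealized_scanner"] = self.idealized_scanner
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        d = dict(d)
        d.pop("idealized_scanner", None)
        d["species"] = [
            s if isinstance(s, SpeciesSpec) else SpeciesSpec(**{**s, "channel_weights": tuple(s.get("channel_weights", (1.0, 0.0)))})
            for s in d.get("species", [])
        ]
        if d.get("barrier") is not None and not isinstance(d["barrier"], BarrierSpec):
            d["barrier"] = BarrierSpec(**d["barrier"])
        if d.get("lamina_channel") is not None and not isinstance(d["lamina_channel"], LaminaSpec):
            d["lamina_channel"] = LaminaSpec(**d["lamina_channel"])
        return cls(**d)


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _evolve_kernel(x0, y0, sx, sy, drift_dx, mobile, Lx, Ly,
                   has_barrier, xb, half_thick, p_cross, u, reflect_x, xs, ys):
    n_lines = xs.shape[0]
    n = xs.shape[1]
    for i in range(n):
        xs[0, i] = x0[i]
        ys[0, i] = y0[i]
    for t in range(1, n_lines):
        for i in range(n):
            if not mobile[i]:
                xs[t, i] = xs[t - 1, i]
                ys[t, i] = ys[t - 1, i]
                continue
            old = xs[t - 1, i]
            nx = old + sx[t - 1, i] + drift_dx
            ny = ys[t - 1, i] + sy[t - 1, i]
            ny = ny % Ly
            if has_barrier:
                side = 1.0 if old > xb else -1.0
                near_face = xb + side * half_thick
                # attempt = step would enter the slab or cross to the far side
                if (nx - near_face) * side < 0.0:
                    if u[t - 1, i] < p_cross:
                        nx = nx - side * 2.0 * half_thick  # emerge past far face
                    else:
                        nx = 2.0 * near_face - nx          # reflect at near face
            if reflect_x:
                for _ in range(8):
                    if nx < 0.0:
                        nx = -nx
                    elif nx > Lx:
                        nx = 2.0 * Lx - nx
                    else:
                        break
            else:
                nx = nx % Lx
            xs[t, i] = nx
            ys[t, i] = ny
    return xs


@njit(cache=True)
def _render_kernel(xs, ys, waist_um, pixel_um, Lx, Ly, periodic_x, n_pixels, out):
    """Accumulate unit-brightness Gaussian PSF samples onto pixel columns."""
    n_lines = xs.shape[0]
    n = xs.shape[1]
    inv = 2.0 / (waist_um * waist_um)
    halfw = int(3.0 * waist_um / pixel_um) + 1
    half_ly = 0.5 * Ly
    for t in range(n_lines):
        for i in range(n):
            yy = ys[t, i]
            if yy > half_ly:
                yy -= Ly
            fy = math.exp(-inv * yy * yy)
            if fy < 1e-9:
                continue
            xc = xs[t, i]
            pc = int(xc / pixel_um)
            for p in range(pc - halfw, pc + halfw + 1):
                dx = xc - (p + 0.5) * pixel_um
                if periodic_x:
                    pp = p % n_pixels
                    if dx > 0.5 * Lx:
                        dx -= Lx
                    elif dx < -0.5 * Lx:
                        dx += Lx
                else:
                    if p < 0 or p >= n_pixels:
                        continue
                    pp = p
                out[t, pp] += fy * math.exp(-inv * dx * dx)
    return out


@njit(cache=True)
def _render_frames_kernel(xs, ys, waist_um, pixel_um, Lx, Ly, n_rows, n_cols, out):
    """2D periodic Gaussian rendering for image time series."""
    n_frames = xs.shape[0]
    n = xs.shape[1]
    inv = 2.0 / (waist_um * waist_um)
    halfw = int(3.0 * waist_um / pixel_um) + 1
    for t in range(n_frames):
        for i in range(n):
            xc = xs[t, i]
            yc = ys[t, i]
            pr = int(yc / pixel_um)
            pcx = int(xc / pixel_um)
            for r in range(pr - halfw, pr + halfw + 1):
                dy = yc - (r + 0.5) * pixel_um
                if dy > 0.5 * Ly:
                    dy -= Ly
                elif dy < -0.5 * Ly:
                    dy += Ly
                rr = r % n_rows
                fy = math.exp(-inv * dy * dy)
                if fy < 1e-9:
                    continue
                for c in range(pcx - halfw, pcx + halfw + 1):
                    dx = xc - (c + 0.5) * pixel_um
                    if dx > 0.5 * Lx:
                        dx -= Lx
                    elif dx < -0.5 * Lx:
                        dx += Lx
                    cc = c % n_cols
                    out[t, rr, cc] += fy * math.exp(-inv * dx * dx)
    return out


# ---------------------------------------------------------------------------
# carpets


def simulate_trajectories(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[dict[str, np.ndarray]]:
    """Evolve all species and return per-species trajectory dicts.

    Each dict holds ``xs``/``ys`` of shape (n_lines, n_particles) in µm
    and the boolean ``mobile`` mask.  Used internally by
    :func:`simulate_carpet`; exposed so barrier physics can be asserted
    directly on trajectories.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    Lx = float(config.field_length_um)
    Ly = float(config.field_depth_um)
    dt = config.line_period_s
    barrier = config.barrier
    has_barrier = barrier is not None
    xb = barrier.position_px * config.pixel_size_nm * 1e-3 if has_barrier else 0.0
    half_thick = barrier.thickness_um / 2.0 if has_barrier else 0.0
    p_cross = barrier.crossing_probability if has_barrier else 1.0
    out = []
    for sp in config.species:
        n = sp.n_particles
        if sp.initial_positions_um is not None:
            pos = np.asarray(sp.initial_positions_um, float).reshape(n, 2)
            x0, y0 = pos[:, 0].copy(), pos[:, 1].copy()
        else:
            x0 = rng.uniform(0.0, Lx, n)
            y0 = rng.uniform(0.0, Ly, n)
            if has_barrier and half_thick > 0:
                inside = np.abs(x0 - xb) < half_thick
                while inside.any():  # keep starts out of the excluded slab
                    x0[inside] = rng.uniform(0.0, Lx, int(inside.sum()))
                    inside = np.abs(x0 - xb) < half_thick
        mobile = rng.random(n) < sp.mobile_fraction
        sigma = math.sqrt(2.0 * sp.D_um2_per_s * dt)
        sx = rng.normal(0.0, 1.0, (config.n_lines - 1, n)) * sigma
        sy = rng.normal(0.0, 1.0, (config.n_lines - 1, n)) * sigma
        u = (
            rng.random((config.n_lines - 1, n))
            if has_barrier
            else np.empty((0, n))
        )
        xs = np.empty((config.n_lines, n))
        ys = np.empty((config.n_lines, n))
        _evolve_kernel(
            x0, y0, sx, sy, sp.velocity_um_per_s * dt, mobile, Lx, Ly,
            has_barrier, xb, half_thick, p_cross, u, has_barrier, xs, ys,
        )
        out.append({"xs": xs, "ys": ys, "mobile": mobile})
    return out


def simulate_carpet(
    config: SimulationConfig,
    expectation: bool = False,
    return_trajectories: bool = False,
):
    """Simulate a two-channel line-scan carpet.

    Counts are Poisson with rate ``background + lamina stripe +
    sum_species brightness * channel_weight * exp(-2 dist^2 / waist^2)``;
    with ``expectation=True`` the expected rate itself is returned
    (deterministic, noise-free).  Identical config and seed give a
    bit-identical carpet.
    """
    rng = np.random.default_rng(config.seed)
    trajs = simulate_trajectories(config, rng)
    Lx = float(config.field_length_um)
    pixel_um = config.pixel_size_nm * 1e-3
    waist_um = config.psf_waist_nm * 1e-3
    periodic_x = (config.barrier is None) and abs(config.scan_extent_um - Lx) < 1e-9
    lam = np.zeros((config.n_lines, config.n_pixels, 2))
    for sp, tr in zip(config.species, trajs):
        if sp.n_particles == 0 or sp.brightness_cpsm == 0:
            continue
        tmp = np.zeros((config.n_lines, config.n_pixels))
        _render_kernel(
            tr["xs"], tr["ys"], waist_um, pixel_um, Lx,
            float(config.field_depth_um), periodic_x, config.n_pixels, tmp,
        )
        for c in (0, 1):
            w = sp.channel_weights[c]
            if w > 0:
                lam[:, :, c] += tmp * (sp.brightness_cpsm * w)
    lam += config.background_rate
    if config.lamina_channel is not None:
        ls = config.lamina_channel
        cols = np.arange(config.n_pixels)
        stripe = ls.amplitude * np.exp(-0.5 * ((cols - ls.position_px) / ls.width_px) ** 2)
        lam[:, :, ls.channel] += stripe[None, :]
    data = lam if expectation else rng.poisson(lam).astype(np.int32)
    carpet = LineScanCarpet(
        data=data,
        pixel_size_nm=config.pixel_size_nm,
        line_period_ms=config.line_period_ms,
        dwell_time_us=config.dwell_time_us,
        channel_names=("ch0", "ch1"),
    )
    if return_trajectories:
        return carpet, trajs
    return carpet


def expected_mean_intensity(config: SimulationConfig) -> np.ndarray:
    """Analytic expected carpet mean per channel for uniformly distributed particles.

    Each particle contributes the PSF integral divided by the field area:
    ``brightness * (pi w^2 / 2) / (Lx * Ly)`` per channel weight; the
    lamina stripe contributes its profile averaged over pixel columns.
    Closed form, independent of the simulation path — used as the
    photon-conservation oracle.
    """
    waist_um = config.psf_waist_nm * 1e-3
    area = config.field_length_um * config.field_depth_um
    per_particle = math.pi * waist_um**2 / 2.0 / area
    mean = np.full(2, float(config.background_rate))
    for sp in config.species:
        for c in (0, 1):
            mean[c] += sp.n_particles * sp.brightness_cpsm * sp.channel_weights[c] * per_particle
    if config.lamina_channel is not None:
        ls = config.lamina_channel
        cols = np.arange(config.n_pixels)
        stripe = ls.amplitude * np.exp(-0.5 * ((cols - ls.position_px) / ls.width_px) ** 2)
        mean[ls.channel] += stripe.mean()
    return mean


# ---------------------------------------------------------------------------
# 2D co-transport stacks


def simulate_cotransport_stack(
    config: SimulationConfig,
    n_frames: int,
    cotransport_fraction: float,
    frame_period_ms: float = 10.0,
    n_rows: int | None = None,
    expectation: bool = False,
) -> ImageStack:
    """Two-channel 2D time series with a stated co-transport fraction.

    ``cotransport_fraction`` of the particles of ``config.species[0]``
    emit in both channels (weights 0.5/0.5) and share one trajectory; the
    remainder are split into independent channel-0-only and
    channel-1-only particles with the same D and brightness.
    """
    if not 0.0 <= cotransport_fraction <= 1.0:
        raise ValueError("cotransport_fraction must be in [0, 1]")
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if not config.species:
        raise ValueError("config must declare at least one species")
    sp = config.species[0]
    rng = np.random.default_rng(config.seed)
    n_cols = config.n_pixels
    n_rows = n_rows or n_cols
    pixel_um = config.pixel_size_nm * 1e-3
    Lx = n_cols * pixel_um
    Ly = n_rows * pixel_um
    waist_um = config.psf_waist_nm * 1e-3
    dt = frame_period_ms * 1e-3

    n_total = sp.n_particles
    n_co = int(round(cotransport_fraction * n_total))
    n_ind = n_total - n_co
    n_ind0 = n_ind // 2 + n_ind % 2
    groups = [  # (count, channel weights)
        (n_co, (0.5, 0.5)),
        (n_ind0, (1.0, 0.0)),
        (n_ind - n_ind0, (0.0, 1.0)),
    ]
    lam = np.zeros((n_frames, n_rows, n_cols, 2))
    sigma = math.sqrt(2.0 * sp.D_um2_per_s * dt)
    for count, weights in groups:
        if count == 0:
            continue
        x0 = rng.uniform(0.0, Lx, count)
        y0 = rng.uniform(0.0, Ly, count)
        xs = (x0[None, :] + np.concatenate(
            [np.zeros((1, count)), np.cumsum(rng.normal(0, sigma, (n_frames - 1, count)), axis=0)]
        )) % Lx
        ys = (y0[None, :] + np.concatenate(
            [np.zeros((1, count)), np.cumsum(rng.normal(0, sigma, (n_frames - 1, count)), axis=0)]
        )) % Ly
        tmp = np.zeros((n_frames, n_rows, n_cols))
        _render_frames_kernel(xs, ys, waist_um, pixel_um, Lx, Ly, n_rows, n_cols, tmp)
        for c in (0, 1):
            if weights[c] > 0:
                lam[:, :, :, c] += tmp * (sp.brightness_cpsm * weights[c])
    lam += config.background_rate
    data = lam if expectation else rng.poisson(lam).astype(np.int32)
    return ImageStack(
        data=data,
        pixel_size_nm=config.pixel_size_nm,
        frame_period_ms=frame_period_ms,
        channel_names=("ch0", "ch1"),
    )


# ---------------------------------------------------------------------------
# 3D sphere fields


@dataclass
class SphereField:
    """Synthetic 3D particle field plus ground truth."""

    stack: ImageStack3D
    nucleus_mask: np.ndarray | None
    truth: "pd.DataFrame"  # noqa: F821 — pandas imported lazily below


def _ellipsoid_mask(shape: tuple[int, int, int],
                    center_vox: Sequence[float],
                    semiaxes_vox: Sequence[float]) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center_vox
    az, ay, ax = semiaxes_vox
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def simulate_sphere_field(
    n_spheres: int,
    radius_vox: float | Sequence[float],
    intensity: float = 100.0,
    shape: tuple[int, int, int] = (32, 96, 96),
    voxel_size_nm: tuple[float, float, float] = (150.0, 55.0, 55.0),
    nucleus_mask_spec: Mapping[str, Sequence[float]] | None = None,
    seed: int = 0,
    centers_vox: Sequence[Sequence[float]] | None = None,
    background: float = 0.0,
    poisson_noise: bool = False,
    max_tries_per_sphere: int = 2000,
) -> SphereField:
    """Place non-overlapping solid spheres in a 3D volume with ground truth.

    Radii are given in units of the x voxel pitch.  ``nucleus_mask_spec``
    (``{"center_vox": (z,y,x), "semiaxes_vox": (az,ay,ax)}``) renders a
    solid ellipsoid mask; the truth table then carries each sphere's
    signed distance from the nucleus surface (negative inside).  Spheres
    are kept outside the nucleus and apart from each other by rejection
    sampling; exceeding the retry budget raises :class:`PlacementError`.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    vz, vy, vx = (v * 1e-3 for v in voxel_size_nm)  # µm
    radii = np.full(n_spheres, float(np.ravel(radius_vox)[0])) if np.isscalar(radius_vox) or np.ndim(radius_vox) == 0 else np.asarray(radius_vox, float)
    if len(radii) != n_spheres:
        raise ValueError("one radius per sphere required")
    nucleus_mask = None
    if nucleus_mask_spec is not None:
        nucleus_mask = _ellipsoid_mask(
            shape, nucleus_mask_spec["center_vox"], nucleus_mask_spec["semiaxes_vox"]
        )

    # centers in physical µm, (z, y, x)
    centers: list[np.ndarray] = []
    if centers_vox is not None:
        if len(centers_vox) != n_spheres:
            raise ValueError("one center per sphere required")
        centers = [np.array([c[0] * vz, c[1] * vy, c[2] * vx]) for c in centers_vox]
    else:
        extent = np.array([shape[0] * vz, shape[1] * vy, shape[2] * vx])
        for i in range(n_spheres):
            r_um = radii[i] * vx
            placed = False
            for _ in range(max_tries_per_sphere):
                c = rng.uniform(r_um, extent - r_um)
                if any(np.linalg.norm(c - c2) < r_um + radii[j] * vx + vx
                       for j, c2 in enumerate(centers)):
                    continue
                if nucleus_mask is not None:
                    iz, iy, ix = (int(c[0] / vz), int(c[1] / vy), int(c[2] / vx))
                    if nucleus_mask[min(iz, shape[0] - 1), min(iy, shape[1] - 1),
                                    min(ix, shape[2] - 1)]:
                        continue
                centers.append(c)
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place sphere {i + 1}/{n_spheres} without overlap"
                )

    data = np.full(shape, float(background))
    records = []
    z_um = (np.arange(shape[0]) + 0.5) * vz
    y_um = (np.arange(shape[1]) + 0.5) * vy
    x_um = (np.arange(shape[2]) + 0.5) * vx
    for i, c in enumerate(centers):
        r_um = radii[i] * vx
        lo = [max(0, int((c[k] - r_um) / v) - 1) for k, v in enumerate((vz, vy, vx))]
        hi = [min(shape[k], int((c[k] + r_um) / v) + 2) for k, v in enumerate((vz, vy, vx))]
        dz = z_um[lo[0]:hi[0]] - c[0]
        dy = y_um[lo[1]:hi[1]] - c[1]
        dx = x_um[lo[2]:hi[2]] - c[2]
        inside = (dz[:, None, None] ** 2 + dy[None, :, None] ** 2
                  + dx[None, None, :] ** 2) <= r_um**2
        region = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        region[inside] += intensity
        n_vox = int(inside.sum())
        records.append({
            "label": i + 1,
            "center_z_um": c[0], "center_y_um": c[1], "center_x_um": c[2],
            "radius_vox": radii[i], "radius_um": r_um,
            "volume_vox": n_vox, "volume_um3": n_vox * vz * vy * vx,
            "total_intensity": n_vox * intensity,
        })
    truth = pd.DataFrame.from_records(
        records,
        columns=["label", "center_z_um", "center_y_um", "center_x_um", "radius_vox",
                 "radius_um", "volume_vox", "volume_um3", "total_intensity"],
    )
    if nucleus_mask is not None and len(truth):
        from carpetfcs.seg3d import signed_distance_to_surface

        pts = truth[["center_z_um", "center_y_um", "center_x_um"]].to_numpy()
        truth["distance_to_ne_um"] = signed_distance_to_surface(
            pts, nucleus_mask, (vz, vy, vx)
        )
    if poisson_noise:
        data = rng.poisson(data).astype(np.int32)
    stack = ImageStack3D(data=data, voxel_size_nm=tuple(voxel_size_nm))
    return SphereField(stack=stack, nucleus_mask=nucleus_mask, truth=truth)
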