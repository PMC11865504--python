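"""Generators emulating the study's raw data, with exact ground truth.

Three generators cover every pipeline input: confocal-like fluorescence
z-stacks of spherical droplets (per-slice disk cross-sections, Gaussian
point spread, Poisson shot noise, Gaussian read noise), oscillatory
upper/lower-half volume series with a prescribed period, trough fraction
and phase shift, and randomly perturbed emulsions around a target radius.
Every generator is a pure function of (parameters, seed) and returns a
truth record sufficient for recovery tests (detection rates, track
identity, period/lag recovery, relaxation after perturbation).

Rendering defaults mirror typical confocal settings (103 nm pixels,
0.36 µm z-step) at a reduced 128×128 px field so test suites stay fast;
the full 512×512 px geometry is one parameter away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_sim import DropletState
from .image_quant import ImageStack
from .osc_metrics import WaveSeries
from .size_control import FOUR_THIRDS_PI, Emulsion, volumes_to_radii

__all__ = [
    "RenderOpts",
    "render_stack",
    "make_oscillation_series",
    "make_perturbed_emulsion",
]


@dataclass(frozen=True)
class RenderOpts:
    """Rendering geometry and noise model for synthetic stacks."""

    shape: tuple[int, int] = (128, 128)  # (ny, nx) px
    n_slices: int = 16
    pixel_size: float = 0.103  # µm/px
    z_step: float = 0.36       # µm
    psf_sigma: float = 1.0     # px
    background: float = 10.0   # counts
    photon_scale: float = 50.0 # droplet peak signal above background, counts
    read_noise: float = 2.0    # counts (Gaussian σ)
    shot_noise: bool = True
    dt_frame: float = 9.0      # s
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) <= 0 or self.n_slices <= 0:
            raise ValueError("sizes must be positive")
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ValueError("calibration must be positive")
        for name in ("psf_sigma", "background", "photon_scale", "read_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_size, self.shape[1] * self.pixel_size)


def _render_frame(droplets, opts: RenderOpts) -> np.ndarray:
    ny, nx = opts.shape
    px = opts.pixel_size
    fy, fx = opts.field_um
    depth = opts.n_slices * opts.z_step
    canvas = np.zeros((opts.n_slices, ny, nx))
    yy = (np.arange(ny) + 0.5) * px
    xx = (np.arange(nx) + 0.5) * px
    for d in droplets:
        if 2.0 * d.R > min(fx, fy):
            raise ValueError(f"droplet radius {d.R} µm exceeds the field of view")
        if not (0.0 <= d.x <= fx and 0.0 <= d.y <= fy and -d.R <= d.z <= depth + d.R):
            raise ValueError("droplet center outside the field of view")
        for k in range(opts.n_slices):
            dz = (k + 0.5) * opts.z_step - d.z
            if abs(dz) >= d.R:
                continue
            r_cross = math.sqrt(d.R ** 2 - dz ** 2)
            # anti-aliased disk: 1 inside, linear roll-off over one pixel
            dist = np.hypot(yy[:, None] - d.y, xx[None, :] - d.x)
            canvas[k] += np.clip((r_cross - dist) / px + 0.5, 0.0, 1.0)
    if opts.psf_sigma > 0:
        from scipy.ndimage import gaussian_filter
        canvas = gaussian_filter(canvas, sigma=(0, opts.psf_sigma, opts.psf_sigma))
    return canvas


def render_stack(
    droplets, opts: RenderOpts = RenderOpts()
) -> tuple[ImageStack, pd.DataFrame]:
    """Render droplets into a noisy confocal-like stack plus ground truth.

    ``droplets`` is a list of DropletState (one frame) or a list of such
    lists (a movie).  Droplet coordinates are in µm with the origin at the
    image corner (x along columns, y along rows, z through the slices).
    Intensities: background + photon_scale·(blurred occupancy), Poisson
    shot noise on the photon signal, additive Gaussian read noise.
    Deterministic for a fixed ``opts.seed``.
    """
    frames = droplets
    if len(frames) == 0 or isinstance(frames[0], DropletState):
        frames = [frames]
    rng = np.random.default_rng(opts.seed)
    out = []
    truth_rows = []
    for f, frame_droplets in enumerate(frames):
        clean = _render_frame(frame_droplets, opts)
        expected = opts.background + opts.photon_scale * clean
        noisy = rng.poisson(expected).astype(float) if opts.shot_noise else expected.copy()
        if opts.read_noise > 0:
            noisy += rng.normal(0.0, opts.read_noise, size=noisy.shape)
        out.append(np.clip(noisy, 0.0, None))
        for d in frame_droplets:
            truth_rows.append({"frame": f, "id": d.id, "x": d.x, "y": d.y,
                               "z": d.z, "R": d.R})
    stack = ImageStack(np.stack(out), pixel_size=opts.pixel_size,
                       z_step=opts.z_step, dt_frame=opts.dt_frame)
    truth = pd.DataFrame(truth_rows, columns=["frame", "id", "x", "y", "z", "R"])
    return stack, truth


def _burst_waveform(phase: np.ndarray, trough_fraction: float, ramp: float) -> np.ndarray:
    """Plateau bursts separated by flat troughs, raised-cosine ramps.

    ``phase`` in [0, 1); trough spans [0, f); the rising ramp (width
    ``ramp`` in phase units) is centered on f and the falling ramp on 1/0,
    so the time below any mid-level matches the trough duration closely.
    """
    f = trough_fraction
    r = ramp
    rising = (phase >= f - r / 2) & (phase < f + r / 2)
    falling = phase >= 1.0 - r / 2
    falling_wrap = phase < r / 2
    plateau = (phase >= f + r / 2) & (phase < 1.0 - r / 2)
    u = (phase - (f - r / 2)) / r            # 0→1 across the rising ramp
    s = (phase - (1.0 - r / 2)) / r          # 0→0.5 across the falling ramp
    s_wrap = (phase + r / 2) / r             # 0.5→1 past the wrap
    return np.select(
        [rising, falling, falling_wrap, plateau],
        [
            0.5 * (1.0 - np.cos(np.pi * u)),
            0.5 * (1.0 + np.cos(np.pi * s)),
            0.5 * (1.0 + np.cos(np.pi * s_wrap)),
            np.ones_like(phase),
        ],
        default=0.0,
    )


def make_oscillation_series(
    period: float = 60.0,
    trough_fraction: float = 0.5,
    amplitude: float = 10.0,
    noise: float = 0.0,
    phase_shift: float = math.pi,
    dt: float = 2.0,
    n: int = 256,
    seed: int = 0,
    waveform: str = "burst",
) -> tuple[WaveSeries, WaveSeries, dict]:
    """Upper/lower-half volume series with known oscillation parameters.

    ``phase_shift`` (radians) offsets the lower series relative to the
    upper; π gives the anti-phase pattern of sedimentation-driven waves.
    ``waveform="burst"`` (default) gives plateau bursts with flat troughs
    of duration trough_fraction·period; ``"sine"`` gives a pure sinusoid.
    Additive Gaussian noise has σ = noise·amplitude.  Returns
    (upper, lower, truth).
    """
    if period <= 2.0 * dt:
        raise ValueError("aliasing: period must exceed 2·dt")
    if not (0.0 < trough_fraction < 1.0):
        raise ValueError("trough_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    shift = phase_shift / (2.0 * math.pi)

    def signal(offset: float) -> np.ndarray:
        phase = np.mod(t / period - offset, 1.0)
        if waveform == "sine":
            base = 0.5 * (1.0 - np.cos(2.0 * math.pi * phase))
        elif waveform == "burst":
            ramp = min(dt / period, trough_fraction / 2.0,
                       (1.0 - trough_fraction) / 2.0)
            base = _burst_waveform(phase, trough_fraction, ramp)
        else:
            raise ValueError("waveform must be 'burst' or 'sine'")
        v = amplitude * base
        if noise > 0:
            v = v + rng.normal(0.0, noise * amplitude, size=n)
        return np.clip(v, 0.0, None)

    upper = WaveSeries(t, signal(0.0), region="upper")
    lower = WaveSeries(t, signal(shift), region="lower")
    truth = {
        "period": period,
        "trough_fraction": trough_fraction,
        "lag_time": trough_fraction * period,
        "amplitude": amplitude,
        "phase_shift": phase_shift,
        "noise": noise,
        "dt": dt,
        "n": n,
        "seed": seed,
        "waveform": waveform,
    }
    return upper, lower, truth


def make_perturbed_emulsion(
    n: int,
    R_star: float,
    spread: float,
    seed: int = 0,
    c_A_pool: float = 0.0375,
    c_P_pool: float = 10.0,
    volume_fraction: float = 2.0e-3,
) -> Emulsion:
    """An emulsion of n droplets perturbed around a target radius.

    Volumes are multiplied by log-normal factors of shape ``spread`` and
    rescaled so the total equals n·(4/3)πR*³ exactly; the system volume is
    set from ``volume_fraction``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if R_star <= 0:
        raise ValueError("R_star must be > 0")
    if spread < 0:
        raise ValueError("spread must be >= 0")
    rng = np.random.default_rng(seed)
    V_star = FOUR_THIRDS_PI * R_star ** 3
    if spread == 0:
        volumes = np.full(n, V_star)
    else:
        factors = rng.lognormal(0.0, spread, size=n)
        volumes = V_star * factors
        volumes *= n * V_star / volumes.sum()
    return Emulsion(
        radii=volumes_to_radii(volumes),
        c_A_pool=c_A_pool,
        c_P_pool=c_P_pool,
        volume=n * V_star / volume_fraction,
    )
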