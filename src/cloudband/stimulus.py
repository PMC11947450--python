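"""Random-phase motion-cloud synthesis and presentation protocols.

A motion cloud is a dense superposition of localized drifting gratings with
random positions and phases.  It is generated in the Fourier domain: a
separable amplitude envelope — Gaussian in log spatial frequency around a
central frequency, wrapped-Gaussian in orientation around a central
orientation — is multiplied by uniformly random phases and inverse
transformed.  The bandwidth parameters are the standard deviations of those
envelopes, so they directly control the dispersion of oriented energy in the
stimulus.  Drift is a rigid translation of the whole texture orthogonal to
the central orientation (rightward for a 0 deg, vertical-edge stimulus) at a
speed of ``temporal_freq / central_sf`` degrees per second, i.e. the central
component completes ``temporal_freq`` cycles per second.

Orientation convention: 0 deg = vertical edges, angles measured
counterclockwise in image coordinates, all orientation arithmetic mod 180.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import AliasingError, InfeasibleSequenceError, InvalidApertureError, InvalidSpecError
from .geometry import DisplayGeometry

__all__ = [
    "CloudSpec",
    "CloudMovie",
    "PresentationSequence",
    "synthesize_cloud",
    "build_protocol",
    "apply_center_aperture",
    "table1_orientation_band_protocol",
    "table1_sf_band_protocol",
    "FRAME_RATE_HZ",
]

#: Monitor refresh rate assumed throughout (300 frames = 5 s).
FRAME_RATE_HZ = 60.0


@dataclass(frozen=True)
class CloudSpec:
    """Parameters of a single motion-cloud condition.

    ``orientation_bandwidth_deg`` and ``sf_bandwidth_cpd`` are dispersion
    (standard-deviation-like) parameters of the orientation and
    spatial-frequency envelopes.
    """

    central_orientation_deg: float
    orientation_bandwidth_deg: float
    central_sf_cpd: float
    sf_bandwidth_cpd: float
    temporal_freq_hz: float = 1.0
    n_frames: int = 300
    frame_shape_px: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-90.0 < self.central_orientation_deg <= 90.0):
            raise InvalidSpecError("central orientation must lie in (-90, 90]")
        if self.orientation_bandwidth_deg <= 0 or self.sf_bandwidth_cpd <= 0:
            raise InvalidSpecError("bandwidths must be > 0")
        if self.central_sf_cpd <= 0:
            raise InvalidSpecError("central spatial frequency must be > 0")
        if self.temporal_freq_hz < 0:
            raise InvalidSpecError("temporal frequency must be >= 0")
        if self.n_frames < 1:
            raise InvalidSpecError("need at least one frame")
        if self.n_frames < 2 and self.temporal_freq_hz > 0:
            raise InvalidSpecError("drifting stimulus needs at least two frames")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "CloudSpec":
        d = json.loads(text)
        d["frame_shape_px"] = tuple(d["frame_shape_px"])
        return cls(**d)


@dataclass(frozen=True)
class CloudMovie:
    """Rendered luminance frames of one motion-cloud rendering.

    ``frames`` is a ``(T, H, W)`` array in [0, 1]; the spatio-temporal mean
    is 0.5 by construction (the zero-frequency component is removed before
    the symmetric contrast rescale).
    """

    frames: np.ndarray
    deg_per_px: float
    spec: CloudSpec
    rendering_id: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.frames)):
            raise InvalidSpecError("movie frames contain NaN/Inf")


def _orientation_envelope(angle_deg: np.ndarray, center_deg: float, bw_deg: float) -> np.ndarray:
    """Wrapped (period 180) Gaussian amplitude envelope over orientation."""
    env = np.zeros_like(angle_deg)
    for k in (-2, -1, 0, 1, 2):
        d = angle_deg - center_deg + 180.0 * k
        env += np.exp(-0.5 * (d / bw_deg) ** 2)
    return env


def _sf_envelope(radius_cpd: np.ndarray, f0: float, bw_cpd: float) -> np.ndarray:
    """Log-frequency Gaussian amplitude envelope.

    The log-domain scale is ``bw_cpd / f0`` so that, linearized at the
    central frequency, the dispersion in cycles/degree equals ``bw_cpd``.
    """
    sigma_log = bw_cpd / f0
    with np.errstate(divide="ignore"):
        logr = np.log(radius_cpd)
    env = np.exp(-0.5 * ((logr - np.log(f0)) / sigma_log) ** 2)
    env[~np.isfinite(logr)] = 0.0
    return env


def synthesize_cloud(
    spec: CloudSpec,
    geometry: DisplayGeometry | float,
    rendering_id: int = 0,
    contrast: str = "symmetric",
) -> CloudMovie:
    """Render one seeded motion-cloud movie.

    Parameters
    ----------
    spec : CloudSpec
    geometry : DisplayGeometry or float
        Either a display geometry (degrees/pixel is derived from it) or a
        degrees-per-pixel value directly.
    rendering_id : int
        Independent renderings of the same spec differ only in this id; the
        per-rendering random stream is derived from ``(spec.seed,
        rendering_id)`` so renderings are independent yet reproducible.
    contrast : {"symmetric", "minmax"}
        "symmetric" rescales the zero-mean field by its global absolute
        maximum onto [0, 1] (mean exactly 0.5); "minmax" stretches
        [min, max] onto [0, 1].
    """
    deg_per_px = geometry.deg_per_px if isinstance(geometry, DisplayGeometry) else float(geometry)
    if deg_per_px <= 0:
        raise InvalidSpecError("degrees per pixel must be > 0")
    nyquist = 0.5 / deg_per_px
    if spec.central_sf_cpd + spec.sf_bandwidth_cpd >= nyquist:
        raise AliasingError(
            f"central SF + bandwidth ({spec.central_sf_cpd + spec.sf_bandwidth_cpd:.3g} cpd) "
            f"reaches the display Nyquist limit ({nyquist:.3g} cpd)"
        )

    h, w = spec.frame_shape_px
    fy = np.fft.fftfreq(h, d=deg_per_px)[:, None]  # cycles/degree
    fx = np.fft.fftfreq(w, d=deg_per_px)[None, :]
    radius = np.hypot(fx, fy)
    angle = np.degrees(np.arctan2(fy, fx))  # frequency angle == edge orientation

    envelope = _sf_envelope(radius, spec.central_sf_cpd, spec.sf_bandwidth_cpd)
    envelope *= _orientation_envelope(
        np.mod(angle, 180.0), np.mod(spec.central_orientation_deg, 180.0),
        spec.orientation_bandwidth_deg,
    )
    envelope[0, 0] = 0.0  # no DC: every frame is zero-mean before rescaling

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) % 2**31, int(rendering_id)]))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=envelope.shape)
    spectrum = envelope * np.exp(1j * phases)

    # Rigid drift orthogonal to the central orientation; speed such that the
    # central component advances temporal_freq cycles per second.
    alpha = np.radians(spec.central_orientation_deg)
    speed_deg_s = spec.temporal_freq_hz / spec.central_sf_cpd
    dx_per_frame = speed_deg_s * np.cos(alpha) / FRAME_RATE_HZ
    dy_per_frame = speed_deg_s * np.sin(alpha) / FRAME_RATE_HZ
    ramp = np.exp(-2j * np.pi * (fx * dx_per_frame + fy * dy_per_frame))

    frames = np.empty((spec.n_frames, h, w), dtype=np.float32)
    s = spectrum
    for t in range(spec.n_frames):
        frames[t] = np.fft.ifft2(s).real
        s = s * ramp

    if contrast == "symmetric":
        peak = np.max(np.abs(frames))
        if peak == 0:
            raise InvalidSpecError("degenerate envelope: rendered field is identically zero")
        frames = 0.5 + 0.5 * frames / peak
    elif contrast == "minmax":
        lo, hi = float(frames.min()), float(frames.max())
        if hi == lo:
            raise InvalidSpecError("degenerate envelope: rendered field is constant")
        frames = (frames - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown contrast mode {contrast!r}")
    return CloudMovie(frames=frames.astype(np.float32), deg_per_px=deg_per_px,
                      spec=spec, rendering_id=rendering_id)


# ---------------------------------------------------------------------------
# Presentation protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PresentationSequence:
    """Ordered pseudo-random trial list with no immediate condition repeats."""

    trials: tuple[tuple[int, int, int], ...]  # (condition_id, rendering_id, repeat_index)
    stim_duration_s: float = 5.0
    isi_s: float = 5.0
    seed: int = 0

    @property
    def condition_ids(self) -> np.ndarray:
        return np.array([t[0] for t in self.trials])

    def __len__(self) -> int:
        return len(self.trials)


def build_protocol(
    conditions: list,
    n_renderings: int = 10,
    n_repeats: int = 20,
    seed: int = 0,
    stim_duration_s: float = 5.0,
    isi_s: float = 5.0,
) -> PresentationSequence:
    """Build a balanced pseudo-random presentation order.

    Every (condition, rendering) pair appears ``n_repeats`` times and no two
    consecutive trials share a condition.  The sequencer draws the next
    condition uniformly among the allowed ones, except that a condition
    holding more than half of the remaining trials is forced (the standard
    feasibility-preserving greedy), so any feasible multiset is arranged.
    """
    n_cond = len(conditions)
    if n_cond < 2:
        raise InfeasibleSequenceError(
            "at least two conditions are required when immediate repeats are banned"
        )
    if n_renderings < 1 or n_repeats < 1:
        raise InvalidSpecError("n_renderings and n_repeats must be >= 1")

    rng = np.random.default_rng(seed)
    per_cond = n_renderings * n_repeats
    remaining = np.full(n_cond, per_cond, dtype=int)
    # per-condition shuffled queues of (rendering, repeat) slots
    queues = []
    for _ in range(n_cond):
        slots = [(r, k) for k in range(n_repeats) for r in range(n_renderings)]
        rng.shuffle(slots)
        queues.append(slots)

    order: list[int] = []
    prev = -1
    total = n_cond * per_cond
    for _ in range(total):
        allowed = [c for c in range(n_cond) if remaining[c] > 0 and c != prev]
        if not allowed:
            raise InfeasibleSequenceError("sequence constraint became unsatisfiable")
        left = int(remaining.sum())
        critical = [c for c in allowed if 2 * remaining[c] > left]
        pick_from = critical if critical else allowed
        c = int(rng.choice(pick_from))
        order.append(c)
        remaining[c] -= 1
        prev = c

    trials = []
    for c in order:
        r, k = queues[c].pop()
        trials.append((c, r, k))
    return PresentationSequence(
        trials=tuple(trials), stim_duration_s=stim_duration_s, isi_s=isi_s, seed=seed
    )


def table1_orientation_band_protocol(
    seed: int = 0, n_frames: int = 300, frame_shape_px: tuple[int, int] = (256, 256)
) -> list[CloudSpec]:
    """The orientation-band-expanding condition set.

    Three orientation bandwidths (5, 25, 45 deg) crossed with two central
    spatial frequencies (0.04, 0.16 cpd) at fixed 0 deg central orientation
    and 0.004 cpd SF bandwidth: six parameter combinations.
    """
    specs = []
    for f0 in (0.04, 0.16):
        for bw in (5.0, 25.0, 45.0):
            specs.append(CloudSpec(
                central_orientation_deg=0.0, orientation_bandwidth_deg=bw,
                central_sf_cpd=f0, sf_bandwidth_cpd=0.004,
                n_frames=n_frames, frame_shape_px=frame_shape_px, seed=seed,
            ))
    return specs


def table1_sf_band_protocol(
    seed: int = 0, n_frames: int = 300, frame_shape_px: tuple[int, int] = (256, 256)
) -> list[CloudSpec]:
    """The SF-band-expanding set: three SF bandwidths x two central orientations."""
    specs = []
    for ori in (0.0, 90.0):
        for bw in (0.004, 0.04, 0.4):
            specs.append(CloudSpec(
                central_orientation_deg=ori, orientation_bandwidth_deg=5.0,
                central_sf_cpd=0.04, sf_bandwidth_cpd=bw,
                n_frames=n_frames, frame_shape_px=frame_shape_px, seed=seed,
            ))
    return specs


def apply_center_aperture(
    movie: CloudMovie,
    center_deg: tuple[float, float] = (0.0, 0.0),
    diameter_deg: float = 15.0,
    background: float = 0.5,
) -> CloudMovie:
    """Mask the movie outside a circular aperture with a uniform background.

    ``center_deg`` is the aperture center as (x, y) degrees relative to the
    frame center (x rightward, y downward).  The disc must lie fully on
    screen.
    """
    if diameter_deg <= 0:
        raise InvalidApertureError("aperture diameter must be > 0")
    t, h, w = movie.frames.shape
    dpp = movie.deg_per_px
    cx_px = (w - 1) / 2.0 + center_deg[0] / dpp
    cy_px = (h - 1) / 2.0 + center_deg[1] / dpp
    radius_px = diameter_deg / 2.0 / dpp
    # The disc must fit on screen, unless it already covers every pixel
    # (then masking is the identity and any overshoot is harmless).
    corners = np.hypot([cx_px, cx_px, cx_px - (w - 1), cx_px - (w - 1)],
                       [cy_px, cy_px - (h - 1), cy_px, cy_px - (h - 1)])
    covers_screen = radius_px >= corners.max()
    on_screen = (cx_px - radius_px >= -0.5 and cx_px + radius_px <= w - 0.5
                 and cy_px - radius_px >= -0.5 and cy_px + radius_px <= h - 0.5)
    if not covers_screen and not on_screen:
        raise InvalidApertureError("aperture extends beyond the screen")
    yy, xx = np.mgrid[0:h, 0:w]
    outside = (xx - cx_px) ** 2 + (yy - cy_px) ** 2 > radius_px**2
    frames = movie.frames.copy()
    frames[:, outside] = background
    return CloudMovie(frames=frames, deg_per_px=dpp, spec=movie.spec,
                      rendering_id=movie.rendering_id)
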