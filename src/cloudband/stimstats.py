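"""Orientation, spatial-frequency and predictability statistics of image sets.

Three measurements, applicable to natural photographs and synthesized motion
clouds alike:

* ``directionality_histogram`` — distribution of local edge orientations from
  a 5x5 Sobel gradient pair, folded mod 180 deg into 180 one-degree bins and
  normalized to probability mass.
* ``radial_sf_spectrum`` — orientation-independent spatial-frequency content:
  the 2-D power spectrum averaged in integer-radius annuli, with the axis
  converted from cycles/image to cycles/degree through the display or camera
  geometry.
* ``raw_coefficient_correlation`` — spatial predictability: the central
  window of the frame-averaged spatial autocorrelation of lowpass-filtered
  frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateDataError, InvalidGeometryError
from .geometry import CameraGeometry, DisplayGeometry
from .stimulus import CloudMovie

__all__ = [
    "OrientationHistogram",
    "RadialSpectrum",
    "AutocorrMap",
    "directionality_histogram",
    "directionality_summary",
    "radial_sf_spectrum",
    "raw_coefficient_correlation",
]

# Separable 5x5 Sobel pair: binomial smoothing across the edge, central
# difference (doubled) along the gradient.
_SMOOTH5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
_DERIV5 = np.array([-1.0, -2.0, 0.0, 2.0, 1.0])
SOBEL5_X = np.outer(_SMOOTH5, _DERIV5)  # responds to variation along columns (x)
SOBEL5_Y = SOBEL5_X.T


@dataclass(frozen=True)
class OrientationHistogram:
    """Probability mass over 180 one-degree orientation bins.

    ``bin_centers_deg[i] = i + 0.5`` covers (0, 180]; bin 0 collects edges
    oriented within one degree of vertical (the 0-deg convention).
    """

    mass: np.ndarray
    bin_centers_deg: np.ndarray

    def __post_init__(self) -> None:
        assert self.mass.shape == (180,)

    @property
    def peak_deg(self) -> float:
        return float(self.bin_centers_deg[int(np.argmax(self.mass))] - 0.5)

    def circular_std_deg(self) -> float:
        """Dispersion around the circular mean (period 180 deg)."""
        ang = np.radians(2.0 * (self.bin_centers_deg - 0.5))
        r = abs(np.sum(self.mass * np.exp(1j * ang)))
        r = min(max(r, 1e-12), 1.0)
        return float(np.degrees(np.sqrt(-2.0 * np.log(r))) / 2.0)


@dataclass(frozen=True)
class RadialSpectrum:
    """Mean spectral energy per integer-radius annulus, axis in cpd."""

    freq_cpd: np.ndarray
    energy: np.ndarray
    counts: np.ndarray

    @property
    def peak_cpd(self) -> float:
        # skip the DC bin when locating the spectral peak
        return float(self.freq_cpd[1:][int(np.argmax(self.energy[1:]))])


@dataclass(frozen=True)
class AutocorrMap:
    """Central window of the frame-averaged spatial autocorrelation."""

    coefficients: np.ndarray
    neighborhood: int
    normalized: bool


def directionality_histogram(
    image: np.ndarray, weighting: str = "energy"
) -> OrientationHistogram:
    """Edge-orientation histogram of one grayscale image.

    Gradients come from the 5x5 Sobel pair; each pixel votes into the
    one-degree bin of its edge orientation (gradient direction rotated to the
    edge convention, mod 180).  ``weighting="energy"`` weights votes by the
    squared gradient magnitude, ``"count"`` counts pixels with any gradient.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 5:
        raise ValueError("image must be 2-D and at least 5x5")
    gx = ndimage.convolve(img, SOBEL5_X, mode="reflect")
    gy = ndimage.convolve(img, SOBEL5_Y, mode="reflect")
    energy = gx**2 + gy**2
    scale = max(1.0, float(np.abs(img).max())) ** 2
    if not np.any(energy > 1e-18 * scale):
        warnings.warn("constant image: returning a uniform orientation histogram")
        mass = np.full(180, 1.0 / 180.0)
        return OrientationHistogram(mass=mass, bin_centers_deg=np.arange(180) + 0.5)
    # gradient along x (horizontal) means a vertical edge -> orientation 0
    theta = np.mod(np.degrees(np.arctan2(gy, gx)), 180.0)
    bins = np.minimum(np.floor(theta).astype(int), 179)
    if weighting == "energy":
        w = energy
    elif weighting == "count":
        w = (energy > 0).astype(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    mass = np.bincount(bins.ravel(), weights=w.ravel(), minlength=180)
    mass = mass / mass.sum()
    return OrientationHistogram(mass=mass, bin_centers_deg=np.arange(180) + 0.5)


def directionality_summary(
    images, weighting: str = "energy", smooth_sigma_bins: float = 2.0
):
    """Across-image mean and s.e.m. of directionality histograms.

    Gaussian smoothing (circular, default sigma = 2 bins) is applied to the
    mean curve only, never to the per-image masses.
    """
    masses = np.stack([directionality_histogram(im, weighting).mass for im in images])
    mean = masses.mean(axis=0)
    sem = masses.std(axis=0, ddof=1) / np.sqrt(len(masses)) if len(masses) > 1 else np.zeros(180)
    if smooth_sigma_bins and smooth_sigma_bins > 0:
        mean = ndimage.gaussian_filter1d(mean, smooth_sigma_bins, mode="wrap")
    return mean, sem


def _angular_size(geometry) -> float:
    if isinstance(geometry, DisplayGeometry):
        return geometry.angular_size_deg
    if isinstance(geometry, CameraGeometry):
        return geometry.fov_deg
    size = float(geometry)
    if size <= 0:
        raise InvalidGeometryError("angular size must be > 0 degrees")
    return size


def radial_sf_spectrum(image: np.ndarray, geometry) -> RadialSpectrum:
    """Orientation-averaged power spectrum of one image, axis in cpd.

    Energies of the centered 2-D power spectrum are averaged within
    integer-Euclidean-distance annuli around the zero frequency; the radius
    (cycles/image) divided by the image's angular size gives cycles/degree.
    ``geometry`` may be a DisplayGeometry, a CameraGeometry, or an angular
    size in degrees.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    size_deg = _angular_size(geometry)
    power = np.abs(np.fft.fftshift(np.fft.fft2(img))) ** 2
    h, w = img.shape
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    radius = np.rint(np.hypot(yy - cy, xx - cx)).astype(int)
    counts = np.bincount(radius.ravel())
    sums = np.bincount(radius.ravel(), weights=power.ravel())
    energy = sums / counts
    freq = np.arange(len(energy)) / size_deg
    return RadialSpectrum(freq_cpd=freq, energy=energy, counts=counts)


def raw_coefficient_correlation(
    movie: CloudMovie | np.ndarray,
    neighborhood: int = 51,
    crop_to: tuple[int, int] | None = (256, 512),
    downsample: int = 2,
    lowpass_sigma_px: float = 2.0,
    normalized: bool = True,
) -> AutocorrMap:
    """Central spatial autocorrelation of lowpass-filtered stimulus frames.

    Each frame is center-cropped (when larger than ``crop_to``), block-mean
    downsampled, Gaussian lowpass filtered, mean-subtracted, and circularly
    autocorrelated via the FFT; the ``neighborhood`` x ``neighborhood``
    window around zero lag is averaged over frames.  With
    ``normalized=True`` coefficients are divided by the frame variance so
    the zero-lag value is 1.
    """
    if neighborhood % 2 == 0:
        raise ValueError("neighborhood must be odd (unique center)")
    frames = movie.frames if isinstance(movie, CloudMovie) else np.asarray(movie, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    maps = []
    for frame in frames:
        f = np.asarray(frame, dtype=float)
        if crop_to is not None and (f.shape[0] > crop_to[0] or f.shape[1] > crop_to[1]):
            th, tw = min(f.shape[0], crop_to[0]), min(f.shape[1], crop_to[1])
            y0 = (f.shape[0] - th) // 2
            x0 = (f.shape[1] - tw) // 2
            f = f[y0:y0 + th, x0:x0 + tw]
        if downsample > 1:
            h = (f.shape[0] // downsample) * downsample
            w = (f.shape[1] // downsample) * downsample
            f = f[:h, :w].reshape(h // downsample, downsample, w // downsample, downsample
                                  ).mean(axis=(1, 3))
        if lowpass_sigma_px and lowpass_sigma_px > 0:
            f = ndimage.gaussian_filter(f, lowpass_sigma_px, mode="wrap")
        if min(f.shape) <= neighborhood:
            raise ValueError("frames (after preprocessing) must exceed the neighborhood")
        f = f - f.mean()
        var = f.var()
        if var == 0:
            raise DegenerateDataError("constant frame has undefined autocorrelation")
        spec = np.fft.fft2(f)
        acf = np.fft.ifft2(spec * np.conj(spec)).real / f.size
        acf = np.fft.fftshift(acf)
        if normalized:
            acf = acf / var
        cy, cx = f.shape[0] // 2, f.shape[1] // 2
        half = neighborhood // 2
        maps.append(acf[cy - half:cy + half + 1, cx - half:cx + half + 1])
    return AutocorrMap(coefficients=np.mean(maps, axis=0), neighborhood=neighborhood,
                       normalized=normalized)
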