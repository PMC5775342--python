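"""Comparator striation metrics: Gabor filter-bank and 2-D Fourier scores.

Both are classical alternatives to co-occurrence texture analysis and serve
as head-to-head baselines:

* **Gabor score** — a bank of Gabor filters over wavelengths and
  orientations; per orientation, the cell-area-normalized response magnitude
  versus wavelength is decomposed into an aperiodic quadratic component plus
  a Gaussian periodic component, and the score is the maximum Gaussian
  *amplitude* (height) over orientations.
* **Fourier score** — the 2-D FFT magnitude of the cell's bounding box,
  radially integrated over 360 one-degree sectors into a frequency profile,
  decomposed into two exponentials (aperiodic) plus a Gaussian (periodic);
  the score is the *area* under the Gaussian.

The Fourier score operates on a bounding box, so cell-shape edges leak into
the spectrum; this shape sensitivity is exactly what mask-respecting
co-occurrence analysis avoids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit.models import ExponentialModel, GaussianModel, QuadraticModel
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

__all__ = [
    "FitDecomposition",
    "default_wavelengths",
    "default_orientations",
    "gabor_score",
    "fourier_score",
    "radial_profile",
]


@dataclass
class FitDecomposition:
    """Aperiodic + Gaussian decomposition of a 1-D response profile."""

    aperiodic: dict
    gaussian_amplitude: float  # Gaussian height
    gaussian_area: float
    gaussian_center: float
    gaussian_sigma: float
    amplitude_stderr: float | None
    area_stderr: float | None
    residual_norm: float


def default_wavelengths() -> np.ndarray:
    """10 log-spaced wavelengths, 4–32 px, spanning plausible striation periods."""
    return np.geomspace(4.0, 32.0, 10)


def default_orientations() -> np.ndarray:
    """16 orientations, 0°–168.75° in 11.25° steps."""
    return np.arange(16) * 11.25


def _fit_profile(x, y, model, params_fn, centers):
    """Multi-start least-squares fit; returns the best lmfit result or None."""
    best = None
    for c0 in centers:
        params = params_fn(c0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(y, params, x=x, max_nfev=300)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    return best


def _decomposition(res, aperiodic_names, dx=None) -> FitDecomposition:
    p = res.params
    sigma = p["g_sigma"].value
    area = p["g_amplitude"].value  # lmfit Gaussian amplitude == area
    height = p["g_height"].value
    area_err = p["g_amplitude"].stderr
    height_err = p["g_height"].stderr
    if area_err is None and dx is not None and res.nfree > 0:
        # bound-pinned parameters leave no covariance estimate; fall back to
        # the linearized single-parameter error of the Gaussian area:
        # Var(A) = s² / Σ (∂model/∂A)² with s the residual standard deviation
        s = float(np.sqrt(res.chisqr / res.nfree))
        area_err = s * float(np.sqrt(2.0 * np.sqrt(np.pi) * sigma * dx))
        if height_err is None and sigma > 0:
            height_err = area_err / (sigma * np.sqrt(2 * np.pi))
    return FitDecomposition(
        aperiodic={n: p[n].value for n in aperiodic_names},
        gaussian_amplitude=float(height),
        gaussian_area=float(area),
        gaussian_center=float(p["g_center"].value),
        gaussian_sigma=float(sigma),
        amplitude_stderr=None if height_err is None else float(height_err),
        area_stderr=None if area_err is None else float(area_err),
        residual_norm=float(np.sqrt(res.chisqr)),
    )


def gabor_score(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
    orientations: np.ndarray | None = None,
    full_output: bool = False,
):
    """Periodic-component score from a Gabor filter bank.

    For each orientation, the mean in-mask response magnitude is profiled
    against wavelength and fitted (trust-region least squares, 3 starts over
    the Gaussian center) to quadratic + Gaussian with nonnegative Gaussian
    amplitude; a quadratic aperiodic term tracks the slow rise of the
    response at long wavelengths.  The score is the maximum fitted Gaussian
    height over orientations.  Orientations whose fit fails are skipped; if
    all fail the score is 0 with a warning.
    """
    image = np.asarray(image, dtype=np.float64)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    wavelengths = default_wavelengths() if wavelengths is None else np.asarray(wavelengths)
    orientations = default_orientations() if orientations is None else np.asarray(orientations)
    if len(wavelengths) < 6:
        raise ValueError("need at least 6 wavelengths")
    if len(orientations) < 8:
        raise ValueError("need at least 8 orientations")

    area = mask.sum()
    # zero-mean input: the DC gain of low-frequency Gabor kernels would
    # otherwise masquerade as a periodic component on flat images
    image = image - image[mask].mean()
    model = QuadraticModel(prefix="q_") + GaussianModel(prefix="g_")
    lam_lo, lam_hi = float(wavelengths.min()), float(wavelengths.max())

    best_score, best_fit, best_theta = 0.0, None, None
    any_fit = False
    for theta in orientations:
        mags = np.empty(len(wavelengths))
        for k, lam in enumerate(wavelengths):
            kern = gabor_kernel(frequency=1.0 / lam, theta=np.deg2rad(theta))
            resp_r = fftconvolve(image, np.real(kern), mode="same")
            resp_i = fftconvolve(image, np.imag(kern), mode="same")
            mags[k] = np.hypot(resp_r, resp_i)[mask].sum() / area

        def params_fn(c0, _mags=mags):
            p = model.make_params()
            coefs = np.polyfit(wavelengths, _mags, 2)
            p["q_a"].set(value=coefs[0])
            p["q_b"].set(value=coefs[1])
            p["q_c"].set(value=coefs[2])
            resid = _mags - np.polyval(coefs, wavelengths)
            amp0 = max(float(resid.max()), 0.0)
            p["g_center"].set(value=c0, min=lam_lo, max=lam_hi)
            p["g_sigma"].set(value=2.0, min=0.3, max=lam_hi)
            p["g_amplitude"].set(value=amp0 * 2.0 * np.sqrt(2 * np.pi), min=0.0)
            return p

        res = _fit_profile(wavelengths, mags, model, params_fn,
                           centers=(lam_lo * 2, np.sqrt(lam_lo * lam_hi), lam_hi / 2))
        if res is None:
            continue
        any_fit = True
        height = float(res.params["g_height"].value)
        if height > best_score:
            best_score = height
            best_fit = _decomposition(res, ("q_a", "q_b", "q_c"))
            best_theta = float(theta)
    if not any_fit:
        warnings.warn("all Gabor profile fits failed; score set to 0", stacklevel=2)
    if full_output:
        return best_score, best_fit, best_theta
    return best_score


def radial_profile(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FFT-magnitude frequency profile integrated over 360 directions.

    The centered magnitude spectrum is sampled along 360 one-degree rays and
    accumulated per radial-frequency bin (one frequency sample wide), giving
    each radius the same angular multiplicity; a decaying spectrum therefore
    yields a decaying profile, which is what the aperiodic two-exponential
    component of the score fit assumes.  Returns (frequency in cycles/px,
    integrated magnitude); DC is excluded.
    """
    from scipy.ndimage import map_coordinates

    image = np.asarray(image, dtype=np.float64)
    spec = np.abs(np.fft.fftshift(np.fft.fft2(image - image.mean())))
    h, w = spec.shape
    cy, cx = h // 2, w // 2
    rmax = min(cy, cx) - 1
    radii = np.arange(1, rmax + 1, dtype=np.float64)
    theta = np.deg2rad(np.arange(360))
    rows = cy + radii[:, None] * np.sin(theta)[None, :]
    cols = cx + radii[:, None] * np.cos(theta)[None, :]
    samples = map_coordinates(spec, [rows.ravel(), cols.ravel()], order=1)
    total = samples.reshape(len(radii), 360).sum(axis=1)
    freq = radii / min(h, w)
    keep = freq <= 0.5
    return freq[keep], total[keep]


def fourier_score(
    image: np.ndarray,
    bbox: tuple[int, int, int, int] | None = None,
    full_output: bool = False,
):
    """Periodic-component score from the bounding-box Fourier spectrum.

    ``bbox`` is (min_row, min_col, max_row, max_col); the default is the
    whole image.  The radial frequency profile is fitted to two exponentials
    plus a Gaussian (nonnegative amplitude, 3 starts over the center); the
    score is the area under the fitted Gaussian.  A failed fit scores 0 with
    a warning.
    """
    image = np.asarray(image, dtype=np.float64)
    if bbox is not None:
        r0, c0, r1, c1 = bbox
        image = image[r0:r1, c0:c1]
    if min(image.shape) < 32:
        raise ValueError(f"bounding box {image.shape} is below the 32x32 minimum")

    x, y = radial_profile(image)
    scale = y.max()
    if scale <= 0:
        if full_output:
            return 0.0, None
        return 0.0
    yn = y / scale

    model = (ExponentialModel(prefix="e1_") + ExponentialModel(prefix="e2_")
             + GaussianModel(prefix="g_"))

    def params_fn(c0):
        p = model.make_params()
        p["e1_amplitude"].set(value=yn[0], min=0.0)
        p["e1_decay"].set(value=0.02, min=1e-4, max=2.0)
        p["e2_amplitude"].set(value=yn[0] / 4, min=0.0)
        p["e2_decay"].set(value=0.2, min=1e-4, max=5.0)
        # a periodic striation component is a narrow spectral peak; the broad
        # background belongs to the exponentials
        p["g_center"].set(value=c0, min=max(float(x[0]), 0.02), max=0.45)
        p["g_sigma"].set(value=0.015, min=0.002, max=0.06)
        p["g_amplitude"].set(value=0.01, min=0.0)
        return p

    res = _fit_profile(x, yn, model, params_fn, centers=(0.06, 0.125, 0.25))
    if res is None:
        warnings.warn("Fourier profile fit failed; score set to 0", stacklevel=2)
        if full_output:
            return 0.0, None
        return 0.0
    dec = _decomposition(res, ("e1_amplitude", "e1_decay", "e2_amplitude", "e2_decay"),
                         dx=float(np.median(np.diff(x))))
    # undo the profile normalization so scores are comparable across cells
    dec.gaussian_area *= scale
    dec.gaussian_amplitude *= scale
    if dec.area_stderr is not None:
        dec.area_stderr *= scale
    if dec.amplitude_stderr is not None:
        dec.amplitude_stderr *= scale
    dec.residual_norm *= scale
    score = float(dec.gaussian_area)
    if full_output:
        return score, dec
    return score
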