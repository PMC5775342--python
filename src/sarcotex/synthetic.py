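"""Synthetic ground-truth imagery: stripe phantoms and multi-channel cell fields.

Two generators make every downstream stage testable without real micrographs:

* :func:`make_stripes` builds idealized sarcomere striation images — periodic
  bands of known period, orientation, duty cycle, noise level, spatial
  coverage and per-band jitter.  These emulate the canonical test patterns for
  texture-based striation analysis (plain, rotated, re-scaled, noisy,
  partial-coverage and randomly offset bands).
* :func:`make_cell_field` lays out non-overlapping cells with known nucleus
  positions, marker combinations (α-actinin / Hcn4 / Nppa), boundary polygons
  and striped α-actinin texture of known period and direction, so the
  segmentation→classification→texture pipeline can be scored against exact
  truth.

Angle convention (used package-wide): an orientation θ in degrees, 0 ≤ θ <
180, names the axis along which intensity is periodic, with 0° along +x
(columns) and angles increasing counterclockwise on screen.  The unit vector
of that axis in (row, col) coordinates is ``(-sin θ, cos θ)``.  Horizontal
bands (periodic top-to-bottom) therefore have θ = 90°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask  # noqa: F401  (re-export convenience)
from skimage.measure import find_contours
from skimage.morphology import dilation, disk

from .stack import ChannelStack, DEFAULT_PIXEL_SIZE_UM


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed without overlap."""


@dataclass(frozen=True)
class StripePhantom:
    """An idealized striation image with exhaustive ground truth."""

    image: np.ndarray
    period_px: float
    orientation_deg: float
    duty: float
    noise_sd: float
    coverage: float
    jitter_sd: float


@dataclass
class CellPhantomTruth:
    """Ground truth for one synthetic cell."""

    cell_id: int
    centroid: tuple[float, float]
    boundary: np.ndarray  # (N, 2) array of (row, col) vertices
    nucleus_centers: list[tuple[float, float]]
    actinin: bool
    hcn4: bool
    nppa: bool
    period_px: float
    orientation_deg: float  # periodicity axis of the α-actinin texture
    major_axis_deg: float

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_centers)


def _axis_coords(shape, orientation_deg):
    """Return (u, t): coordinates along / across the periodicity axis.

    Both are measured from the image center so that regenerating with a
    rotated orientation matches rotating the image about its center.
    """
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    rows -= (h - 1) / 2.0
    cols -= (w - 1) / 2.0
    th = math.radians(orientation_deg)
    u = cols * math.cos(th) - rows * math.sin(th)
    t = cols * math.sin(th) + rows * math.cos(th)
    return u, t


def make_stripes(
    shape: tuple[int, int] = (128, 128),
    period_px: float = 8.0,
    orientation_deg: float = 90.0,
    duty: float = 0.5,
    noise_sd: float = 0.0,
    coverage: float = 1.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    *,
    lo: float = 0.2,
    hi: float = 0.8,
    smooth_sigma: float = 1.0,
    profile: str = "bands",
    jitter_band_px: float | None = None,
) -> StripePhantom:
    """Generate a stripe phantom.

    Parameters
    ----------
    shape
        Image shape (rows, cols); each dimension must be ≥ 4×period_px.
    period_px
        Distance between band centers in pixels (≥ 2; sub-Nyquist periods
        are rejected).
    orientation_deg
        Direction along which intensity is periodic, in [0, 180).
    duty
        Band width as a fraction of the period, in (0, 1).
    noise_sd
        Standard deviation of additive Gaussian noise (image is clipped to
        [0, 1] afterwards).
    coverage
        Fraction of the image, measured along the periodicity axis, that
        contains stripes; the remainder is flat background.
    jitter_sd
        Standard deviation (px) of a random phase offset applied per lateral
        band, emulating serially misregistered striations.
    lo, hi
        Background / band intensity levels.
    smooth_sigma
        Gaussian smoothing of the hard-edged bands (0 disables; the default
        1 px softens raster edges).
    profile
        ``"bands"`` for rectangular bands, ``"sine"`` for a sinusoidal
        intensity profile.
    jitter_band_px
        Lateral width of independently jittered bands (default 2×period).
    """
    period_px = float(period_px)
    if period_px < 2:
        raise ValueError(f"period_px must be ≥ 2 (got {period_px}): sub-Nyquist stripes")
    if not (0 < duty < 1):
        raise ValueError("duty must lie in (0, 1)")
    if not (0 < coverage <= 1):
        raise ValueError("coverage must lie in (0, 1]")
    if min(shape) < 4 * period_px:
        raise ValueError(f"each image dimension must be ≥ 4×period_px ({4 * period_px:g})")
    orientation_deg = float(orientation_deg) % 180.0

    rng = np.random.default_rng(seed)
    u, t = _axis_coords(shape, orientation_deg)

    if jitter_sd > 0:
        bw = jitter_band_px if jitter_band_px else 2.0 * period_px
        band_idx = np.floor(t / bw).astype(np.int64)
        uniq, inv = np.unique(band_idx, return_inverse=True)
        offsets = rng.normal(0.0, jitter_sd, size=uniq.size)
        u_eff = u + offsets[inv].reshape(u.shape)
    else:
        u_eff = u

    phase = np.mod(u_eff, period_px) / period_px
    if profile == "sine":
        img = lo + (hi - lo) * 0.5 * (1.0 + np.cos(2 * np.pi * phase))
    elif profile == "bands":
        img = np.where(phase < duty, hi, lo)
    else:
        raise ValueError(f"unknown profile {profile!r}")

    if coverage < 1.0:
        umin, umax = u.min(), u.max()
        striped = (u - umin) <= coverage * (umax - umin)
        img = np.where(striped, img, lo)

    img = img.astype(np.float64)
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    return StripePhantom(
        image=img,
        period_px=period_px,
        orientation_deg=orientation_deg,
        duty=duty,
        noise_sd=noise_sd,
        coverage=coverage,
        jitter_sd=jitter_sd,
    )


def make_sarcomere_phantom(
    shape: tuple[int, int] = (160, 160),
    period_px: float = 12.8,
    orientation_deg: float = 90.0,
    noise_sd: float = 0.0,
    coverage: float = 1.0,
    seed: int = 0,
) -> StripePhantom:
    """Striation phantom with realistic lateral myofibril misregistration.

    Identical to :func:`make_stripes` but with per-band phase jitter
    (sd 2.5 px over lateral bands one period wide).  Real striations are
    laterally incoherent — neighbouring myofibrils are registered only
    approximately — and that incoherence is what makes the primary striation
    direction identifiable: for perfectly coherent infinite stripes every
    sampling direction sees a periodic correlation trace (of the projected
    period), so the direction of maximum peak prominence is ill-posed.
    """
    return make_stripes(
        shape,
        period_px,
        orientation_deg,
        noise_sd=noise_sd,
        coverage=coverage,
        jitter_sd=2.5,
        jitter_band_px=period_px,
        seed=seed,
    )


def stripe_suite(seed: int = 0, shape=(128, 128)) -> dict[str, StripePhantom]:
    """The six canonical phantom variants used throughout the test suite.

    Horizontal bands, the same bands rotated 45°, a longer period, added
    noise, stripes confined to one third of the image, and bands with random
    per-band offset.
    """
    return {
        "horizontal": make_stripes(shape, 8, 90, seed=seed),
        "diagonal": make_stripes(shape, 8, 45, seed=seed),
        "long_period": make_stripes(shape, 16, 90, seed=seed),
        "noisy": make_stripes(shape, 8, 90, noise_sd=0.2, seed=seed),
        "partial": make_stripes(shape, 8, 90, coverage=1 / 3, seed=seed),
        "jittered": make_stripes(shape, 8, 90, jitter_sd=2.0, seed=seed),
    }


# ---------------------------------------------------------------------------
# multi-channel cell fields
# ---------------------------------------------------------------------------

#: default marker-combination table: (actinin, hcn4, nppa, n_nuclei) per cell.
#: Mirrors the subtype combinations the pipeline must distinguish: general
#: cardiomyocyte-like, pacemaker-like, atrial-like, dual/triple positives and
#: marker-mixtures, with two binucleated cells.
DEFAULT_SUBTYPE_TABLE: tuple[tuple[bool, bool, bool, int], ...] = (
    (True, False, False, 1),
    (True, False, False, 2),
    (True, False, False, 1),
    (True, True, False, 1),
    (True, True, False, 1),
    (True, False, True, 1),
    (True, False, True, 2),
    (False, True, False, 1),
    (False, True, False, 1),
    (True, True, True, 1),
)


def _perturbed_ellipse_mask(shape, center, a, b, axis_deg, rng):
    """Boolean mask of an ellipse with a mild radial boundary perturbation."""
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    dr = rows - center[0]
    dc = cols - center[1]
    th = math.radians(axis_deg)
    # major-axis coordinate along (-sin, cos), minor along the normal
    x = dc * math.cos(th) - dr * math.sin(th)
    y = dc * math.sin(th) + dr * math.cos(th)
    rho = np.hypot(x / a, y / b)
    psi = np.arctan2(y, x)
    amp3, amp5 = rng.uniform(0.03, 0.08), rng.uniform(0.02, 0.05)
    ph3, ph5 = rng.uniform(0, 2 * np.pi, 2)
    bound = 1.0 + amp3 * np.sin(3 * psi + ph3) + amp5 * np.sin(5 * psi + ph5)
    return rho <= bound


def _boundary_polygon(mask: np.ndarray) -> np.ndarray:
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        return np.empty((0, 2))
    return max(contours, key=len)


def make_cell_field(
    n_cells: int = 10,
    subtype_table=None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (512, 512),
    period_px: float = 12.8,
    nucleus_sigma_px: float = 4.0,
    binucleate_sep_px: float = 20.0,
    noise_sd: float = 0.01,
    max_tries: int = 300,
) -> tuple[ChannelStack, list[CellPhantomTruth]]:
    """Render a multi-channel field of non-overlapping synthetic cells.

    Each cell is a randomized perturbed ellipse.  The DAPI channel carries one
    Gaussian blob per nucleus; the α-actinin channel carries striped texture
    (period ``period_px``, periodic along the cell's major axis) inside
    actinin⁺ cells; the Hcn4 channel is filled inside hcn4⁺ cells; the Nppa
    channel is rendered only in a perinuclear annulus of nppa⁺ cells.
    Binucleated cells place their two nucleus centers ``binucleate_sep_px``
    (< 25 px) apart.  Nuclei of distinct cells are kept far enough apart that
    the binucleate join rule cannot bridge cells.

    Returns the stack and one :class:`CellPhantomTruth` per cell.  Raises
    :class:`PlacementError` if cells cannot be placed within ``max_tries``
    attempts each.
    """
    if subtype_table is None:
        subtype_table = DEFAULT_SUBTYPE_TABLE
    rows = [tuple(r) for r in subtype_table][:n_cells]
    while len(rows) < n_cells:
        rows.append(rows[len(rows) % len(subtype_table)])
    rows = [(bool(r[0]), bool(r[1]), bool(r[2]), int(r[3]) if len(r) > 3 else 1) for r in rows]

    rng = np.random.default_rng(seed)
    h, w = shape
    occupied = np.zeros(shape, dtype=bool)
    all_nucleus_centers: list[tuple[float, float]] = []

    dapi = np.zeros(shape)
    act = np.zeros(shape)
    hcn = np.zeros(shape)
    npp = np.zeros(shape)
    truths: list[CellPhantomTruth] = []
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)

    for cid, (f_act, f_hcn, f_npp, n_nuc) in enumerate(rows, start=1):
        placed = False
        for _ in range(max_tries):
            a = rng.uniform(30, 44)
            b = rng.uniform(17, min(28, a - 2))
            axis_deg = rng.uniform(0, 180)
            margin = a + 8
            center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            # nuclei near the cell center, along the major axis for binucleates
            th = math.radians(axis_deg)
            e = np.array([-math.sin(th), math.cos(th)])
            if n_nuc == 2:
                half = binucleate_sep_px / 2.0
                centers = [tuple(np.array(center) + s * half * e) for s in (-1, 1)]
            else:
                jitter = rng.uniform(-3, 3, size=2)
                centers = [tuple(np.array(center) + jitter)]
            # keep nuclei of different cells well beyond the 25 px join rule
            if any(
                math.hypot(c0[0] - c1[0], c0[1] - c1[1]) < 48
                for c0 in centers
                for c1 in all_nucleus_centers
            ):
                continue
            mask = _perturbed_ellipse_mask(shape, center, a, b, axis_deg, rng)
            grown = dilation(mask, disk(10))
            if (grown & occupied).any():
                continue
            # nucleus blobs (radius ~7 px once detected) must sit inside the cell
            if not all(mask[int(round(c[0])), int(round(c[1]))] for c in centers):
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {cid} of {n_cells} without overlap "
                f"after {max_tries} attempts; reduce n_cells or enlarge the field"
            )

        occupied |= grown
        nuc_mask = np.zeros(shape, dtype=bool)
        for c in centers:
            d2 = (rr - c[0]) ** 2 + (cc - c[1]) ** 2
            blob = np.exp(-d2 / (2 * nucleus_sigma_px**2))
            dapi = np.maximum(dapi, 0.9 * blob)
            nuc_mask |= blob > 0.35
            all_nucleus_centers.append(c)

        if f_act:
            # Z-line striation rides on a bright cytoplasmic α-actinin background,
            # so the in-cell modulation stays well above the cell/background edge.
            # Lateral bands are phase-jittered: neighbouring myofibrils register
            # only approximately, which is also what makes the striation
            # direction identifiable (see make_sarcomere_phantom).
            u = (cc - center[1]) * math.cos(th) - (rr - center[0]) * math.sin(th)
            tcoord = (cc - center[1]) * math.sin(th) + (rr - center[0]) * math.cos(th)
            band = np.floor(tcoord / period_px).astype(np.int64)
            uniq, inv = np.unique(band, return_inverse=True)
            u = u + rng.normal(0.0, 2.5, size=uniq.size)[inv].reshape(u.shape)
            phase = np.mod(u, period_px) / period_px
            tex = np.where(phase < 0.5, 0.9, 0.55)
            act = np.where(mask, tex, act)
        if f_hcn:
            hcn = np.where(mask, 0.65, hcn)
        if f_npp:
            ring = dilation(nuc_mask, disk(8)) & ~nuc_mask
            npp = np.where(ring, 0.5, npp)

        truths.append(
            CellPhantomTruth(
                cell_id=cid,
                centroid=center,
                boundary=_boundary_polygon(mask),
                nucleus_centers=centers,
                actinin=f_act,
                hcn4=f_hcn,
                nppa=f_npp,
                period_px=period_px,
                orientation_deg=axis_deg,
                major_axis_deg=axis_deg,
            )
        )

    channels = {}
    for name, img in (("dapi", dapi), ("actinin", act), ("hcn4", hcn), ("nppa", npp)):
        img = ndimage.gaussian_filter(img, 1.0)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, 1.0)

    return ChannelStack(channels, pixel_size_um), truths


def truth_table(truths: list[CellPhantomTruth]):
    """Tabulate cell-field ground truth as a DataFrame (one row per cell)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in truths],
            "centroid_row": [t.centroid[0] for t in truths],
            "centroid_col": [t.centroid[1] for t in truths],
            "n_nuclei": [t.n_nuclei for t in truths],
            "actinin": [t.actinin for t in truths],
            "hcn4": [t.hcn4 for t in truths],
            "nppa": [t.nppa for t in truths],
            "period_px": [t.period_px for t in truths],
            "orientation_deg": [t.orientation_deg for t in truths],
            "major_axis_deg": [t.major_axis_deg for t in truths],
        }
    )
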