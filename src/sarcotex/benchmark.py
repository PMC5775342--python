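"""Metric benchmarking on labeled phantom sets.

Builds the packaged discrimination fixture — masked striation phantoms with
organized versus disorganized texture — and scores every metric variant on
it: the four Haralick-surface scores (correlation, contrast, uniformity,
homogeneity), the Gabor score and the Fourier score.  A two-sample t-test
per metric summarizes how well each separates the groups.

The disorganized group is made by randomly permuting the pixels of an
organized phantom inside its mask: the intensity histogram is preserved
exactly while all spatial structure is destroyed, so any separation comes
from texture, not brightness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import fourier_score, gabor_score
from .sota import best_surface_peak, haralick_surfaces
from .synthetic import make_sarcomere_phantom

SOTA_FEATURES = ("correlation", "contrast", "uniformity", "homogeneity")
ALL_METRICS = tuple(f"sota_{f}" for f in SOTA_FEATURES) + ("gabor", "fourier")


def _ellipse_mask(shape, rng):
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    a = rng.uniform(0.36, 0.46) * w
    b = rng.uniform(0.26, 0.36) * h
    return (((cols - w / 2) / a) ** 2 + ((rows - h / 2) / b) ** 2) <= 1.0


def make_discrimination_fixture(
    n_per_group: int = 20,
    seed: int = 0,
    shape=(128, 128),
    period_px: float = 12.8,
):
    """Return (organized, disorganized): lists of (image, mask) pairs.

    Organized cells are stripe phantoms of fixed period, random orientation
    and mild noise inside random elliptical masks; each disorganized cell is
    the in-mask pixel permutation of the corresponding organized one.
    """
    rng = np.random.default_rng(seed)
    organized, disorganized = [], []
    for i in range(n_per_group):
        theta = rng.uniform(0, 180)
        ph = make_sarcomere_phantom(
            shape, period_px, theta, noise_sd=0.05,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mask = _ellipse_mask(shape, rng)
        organized.append((ph.image, mask))
        img = ph.image.copy()
        vals = img[mask]
        img[mask] = rng.permutation(vals)
        disorganized.append((img, mask))
    return organized, disorganized


def score_cell(image, mask, pixel_size_um: float = 0.15625) -> dict[str, float]:
    """All six metric variants for one masked cell image."""
    surfaces = haralick_surfaces(image, mask, SOTA_FEATURES)
    out = {}
    for f in SOTA_FEATURES:
        out[f"sota_{f}"] = best_surface_peak(surfaces[f])[0]
    out["gabor"] = float(gabor_score(image, mask))
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
    out["fourier"] = float(fourier_score(image * mask, bbox))
    return out


def score_groups(organized, disorganized, pixel_size_um: float = 0.15625) -> pd.DataFrame:
    """Score both groups; rows are cells, columns metrics plus ``group``."""
    rows = []
    for grp, cells in (("organized", organized), ("disorganized", disorganized)):
        for image, mask in cells:
            r = score_cell(image, mask, pixel_size_um)
            r["group"] = grp
            rows.append(r)
    return pd.DataFrame(rows)


def metric_pvalue_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Group means/SDs and two-sample t-test p per metric (−log10 p included)."""
    org = scores[scores["group"] == "organized"]
    dis = scores[scores["group"] == "disorganized"]
    rows = []
    for metric in [c for c in scores.columns if c != "group"]:
        a, b = org[metric].to_numpy(float), dis[metric].to_numpy(float)
        t, p = stats.ttest_ind(a, b)
        rows.append(
            {
                "metric": metric,
                "organized_mean": a.mean(),
                "organized_sd": a.std(ddof=1),
                "disorganized_mean": b.mean(),
                "disorganized_sd": b.std(ddof=1),
                "t": t,
                "p": p,
                "neglog10_p": -np.log10(p) if p > 0 else np.inf,
            }
        )
    return pd.DataFrame(rows).set_index("metric")
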