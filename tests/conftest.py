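"""Shared fixtures: synthetic fields and their segmentation, computed once."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sarcotex import PipelineConfig, make_cell_field, segment_field

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_field():
    """The canonical 10-cell synthetic field with ground truth (seed 0)."""
    stack, truths = make_cell_field(n_cells=10, seed=0)
    return stack, truths


@pytest.fixture(scope="session")
def segmented_field(default_field):
    """Segmentation of the canonical field under default configuration."""
    stack, truths = default_field
    cells, nuclei, nuc_labels, cell_labels = segment_field(stack, PipelineConfig())
    return {
        "stack": stack,
        "truths": truths,
        "cells": cells,
        "nuclei": nuclei,
        "nucleus_labels": nuc_labels,
        "cell_labels": cell_labels,
    }


def brute_force_glcm(image, mask, offset, levels, symmetric=True):
    """Independent GLCM oracle: explicit double loop over all pixel pairs."""
    image = np.asarray(image, dtype=float)
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    h, w = image.shape
    counts = np.zeros((levels, levels))
    dr, dc = offset

    def level_of(v):
        if hi <= lo:
            return 0
        k = int(np.floor((v - lo) / (hi - lo) * levels))
        return min(max(k, 0), levels - 1)

    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < h and 0 <= c2 < w):
                continue
            if mask[r, c] and mask[r2, c2]:
                counts[level_of(image[r, c]), level_of(image[r2, c2])] += 1
    if symmetric:
        counts = counts + counts.T
    return counts
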