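import numpy as np
import pytest

from traffiq.io import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_channel_stack(rng):
    """Small random two-channel stack for mask arithmetic tests."""
    return ImageStack(
        channels={
            "Cy5": rng.integers(0, 100, size=(4, 12, 12)).astype(float),
            "Cy3": rng.integers(0, 100, size=(4, 12, 12)).astype(float),
        }
    )


def brute_force_quartet(cy5, cy3, t5, t3):
    """Per-voxel loop oracle for the four endocytosis masks."""
    shape = cy5.shape
    m1 = np.zeros(shape, dtype=bool)
    m2 = np.zeros(shape, dtype=bool)
    m3 = np.zeros(shape, dtype=bool)
    m4 = np.zeros(shape, dtype=bool)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                m1[z, y, x] = cy5[z, y, x] >= t5
                m2[z, y, x] = cy3[z, y, x] >= t3
                m3[z, y, x] = m2[z, y, x] and m1[z, y, x]
                m4[z, y, x] = m2[z, y, x] and not m3[z, y, x]
    return m1, m2, m3, m4


def brute_force_coloc(a, b, ta, tb):
    """Per-voxel loop oracle for the colocalized fraction (no size filter)."""
    total_a = 0.0
    overlap_a = 0.0
    uptake_b = 0.0
    shape = a.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                in_a = a[z, y, x] >= ta
                in_b = b[z, y, x] >= tb
                if in_a:
                    total_a += a[z, y, x]
                    if in_b:
                        overlap_a += a[z, y, x]
                if in_b:
                    uptake_b += b[z, y, x]
    return overlap_a / total_a, uptake_b


def exhaustive_otsu(values, nbins=256):
    """Otsu threshold by exhaustive search over all histogram cut points,
    maximising between-class variance; returns the bin-centre threshold."""
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    best_t, best_var = centers[0], -1.0
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_t = centers[k]
    return best_t
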