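"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive results by exhaustive enumeration (nested
Python loops, flood fill) and are kept deliberately naive so they stay
independent of the library's vectorised implementations.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest
from hypothesis import settings

from petresponse import BinaryMask, ImageVolume, PhantomSpec, ValueKind

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Constructors


def volume(values, spacing=(1.0, 1.0, 1.0), kind=ValueKind.SUL, origin=(0.0, 0.0, 0.0)):
    return ImageVolume(values=np.asarray(values, dtype=np.float64), spacing=spacing, origin=origin, value_kind=kind)


def mask(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return BinaryMask(values=np.asarray(values, dtype=bool), spacing=spacing, origin=origin)


@pytest.fixture
def small_spec():
    """A coarse, fast phantom for pipeline-level tests."""
    return PhantomSpec(
        shape=(48, 48, 96),
        spacing=(4.0, 4.0, 4.0),
        body_semiaxes=(80.0, 60.0),
        lesion_count_mean=4.0,
        lesion_diameter_mm=(10.0, 24.0),
    )


# ---------------------------------------------------------------------------
# Brute-force SULpeak oracle


def sul_peak_oracle(sul: ImageVolume, m: BinaryMask, diameter_mm: float = 12.0):
    """Exhaustive sphere-mean search: all mask voxels x all image voxels."""
    r = diameter_mm / 2.0
    values = np.asarray(sul.values, dtype=np.float64)
    sx, sy, sz = sul.spacing
    best = None
    best_center = None
    for ci, cj, ck in np.argwhere(m.values):
        vals = []
        for i in range(values.shape[0]):
            for j in range(values.shape[1]):
                for k in range(values.shape[2]):
                    d2 = ((i - ci) * sx) ** 2 + ((j - cj) * sy) ** 2 + ((k - ck) * sz) ** 2
                    if d2 <= r * r:
                        vals.append(values[i, j, k])
        mean = np.mean(np.asarray(vals))
        if best is None or mean > best:
            best, best_center = mean, (int(ci), int(cj), int(ck))
    return best, best_center


# ---------------------------------------------------------------------------
# Brute-force flood-fill labelling oracle


_NEIGHBORS = {
    6: [(di, dj, dk) for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
        if abs(di) + abs(dj) + abs(dk) == 1],
    18: [(di, dj, dk) for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
         if 0 < abs(di) + abs(dj) + abs(dk) <= 2],
    26: [(di, dj, dk) for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
         if (di, dj, dk) != (0, 0, 0)],
}


def flood_fill_components(values: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components as voxel-index sets, by breadth-first flood fill."""
    values = np.asarray(values, dtype=bool)
    seen = np.zeros_like(values)
    comps = []
    for start in map(tuple, np.argwhere(values)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for off in _NEIGHBORS[connectivity]:
                n = tuple(a + b for a, b in zip(v, off))
                if all(0 <= c < s for c, s in zip(n, values.shape)) and values[n] and not seen[n]:
                    seen[n] = True
                    queue.append(n)
        comps.append(comp)
    return comps


def detection_oracle(gt: np.ndarray, pred: np.ndarray, threshold: float = 0.5, connectivity: int = 26):
    """Per-component overlap counting on voxel-index sets."""
    gt_set = set(map(tuple, np.argwhere(gt)))
    pred_set = set(map(tuple, np.argwhere(pred)))
    tp = fn = fp = 0
    for comp in flood_fill_components(gt, connectivity):
        if len(comp & pred_set) / len(comp) >= threshold:
            tp += 1
        else:
            fn += 1
    for comp in flood_fill_components(pred, connectivity):
        if len(comp & gt_set) / len(comp) < threshold:
            fp += 1
    return tp, fn, fp


def random_scene(rng: np.random.Generator, shape=(16, 16, 16), n_blobs=(1, 5), spacing=(1.0, 1.0, 1.0)):
    """A random blobby binary mask for oracle-equivalence tests."""
    m = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(*n_blobs)):
        c = rng.integers(0, shape[0], size=3)
        r = rng.integers(1, 4)
        g = np.ogrid[: shape[0], : shape[1], : shape[2]]
        m |= sum((gi - ci) ** 2 for gi, ci in zip(g, c)) <= r**2
    return m
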