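"""Circular-particle detection by the circle Hough transform.

Candidate lysosomes are circular puncta in a configured radius window
(default 2-10 px).  Edges from a Canny filter vote in a circle Hough
accumulator over that radius range; accumulator peaks above a sensitivity
floor become candidates, each carrying an estimated center, radius, the
mean disk intensity (as a fraction of saturation) and a circularity score —
the normalized accumulator support, i.e. the fraction of the circle
perimeter backed by edge evidence (1.0 = a complete circle).  Nearby
detections are merged, keeping the stronger peak.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.feature import canny, peak_local_max
from skimage.transform import hough_circle

from .types import CandidateParticle, FieldOfView

DEFAULT_RADIUS_RANGE = (2, 10)  # px, the lysosome acceptance window


def mean_disk_intensity(img: np.ndarray, center, radius: float, saturation: float) -> float:
    rr, cc = draw_disk(center, max(radius, 1.0), shape=img.shape)
    if rr.size == 0:
        return 0.0
    return float(img[rr, cc].mean() / saturation)


def _annulus_intensity(img: np.ndarray, center, radius: float) -> float:
    rr_o, cc_o = draw_disk(center, radius * 1.8 + 1.0, shape=img.shape)
    rr_i, cc_i = draw_disk(center, radius * 1.15, shape=img.shape)
    inner = set(zip(rr_i.tolist(), cc_i.tolist()))
    pts = [(r, c) for r, c in zip(rr_o.tolist(), cc_o.tolist()) if (r, c) not in inner]
    if not pts:
        return 0.0
    idx = np.array(pts)
    return float(img[idx[:, 0], idx[:, 1]].mean())


def detect_candidates(
    fov: FieldOfView,
    radius_range: tuple[int, int] = DEFAULT_RADIUS_RANGE,
    circularity_tolerance: float = 0.4,
    sensitivity: float = 0.35,
    channel: str = "lysosomal",
    canny_sigma: float = 1.0,
    min_contrast: float = 0.05,
) -> list[CandidateParticle]:
    """Detect circular candidates on one channel.

    Accumulator local maxima above ``sensitivity`` become candidate circles;
    duplicates closer than one radius are merged (stronger peak kept).  A
    candidate must then pass two criteria: circularity (normalized perimeter
    support, ideal value 1.0) of at least ``circularity_tolerance``, and a
    photometric check — the mean disk intensity must exceed the surrounding
    annulus by ``min_contrast`` of saturation (sufficient fluorescent
    signal), which suppresses phantom circles assembled from the edges of
    several neighbours.
    """
    lo, hi = int(radius_range[0]), int(radius_range[1])
    h, w = fov.shape
    if lo < 1 or hi <= lo or hi > min(h, w) // 2:
        raise ValueError(f"radius_range {radius_range} invalid for image {h}x{w}")
    img = fov.channel(channel) / fov.saturation_value
    edges = canny(img, sigma=canny_sigma)
    if not edges.any():
        return []
    radii = np.arange(lo, hi + 1)
    accum = hough_circle(edges, radii)  # normalized per-radius accumulator

    floor = max(sensitivity, circularity_tolerance * 0.5, 0.05)
    cands: list[tuple[float, int, int, int]] = []  # (score, radius, row, col)
    for ridx, radius in enumerate(radii):
        acc = accum[ridx]
        peaks = peak_local_max(acc, min_distance=2, threshold_abs=floor, exclude_border=False)
        for r0, c0 in peaks:
            cands.append((float(acc[r0, c0]), int(radius), int(r0), int(c0)))
    if not cands:
        return []
    cands.sort(reverse=True)

    kept: list[tuple[float, int, int, int]] = []
    for score, radius, r0, c0 in cands:
        if any(
            np.hypot(r0 - krow, c0 - kcol) <= max(radius, kr)
            for _, kr, krow, kcol in kept
        ):
            continue
        kept.append((score, radius, r0, c0))

    out = []
    for score, radius, r0, c0 in kept:
        circ = min(score, 1.0)
        if circ < circularity_tolerance:
            continue
        mean_i = mean_disk_intensity(
            fov.channel(channel), (r0, c0), radius, fov.saturation_value
        )
        if min_contrast > 0:
            bg = _annulus_intensity(img, (r0, c0), radius)
            if mean_i - bg < min_contrast:
                continue
        out.append(
            CandidateParticle(
                center=(float(r0), float(c0)),
                radius=float(radius),
                mean_intensity=mean_i,
                circularity=circ,
            )
        )
    return out
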