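"""Per-cell and spatial statistics of classified lysosomes."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .detect import detect_candidates
from .types import (
    CandidateParticle,
    CellRegions,
    DistanceHistogram,
    FieldOfView,
    LysosomeStats,
)

MAGIC_RED_PRUNE_FRACTION = 0.15  # particles dimmer than this fraction of saturation are pruned


def _accepted(particles: list[CandidateParticle]) -> list[CandidateParticle]:
    return [p for p in particles if p.accepted]


def lysosomes_per_cell(
    particles: list[CandidateParticle], regions: CellRegions
) -> LysosomeStats:
    """Accepted particles inside the cell mask, normalized by nucleus count.

    A field with zero nuclei yields ``lysosomes_per_cell = None`` and is
    flagged for exclusion from hierarchical aggregation.
    """
    acc = _accepted(particles)
    inside = [
        p
        for p in acc
        if regions.cell_mask[int(round(p.center[0])), int(round(p.center[1]))]
    ]
    n_nuc = regions.n_nuclei
    stats = LysosomeStats(
        n_nuclei=n_nuc,
        n_lysosomes=len(inside),
        lysosomes_per_cell=(len(inside) / n_nuc) if n_nuc > 0 else None,
        particle_areas_px2=np.array([np.pi * p.radius**2 for p in inside]),
        flagged=n_nuc == 0,
    )
    return stats


def nucleus_distances(
    particles: list[CandidateParticle], nucleus_labels: np.ndarray
) -> np.ndarray:
    """Euclidean-distance-transform distance from each accepted particle
    center to the nearest nucleus pixel (0 inside nuclei)."""
    if not np.any(nucleus_labels > 0):
        raise ValueError("need >= 1 nucleus for distance statistics")
    edt = ndi.distance_transform_edt(nucleus_labels == 0)
    acc = _accepted(particles)
    return np.array(
        [edt[int(round(p.center[0])), int(round(p.center[1]))] for p in acc]
    )


def half_max_distance(counts: np.ndarray, centers: np.ndarray) -> float | None:
    """Distance where frequency first falls to half the modal frequency,
    searched on the decreasing (right) flank of the mode, with linear
    interpolation between bin centers."""
    if counts.sum() == 0:
        return None
    imode = int(np.argmax(counts))
    half = counts[imode] / 2.0
    for i in range(imode, len(counts) - 1):
        if counts[i] >= half >= counts[i + 1]:
            t = (counts[i] - half) / (counts[i] - counts[i + 1] + 1e-12)
            return float(centers[i] + t * (centers[i + 1] - centers[i]))
    return float(centers[-1])


def nucleus_distance_histogram(
    particles: list[CandidateParticle],
    nucleus_labels: np.ndarray,
    bins: int | np.ndarray = 20,
) -> DistanceHistogram:
    """Histogram of lysosome-to-nearest-nucleus distances with the
    half-maximal-abundance marker.  No accepted particles yields an empty
    (but valid) histogram."""
    acc = _accepted(particles)
    if not acc:
        edges = np.linspace(0, 1, 2) if np.isscalar(bins) else np.asarray(bins)
        return DistanceHistogram(
            bin_edges=edges, counts=np.zeros(len(edges) - 1), half_max_distance=None
        )
    d = nucleus_distances(particles, nucleus_labels)
    counts, edges = np.histogram(d, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DistanceHistogram(
        bin_edges=edges,
        counts=counts.astype(float),
        half_max_distance=half_max_distance(counts.astype(float), centers),
    )


def magic_red_count(
    fov: FieldOfView,
    regions: CellRegions,
    radius_range: tuple[int, int] = (2, 10),
    prune_fraction: float = MAGIC_RED_PRUNE_FRACTION,
    sensitivity: float = 0.35,
    circularity_tolerance: float = 0.65,
) -> tuple[float | None, list[CandidateParticle]]:
    """Cathepsin-activity puncta per segmented cell.

    Particles are detected on the activity channel with the lysosome radius
    window; particles of mean fluorescence below ``prune_fraction`` of the
    saturating signal are pruned.  Returns (count per cell or None when the
    field has no nuclei, the retained particles).
    """
    if "activity" not in fov.channels:
        raise ValueError("field of view has no 'activity' channel")
    if fov.saturation_value is None or fov.saturation_value <= 0:
        raise ValueError("saturation_value required for intensity pruning")
    cands = detect_candidates(
        fov,
        radius_range=radius_range,
        channel="activity",
        sensitivity=sensitivity,
        circularity_tolerance=circularity_tolerance,
    )
    kept = [p for p in cands if p.mean_intensity >= prune_fraction]
    for p in kept:
        p.accepted = True
    inside = [
        p
        for p in kept
        if regions.cell_mask[int(round(p.center[0])), int(round(p.center[1]))]
    ]
    n_nuc = regions.n_nuclei
    return (len(inside) / n_nuc if n_nuc > 0 else None), kept
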