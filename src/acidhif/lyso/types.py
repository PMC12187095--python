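"""Core containers for the lysosome imaging pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FieldOfView:
    """Multi-channel 2-D image with named channel roles.

    Channels are float arrays of identical shape; intensities are expressed
    relative to ``saturation_value`` (pixel coordinates are 0-based
    (row, col)).  Standard roles: "nuclear", "lysosomal", "activity".
    """

    channels: dict[str, np.ndarray]
    saturation_value: float = 1.0
    pixel_size_um: float | None = None

    def __post_init__(self):
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        if self.saturation_value <= 0:
            raise ValueError("saturation_value must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise KeyError(f"channel role {role!r} not present (have {sorted(self.channels)})")
        return self.channels[role]


@dataclass
class CandidateParticle:
    """A detected circular object, before/after classification."""

    center: tuple[float, float]  # (row, col), px
    radius: float  # px
    mean_intensity: float  # fraction of saturation over the disk
    circularity: float  # normalized perimeter support of the Hough peak
    accepted: bool | None = None


@dataclass
class CellRegions:
    """Cell-occupied mask plus the segmented nucleus label map."""

    cell_mask: np.ndarray  # bool
    nucleus_labels: np.ndarray  # int, 0 = background

    @property
    def n_nuclei(self) -> int:
        return int(len(np.unique(self.nucleus_labels[self.nucleus_labels > 0])))


@dataclass
class DistanceHistogram:
    """Binned lysosome-to-nearest-nucleus distances."""

    bin_edges: np.ndarray  # px
    counts: np.ndarray
    half_max_distance: float | None  # px, on the decreasing flank of the mode

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class LysosomeStats:
    """Per-field-of-view summary used for hierarchical aggregation."""

    n_nuclei: int
    n_lysosomes: int
    lysosomes_per_cell: float | None  # None when n_nuclei == 0
    particle_areas_px2: np.ndarray = field(default_factory=lambda: np.empty(0))
    particle_distances_px: np.ndarray = field(default_factory=lambda: np.empty(0))
    distance_histogram: DistanceHistogram | None = None
    flagged: bool = False
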