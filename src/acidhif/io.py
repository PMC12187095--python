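"""File round-tripping for the standard interchange formats.

Images travel as multi-page TIFF (one page per channel role, order
recorded), truth/particle tables and plates as tidy CSV, abundance
matrices as TSV (rows = proteins, columns = sample IDs) with a companion
design CSV, and calibrations as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .flux import CalibrationParams, O2ProbeCalibration, PhProbeCalibration
from .lyso.types import CandidateParticle, FieldOfView

DEFAULT_CHANNEL_ORDER = ("nuclear", "lysosomal", "activity")


def write_fov_tiff(fov: FieldOfView, path, channel_order=None) -> list[str]:
    """Write one page per channel; returns the page order used."""
    order = [r for r in (channel_order or DEFAULT_CHANNEL_ORDER) if r in fov.channels]
    order += [r for r in fov.channels if r not in order]
    pages = np.stack([fov.channels[r].astype(np.float32) for r in order])
    tifffile.imwrite(path, pages)
    return order


def read_fov_tiff(path, channel_roles, saturation_value: float = 1.0) -> FieldOfView:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if len(channel_roles) != len(pages):
        raise ValueError(f"{len(pages)} pages but {len(channel_roles)} roles given")
    return FieldOfView(
        channels={r: np.asarray(p, dtype=float) for r, p in zip(channel_roles, pages)},
        saturation_value=saturation_value,
    )


def write_label_tiff(labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, labels.astype(np.uint16))


def particles_to_frame(particles: list[CandidateParticle], fov_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fov": fov_id,
            "row": [p.center[0] for p in particles],
            "col": [p.center[1] for p in particles],
            "radius_px": [p.radius for p in particles],
            "intensity_frac": [p.mean_intensity for p in particles],
            "circularity": [p.circularity for p in particles],
            "accepted": [p.accepted for p in particles],
        }
    )


def truth_to_frame(truth_particles) -> pd.DataFrame:
    """Ground-truth CSV layout: center_row, center_col, radius_px, class, cell_id."""
    return pd.DataFrame(
        {
            "center_row": [p.center[0] for p in truth_particles],
            "center_col": [p.center[1] for p in truth_particles],
            "radius_px": [p.radius for p in truth_particles],
            "class": [p.class_label for p in truth_particles],
            "cell_id": [p.parent_cell for p in truth_particles],
        }
    )


def write_abundance_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="protein")


def read_abundance_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein")


def write_design_csv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def read_design_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_calibration_yaml(path) -> CalibrationParams:
    """Calibration YAML: top-level physical constants plus nested
    ``ph_probe`` (pka, ratio_min, ratio_max) and ``o2_probe``
    (intensity_at_zero_o2, stern_volmer_constant) blocks."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    ph = PhProbeCalibration(**cfg.pop("ph_probe", {}))
    o2 = O2ProbeCalibration(**cfg.pop("o2_probe", {}))
    return CalibrationParams(ph_probe=ph, o2_probe=o2, **cfg)


def save_calibration_yaml(cal: CalibrationParams, path) -> None:
    payload = {
        "ph_probe": {
            "pka": cal.ph_probe.pka,
            "ratio_min": cal.ph_probe.ratio_min,
            "ratio_max": cal.ph_probe.ratio_max,
        },
        "o2_probe": {
            "intensity_at_zero_o2": cal.o2_probe.intensity_at_zero_o2,
            "stern_volmer_constant": cal.o2_probe.stern_volmer_constant,
        },
        "buffering_capacity": cal.buffering_capacity,
        "o2_solubility": cal.o2_solubility,
        "volume": cal.volume,
        "oil_ingress_rate": cal.oil_ingress_rate,
        "atmospheric_po2": cal.atmospheric_po2,
    }
    Path(path).write_text(yaml.safe_dump(payload))
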