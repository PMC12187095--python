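"""Trained radius-intensity classification of candidate particles.

Mirrors the user-trained acceptance criterion: annotated candidates (is it
a lysosome or not?) are summarized as kernel-smoothed class-conditional
densities over the (radius, mean intensity) plane; with class priors taken
from training frequencies these give a posterior probability-of-lysosome
surface.  A candidate is accepted when its posterior meets the configured
threshold (default the 50% probability level).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import gaussian_kde

from .types import CandidateParticle


class TrainingError(ValueError):
    pass


RECOMMENDED_TRAINING_FLOOR = 6000  # annotations used for the published criterion


@dataclass
class RadiusIntensityClassifier:
    """Posterior probability-of-lysosome surface over (radius, intensity)."""

    radius_grid: np.ndarray
    intensity_grid: np.ndarray
    posterior: np.ndarray  # shape (len(radius_grid), len(intensity_grid)), in [0, 1]
    threshold: float
    n_training: int
    prior_lysosome: float

    def __post_init__(self):
        self._interp = RegularGridInterpolator(
            (self.radius_grid, self.intensity_grid),
            self.posterior,
            bounds_error=False,
            fill_value=None,
        )

    def probability(self, radius, intensity) -> np.ndarray:
        """Posterior P(lysosome | radius, intensity), clipped to [0, 1]."""
        pts = np.column_stack(
            [np.atleast_1d(radius).astype(float), np.atleast_1d(intensity).astype(float)]
        )
        # clamp queries onto the trained grid before interpolating
        pts[:, 0] = np.clip(pts[:, 0], self.radius_grid[0], self.radius_grid[-1])
        pts[:, 1] = np.clip(pts[:, 1], self.intensity_grid[0], self.intensity_grid[-1])
        return np.clip(self._interp(pts), 0.0, 1.0)

    def accepts(self, radius, intensity) -> np.ndarray:
        return self.probability(radius, intensity) >= self.threshold

    def to_json(self, path) -> None:
        payload = {
            "radius_grid": self.radius_grid.tolist(),
            "intensity_grid": self.intensity_grid.tolist(),
            "posterior": self.posterior.tolist(),
            "threshold": self.threshold,
            "n_training": self.n_training,
            "prior_lysosome": self.prior_lysosome,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RadiusIntensityClassifier":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            radius_grid=np.asarray(d["radius_grid"]),
            intensity_grid=np.asarray(d["intensity_grid"]),
            posterior=np.asarray(d["posterior"]),
            threshold=d["threshold"],
            n_training=d["n_training"],
            prior_lysosome=d["prior_lysosome"],
        )


def train_radius_intensity_classifier(
    annotated: list[tuple[CandidateParticle, bool]],
    threshold: float = 0.5,
    radius_grid: np.ndarray | None = None,
    intensity_grid: np.ndarray | None = None,
    min_training: int = 2,
) -> RadiusIntensityClassifier:
    """Fit the posterior surface from annotated (candidate, is_lysosome) pairs.

    Class-conditional densities are Gaussian-KDE estimates (Scott plug-in
    bandwidth) of each class's (radius, intensity) sample; the posterior
    combines them with training-frequency priors.  Both classes must be
    present.  ``min_training`` is a configurable floor on annotations; the
    published criterion used >= 6000.
    """
    if len(annotated) < max(min_training, 2):
        raise TrainingError(f"need >= {max(min_training, 2)} annotated particles")
    feats = np.array([[p.radius, p.mean_intensity] for p, _ in annotated], dtype=float)
    y = np.array([bool(lab) for _, lab in annotated])
    if y.all() or not y.any():
        raise TrainingError("training set must contain both classes")

    pos, neg = feats[y], feats[~y]
    if radius_grid is None:
        rmax = float(feats[:, 0].max()) + 2.0
        radius_grid = np.linspace(0.0, max(rmax, 12.0), 121)
    if intensity_grid is None:
        intensity_grid = np.linspace(0.0, 1.0, 101)

    def _kde(sample):
        # KDE needs spread in both dims; add a whisper of jitter-free ridge
        # via bandwidth floor by falling back to a tiny diagonal covariance
        try:
            return gaussian_kde(sample.T)
        except np.linalg.LinAlgError as exc:
            raise TrainingError("degenerate training sample (no spread)") from exc

    kde_pos, kde_neg = _kde(pos), _kde(neg)
    prior = float(y.mean())
    rg, ig = np.meshgrid(radius_grid, intensity_grid, indexing="ij")
    pts = np.vstack([rg.ravel(), ig.ravel()])
    f1 = kde_pos(pts).reshape(rg.shape)
    f0 = kde_neg(pts).reshape(rg.shape)
    denom = prior * f1 + (1.0 - prior) * f0
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(denom > 0, prior * f1 / np.where(denom > 0, denom, 1.0), 0.0)
    return RadiusIntensityClassifier(
        radius_grid=np.asarray(radius_grid, dtype=float),
        intensity_grid=np.asarray(intensity_grid, dtype=float),
        posterior=post,
        threshold=threshold,
        n_training=len(annotated),
        prior_lysosome=prior,
    )


def classify_particles(
    candidates: list[CandidateParticle], classifier: RadiusIntensityClassifier
) -> list[CandidateParticle]:
    """Set ``accepted`` on each candidate; returns the same list."""
    if not candidates:
        return candidates
    radii = np.array([c.radius for c in candidates])
    intens = np.array([c.mean_intensity for c in candidates])
    acc = classifier.accepts(radii, intens)
    for cand, a in zip(candidates, acc):
        cand.accepted = bool(a)
    return candidates
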