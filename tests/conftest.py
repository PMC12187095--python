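"""Shared fixtures: synthetic fields of view and a trained classifier.

Session-scoped so the image batch and the KDE training run once.
"""

import numpy as np
import pytest

from acidhif.lyso import classify_particles, detect_candidates, train_radius_intensity_classifier
from acidhif.simulate import SyntheticImageSpec, make_fov_image


def match_candidates(cands, truth, tol=3.0):
    """Greedy one-to-one matching of detections to truth by center distance."""
    used = set()
    pairs = []
    for c in sorted(cands, key=lambda c: -c.circularity):
        best, bd = None, np.inf
        for i, p in enumerate(truth):
            if i in used:
                continue
            d = np.hypot(c.center[0] - p.center[0], c.center[1] - p.center[1])
            if d < bd:
                bd, best = d, i
        if best is not None and bd <= tol:
            used.add(best)
            pairs.append((c, truth[best]))
    return pairs


@pytest.fixture(scope="session")
def fov_batch():
    """Twelve default-spec synthetic fields of view."""
    return [make_fov_image(SyntheticImageSpec(seed=s)) for s in range(12)]


@pytest.fixture(scope="session")
def trained_classifier():
    """Radius-intensity classifier trained on detections from held-out fields."""
    annotated = []
    for seed in range(100, 110):
        syn = make_fov_image(SyntheticImageSpec(seed=seed))
        cands = detect_candidates(syn.fov)
        for c, p in match_candidates(cands, syn.particles):
            annotated.append((c, p.class_label == "lysosome"))
    return train_radius_intensity_classifier(annotated)


@pytest.fixture(scope="session")
def classified_batch(fov_batch, trained_classifier):
    """(synthetic fov, classified candidate list) pairs for the default batch."""
    out = []
    for syn in fov_batch:
        cands = classify_particles(detect_candidates(syn.fov), trained_classifier)
        out.append((syn, cands))
    return out
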