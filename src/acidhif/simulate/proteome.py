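"""Synthetic label-free proteomics matrices with factorial structure.

Generates a proteins x samples log2-abundance matrix under a 2 (pH) x
2 (O2) x b (batch) design with planted response classes that mirror the
canonical hypoxia-response archetypes:

    A  - hypoxic induction strongly attenuated by acidosis (the HIF-1a pattern)
    B  - hypoxic induction partially attenuated by acidosis
    C  - hypoxic induction strengthened by acidosis (synergy)
    D  - hypoxia-driven downregulation, pH-independent

plus a null remainder.  Batch offsets are per-protein random intercepts;
missingness is left-censored: the probability that an entry is missing is a
logistic function of the underlying true abundance, rising as abundance
falls below a low quantile of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class EffectClass:
    """One planted response class (log2 units)."""

    fraction: float
    hypoxia_fc_alkaline: float
    hypoxia_fc_acidic: float
    acidosis_effect: float = 0.0


DEFAULT_EFFECT_CLASSES: dict[str, EffectClass] = {
    "A": EffectClass(0.003, 2.0, 0.3, 0.0),
    "B": EffectClass(0.011, 2.0, 1.2, 0.0),
    "C": EffectClass(0.015, 1.5, 2.5, 0.5),
    "D": EffectClass(0.003, -1.5, -1.5, 0.0),
}


def make_design(n_batches: int = 3) -> pd.DataFrame:
    """Full 2 x 2 x n_batches design frame (sample, ph, o2, batch)."""
    if n_batches < 2:
        raise DesignError("need >= 2 batches")
    rows = []
    for batch in range(1, n_batches + 1):
        for ph in ("alkaline", "acidic"):
            for o2 in ("normoxia", "hypoxia"):
                rows.append(
                    {
                        "sample": f"{ph[:3]}_{o2[:3]}_b{batch}",
                        "ph": ph,
                        "o2": o2,
                        "batch": batch,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ProteomicsSimSpec:
    n_proteins: int = 2000
    design: pd.DataFrame = field(default_factory=make_design)
    effect_classes: dict[str, EffectClass] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_CLASSES)
    )
    baseline_mean: float = 25.0  # log2 LFQ scale
    baseline_sd: float = 3.0
    batch_sd: float = 0.3
    residual_sd: float = 0.3
    censor_quantile: float = 0.05  # abundance quantile where missingness rises
    censor_max_prob: float = 0.5
    censor_scale: float = 1.0  # logistic width, log2 units
    reference_protein_index: int = 0  # row designated as the HIF-1a analogue
    seed: int = 0

    def __post_init__(self):
        for col in ("sample", "ph", "o2", "batch"):
            if col not in self.design.columns:
                raise DesignError(f"design lacks column {col!r}")
        for col in ("ph", "o2"):
            if self.design[col].nunique() < 2:
                raise DesignError(f"factor {col!r} needs 2 levels")
        if self.design["batch"].nunique() < 2:
            raise DesignError("need >= 2 batches")
        total = sum(c.fraction for c in self.effect_classes.values())
        if total > 1.0 + 1e-9:
            raise DesignError("effect-class fractions must sum to <= 1")
        if self.batch_sd < 0 or self.residual_sd < 0:
            raise DesignError("sds must be >= 0")


def make_abundance_matrix(
    spec: ProteomicsSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate (observed matrix with NaN for missing, design, truth labels).

    The observed matrix is proteins x samples; truth labels are the planted
    class per protein ("null" for the unaffected remainder).  The designated
    reference row is forced into class "A" so it behaves like the HIF-1a
    analogue (hypoxia-induced, acid-attenuated).
    """
    rng = np.random.default_rng(spec.seed)
    design = spec.design.reset_index(drop=True)
    n, m = spec.n_proteins, len(design)

    labels = np.array(["null"] * n, dtype=object)
    start = 0
    order = rng.permutation(n)
    for name, cls in spec.effect_classes.items():
        k = int(round(cls.fraction * n))
        labels[order[start : start + k]] = name
        start += k
    if not 0 <= spec.reference_protein_index < n:
        raise DesignError("reference_protein_index out of range")
    labels[spec.reference_protein_index] = "A"

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    batches = design["batch"].to_numpy()
    batch_levels = np.unique(batches)
    batch_off = rng.normal(0.0, spec.batch_sd, size=(n, len(batch_levels)))
    batch_idx = np.searchsorted(batch_levels, batches)

    acid = (design["ph"].to_numpy() == "acidic").astype(float)
    hyp = (design["o2"].to_numpy() == "hypoxia").astype(float)

    effects = np.zeros((n, m))
    for name, cls in spec.effect_classes.items():
        sel = labels == name
        if not np.any(sel):
            continue
        per_sample = (
            cls.acidosis_effect * acid
            + cls.hypoxia_fc_alkaline * hyp * (1.0 - acid)
            + cls.hypoxia_fc_acidic * hyp * acid
        )
        effects[sel] = per_sample

    truth = baseline[:, None] + effects + batch_off[:, batch_idx]
    values = truth + rng.normal(0.0, spec.residual_sd, size=(n, m))

    if spec.censor_max_prob > 0:
        pivot = np.quantile(truth, spec.censor_quantile)
        p_miss = spec.censor_max_prob / (
            1.0 + np.exp((truth - pivot) / spec.censor_scale)
        )
        missing = rng.random(size=(n, m)) < p_miss
        values = np.where(missing, np.nan, values)

    proteins = [f"P{i:05d}" for i in range(n)]
    matrix = pd.DataFrame(values, index=proteins, columns=design["sample"])
    return matrix, design, pd.Series(labels, index=proteins, name="class")
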