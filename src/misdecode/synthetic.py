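"""Seeded generator of intensity matrices with class-dependent error rates.

The generative model is deliberately the coarsest one consistent with the
summary statistics the analysis measures: every noncognate combination is
assigned its rule class (rule-1 classes are refined to the four
(column, group) cells, whose published frequencies differ), misdecoding
occurrence is Bernoulli with a class-dependent probability, and a positive
cell receives an ordinal intensity drawn from a categorical distribution
over 1..5 (uniform by default; the published per-level histograms are
graphical only, so the distribution is configurable and nothing downstream
depends on it).

Occurrence probability depends only on the class, not on codon identity.
Per-cell overrides allow finer emulation of all 16 (column, group) cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from . import genetic_code as gc
from .matrix import IntensityMatrix
from .rules import (
    OTHER,
    RULE2_FIRST_GU,
    RULE2_SECOND_GU,
    classify_all,
)
from .wobble import Isoacceptor, default_repertoire

#: default per-class occurrence probabilities, anchored to the published
#: cell frequencies (rule-1 cells) and rule-2 / other coverage rates
DEFAULT_CLASS_PROBS: dict[str, float] = {
    "RULE1:NUN/U": 0.875,
    "RULE1:NCN/C": 0.917,
    "RULE1:NUN/C": 0.750,
    "RULE1:NCN/U": 0.538,
    RULE2_SECOND_GU: 0.786,
    RULE2_FIRST_GU: 0.538,
    OTHER: 0.179,
}


@dataclass(frozen=True)
class GeneratorParams:
    """Occurrence probabilities per class, intensity distribution and seed."""

    class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    intensity_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        for key, p in self.class_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {key} must be in [0, 1], got {p}")
        if len(self.intensity_probs) != 5 or any(p < 0 for p in self.intensity_probs):
            raise ValueError("intensity_probs must be five non-negative weights")
        if abs(sum(self.intensity_probs) - 1.0) > 1e-9:
            raise ValueError("intensity_probs must sum to 1")

    def with_seed(self, seed: int) -> "GeneratorParams":
        return replace(self, seed=seed)


def generation_class(
    pair: tuple[str, str], repertoire: tuple[Isoacceptor, ...] | None = None
) -> str:
    """Class key used by the generator: rule-1 cells, rule-2 labels, OTHER."""
    codon, aa = pair
    from .rules import classify

    label = classify(codon, aa, repertoire).label
    if label.startswith("RULE1"):
        return f"RULE1:{gc.column_of(codon)}/{gc.AA_GROUP[aa]}"
    if label.startswith("RULE2"):
        return label
    return OTHER


@lru_cache(maxsize=4)
def _class_map(
    repertoire: tuple[Isoacceptor, ...] | None,
) -> dict[tuple[str, str], str]:
    repertoire = repertoire or default_repertoire()
    out = {}
    for pair, cls in classify_all(repertoire).items():
        codon, aa = pair
        if cls.label.startswith("RULE1"):
            out[pair] = f"RULE1:{gc.column_of(codon)}/{gc.AA_GROUP[aa]}"
        elif cls.label.startswith("RULE2"):
            out[pair] = cls.label
        else:
            out[pair] = OTHER
    return out


def generate_matrix(
    params: GeneratorParams,
    repertoire: tuple[Isoacceptor, ...] | None = None,
) -> IntensityMatrix:
    """Draw one intensity matrix; reproducible for a fixed seed.

    Randomness comes from a single ``numpy.random.default_rng(params.seed)``
    PCG64 generator; combinations are visited in the canonical universe
    order, so identical params give byte-identical TSV output.
    """
    rng = np.random.default_rng(params.seed)
    class_map = _class_map(repertoire)
    intensities: dict[tuple[str, str], int] = {}
    levels = np.arange(1, 6)
    for pair in gc.combination_universe():
        p = params.class_probs[class_map[pair]]
        if rng.random() < p:
            intensities[pair] = int(rng.choice(levels, p=params.intensity_probs))
    return IntensityMatrix.from_events(intensities)


def recover_params(
    matrices: list[IntensityMatrix],
    repertoire: tuple[Isoacceptor, ...] | None = None,
) -> dict[str, dict[str, float]]:
    """Empirical (maximum-likelihood) per-class occurrence estimates.

    Pools all matrices; for each class reports the proportion of positive
    draws, the binomial standard error sqrt(p_hat (1 - p_hat) / n), and n.
    """
    if not matrices:
        raise ValueError("at least one matrix is required")
    class_map = _class_map(repertoire)
    hits: dict[str, int] = {}
    totals: dict[str, int] = {}
    for m in matrices:
        for pair, key in class_map.items():
            totals[key] = totals.get(key, 0) + 1
            hits[key] = hits.get(key, 0) + int(m.occurred(*pair))
    out = {}
    for key, n in totals.items():
        p_hat = hits[key] / n
        out[key] = {
            "estimate": p_hat,
            "se": float(np.sqrt(p_hat * (1.0 - p_hat) / n)),
            "n": n,
        }
    return out
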