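"""The amino-acid diversity index and its relation to misdecoding frequency.

The diversity index of a set of amino acids is the product of the within-set
ranges of three physicochemical properties:

    index = (hydropathy range) x (residue volume range, A^3) x (pI range)

It quantifies the functional/structural spread of the set: a codon column
assigned to a low-diversity amino-acid set pays a small penalty per
misdecoding event.  For a pair of amino acids each range is the absolute
property difference.  Values are reported at three significant figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from itertools import combinations

from . import genetic_code as gc
from ._util import sigfig
from .genetic_code import AminoAcidRecord
from .matrix import IntensityMatrix, group_pair_frequency

#: cognate->misincorporated pairs highlighted in the rule-2 analysis
RULE2_PAIRS = (
    ("Y", "C"),  # Tyr misincorporated at Cys UGY codons (second-position G-U)
    ("H", "R"),  # His at Arg CGY
    ("Q", "R"),  # Gln at Arg CGR
    ("N", "S"),  # Asn at Ser AGY
    ("H", "Y"),  # His at Tyr UAY (first-position G-U)
    ("S", "G"),  # Ser at Gly GGY
)


@dataclass(frozen=True)
class DiversityIndex:
    hydropathy_range: float
    volume_range: float
    pI_range: float

    @property
    def index(self) -> float:
        return self.hydropathy_range * self.volume_range * self.pI_range

    @property
    def rounded(self) -> float:
        """Index at the printed precision (3 significant figures)."""
        return sigfig(self.index, 3)


def _records(
    amino_acids: Iterable[str | AminoAcidRecord],
    properties: dict[str, AminoAcidRecord] | None,
) -> list[AminoAcidRecord]:
    props = properties or gc.load_properties(gc.properties_path())
    return [aa if isinstance(aa, AminoAcidRecord) else props[aa] for aa in amino_acids]


def diversity_index(
    amino_acids: Iterable[str | AminoAcidRecord],
    properties: dict[str, AminoAcidRecord] | None = None,
) -> DiversityIndex:
    """Diversity index of a set of >= 2 amino acids (records or one-letter codes)."""
    recs = _records(amino_acids, properties)
    if len(recs) < 2:
        raise ValueError("diversity index requires at least two amino acids")
    hyd = [r.hydropathy for r in recs]
    vol = [r.volume for r in recs]
    pi = [r.pI for r in recs]
    return DiversityIndex(
        hydropathy_range=max(hyd) - min(hyd),
        volume_range=max(vol) - min(vol),
        pI_range=max(pi) - min(pi),
    )


def group_indexes(
    properties: dict[str, AminoAcidRecord] | None = None,
) -> dict[str, float]:
    """Diversity indexes of the four second-base groups plus group Y (U ∪ C)."""
    out = {
        g: diversity_index(gc.AA_GROUPS[g], properties).rounded for g in "UCAG"
    }
    out["Y"] = diversity_index(gc.AA_GROUPS["U"] + gc.AA_GROUPS["C"], properties).rounded
    return out


def pair_diversity_table(
    properties: dict[str, AminoAcidRecord] | None = None,
) -> dict[str, float]:
    """Indexes of the six rule-2 pairs and the mean over all 190 unordered pairs."""
    out = {
        f"{a}/{b}": diversity_index((a, b), properties).rounded for a, b in RULE2_PAIRS
    }
    all_pairs = [
        diversity_index(pair, properties).index
        for pair in combinations(gc.AMINO_ACIDS, 2)
    ]
    out["mean"] = sigfig(sum(all_pairs) / len(all_pairs), 3)
    return out


def frequency_vs_diversity(
    matrix: IntensityMatrix,
    properties: dict[str, AminoAcidRecord] | None = None,
) -> dict:
    """The four same-letter (column, group) points relating error rate to spread.

    For each column NXN the misdecoding frequency of the NXN/X cell is put
    against the diversity index of group X.  Returns the points, a rank
    check (every U/C frequency above every A/G one while the U/C indexes are
    smaller), and the Pearson correlation between frequency and log10 index
    (descriptive only: with four points no significance is attached).
    """
    indexes = group_indexes(properties)
    points = []
    for column in gc.COLUMNS:
        group = column[1]
        rec = group_pair_frequency(matrix, column, group)
        points.append(
            {
                "column": column,
                "group": group,
                "percent": rec.percent,
                "diversity_index": indexes[group],
            }
        )
    low = [p for p in points if p["group"] in "UC"]
    high = [p for p in points if p["group"] in "AG"]
    rank_consistent = all(
        lo["percent"] > hi["percent"] and lo["diversity_index"] < hi["diversity_index"]
        for lo in low
        for hi in high
    )
    freqs = np.array([p["percent"] for p in points])
    logidx = np.log10([p["diversity_index"] for p in points])
    r = float(np.corrcoef(freqs, logidx)[0, 1])
    return {"points": points, "rank_consistent": rank_consistent, "pearson_r_log10": r}
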