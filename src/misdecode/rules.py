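"""The two empirical misdecoding rules and their coverage statistics.

Rule 1 (second codon base U or C): misdecoding is frequent under mismatches
at the first and/or third base, where any mismatch kind is tolerated, and
horizontal/diagonal errors between the NUN and NCN columns are also common.
Operationally, a combination is rule 1 iff its codon column is NUN or NCN
AND its amino-acid group is U or C ("vertical" when column letter equals
group letter, else "horizontal").  That purely set-theoretic definition
yields the 256-combination rule-1 universe.

Rule 2 (second codon base A or G): misdecoding is promoted by a single
G-U/U-G pair, either at the second position (codon base 2 = G read against
an anticodon U, positions 1 and 3 matched) or at the first position (codon
base 1 G or U wobbled against anticodon base 36, positions 2 and 3 matched).
Combinations where positions 1 AND 2 both form G-U/U-G pairs showed no
misdecoding and are excluded from rule 2 (kept in OTHER, reported
separately as DOUBLE_GU).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from . import genetic_code as gc
from .matrix import FrequencyRecord, IntensityMatrix
from .wobble import Isoacceptor, default_repertoire, position_verdicts

RULE1_VERTICAL = "RULE1_VERTICAL"
RULE1_HORIZONTAL = "RULE1_HORIZONTAL"
RULE2_SECOND_GU = "RULE2_SECOND_GU"
RULE2_FIRST_GU = "RULE2_FIRST_GU"
OTHER = "OTHER"
ALL_LABELS = (RULE1_VERTICAL, RULE1_HORIZONTAL, RULE2_SECOND_GU, RULE2_FIRST_GU, OTHER)

_GU = ({"G-U", "U-G"}).__contains__


@dataclass(frozen=True)
class CombinationClass:
    """Rule label of one combination plus the supporting pairing evidence.

    For rule-2 labels, ``evidence`` lists (isoacceptor name, position) pairs
    whose single-G-U geometry satisfied the rule.  ``double_gu`` marks OTHER
    combinations whose only G-U geometry has wobbled pairs at both positions
    1 and 2 (observed misdecoding frequency 0, hence not rule 2).
    """

    label: str
    evidence: tuple[tuple[str, int], ...] = field(default=())
    double_gu: bool = False


def classify(
    codon: str,
    amino_acid: str,
    repertoire: tuple[Isoacceptor, ...] | None = None,
) -> CombinationClass:
    """Assign a noncognate combination to RULE1/RULE2/OTHER.

    Pure function of (codon, amino acid, repertoire); the intensity matrix
    plays no part.
    """
    codon = gc.normalize_codon(codon)
    if gc.is_cognate(codon, amino_acid):
        raise ValueError(f"({codon}, {amino_acid}) is a cognate pair")
    repertoire = repertoire or default_repertoire()

    column_letter = codon[1]
    group = gc.AA_GROUP[amino_acid]
    if column_letter in "UC" and group in "UC":
        return CombinationClass(
            RULE1_VERTICAL if column_letter == group else RULE1_HORIZONTAL
        )

    second_evidence: list[tuple[str, int]] = []
    first_evidence: list[tuple[str, int]] = []
    double_gu = False
    for iso in repertoire:
        if iso.amino_acid != amino_acid:
            continue
        v1, v2, v3 = position_verdicts(codon, iso)
        gu1 = v1 is not None and _GU(v1)
        gu2 = v2 is not None and _GU(v2)
        if gu1 and gu2 and v3 is None:
            double_gu = True
        if codon[1] == "G" and gu2 and v1 is None and v3 is None:
            second_evidence.append((iso.name, 2))
        if codon[1] in "AG" and gu1 and v2 is None and v3 is None:
            first_evidence.append((iso.name, 1))
    if second_evidence:
        return CombinationClass(RULE2_SECOND_GU, tuple(second_evidence))
    if first_evidence:
        return CombinationClass(RULE2_FIRST_GU, tuple(first_evidence))
    return CombinationClass(OTHER, double_gu=double_gu)


@lru_cache(maxsize=4)
def classify_all(
    repertoire: tuple[Isoacceptor, ...] | None = None,
) -> dict[tuple[str, str], CombinationClass]:
    """Classification of all 1159 combinations (a partition by construction).

    Cached per repertoire (the result is treated as read-only).
    """
    repertoire = repertoire or default_repertoire()
    return {
        pair: classify(*pair, repertoire) for pair in gc.combination_universe()
    }


def universe_sizes(
    repertoire: tuple[Isoacceptor, ...] | None = None,
) -> dict[str, int]:
    """Combination counts per label, plus the rule-level totals.

    On the packaged repertoire: rule 1 = 256, rule 2 = 27 (14 second-G-U +
    13 first-G-U), other = 876, summing to 1159.
    """
    classes = classify_all(repertoire)
    sizes = {label: 0 for label in ALL_LABELS}
    sizes["DOUBLE_GU"] = 0
    for cls in classes.values():
        sizes[cls.label] += 1
        if cls.double_gu:
            sizes["DOUBLE_GU"] += 1
    sizes["RULE1"] = sizes[RULE1_VERTICAL] + sizes[RULE1_HORIZONTAL]
    sizes["RULE2"] = sizes[RULE2_SECOND_GU] + sizes[RULE2_FIRST_GU]
    return sizes


def coverage_stats(
    matrix: IntensityMatrix,
    repertoire: tuple[Isoacceptor, ...] | None = None,
) -> dict[str, FrequencyRecord]:
    """Share of misdecoding combinations within each rule universe.

    Keys: the five labels, the aggregates RULE1/RULE2, and DOUBLE_GU (the
    both-positions-G-U subset of OTHER, reported separately).
    """
    classes = classify_all(repertoire)
    buckets: dict[str, list[tuple[str, str]]] = {label: [] for label in ALL_LABELS}
    buckets["DOUBLE_GU"] = []
    for pair, cls in classes.items():
        buckets[cls.label].append(pair)
        if cls.double_gu:
            buckets["DOUBLE_GU"].append(pair)
    buckets["RULE1"] = buckets[RULE1_VERTICAL] + buckets[RULE1_HORIZONTAL]
    buckets["RULE2"] = buckets[RULE2_SECOND_GU] + buckets[RULE2_FIRST_GU]
    return {
        key: FrequencyRecord(sum(matrix.occurred(*p) for p in pairs), len(pairs))
        for key, pairs in buckets.items()
        if pairs
    }
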