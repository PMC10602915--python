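"""Group-averaged PAM30 substitution scores.

The 20 amino acids are grouped by codon second base (U/C/A/G) and the PAM30
log-odds scores are averaged within and between groups.  Averages use
off-diagonal pairs only: a within-group average runs over the C(n,2)
unordered distinct pairs, a between-group average over all n_a x n_b cross
pairs.  Identity (diagonal) scores never enter — that is the only convention
consistent with the published group averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement
from pathlib import Path

import pandas as pd
from Bio.Align import substitution_matrices

from . import genetic_code as gc
from ._util import round_half_up


class SubstitutionMatrixError(ValueError):
    """Raised for malformed or asymmetric substitution matrices."""


@dataclass(frozen=True)
class SubstitutionMatrixModel:
    """Symmetric 20x20 integer score table with second-base group labels."""

    scores: pd.DataFrame  # index/columns: the 20 one-letter amino acids

    def score(self, a: str, b: str) -> float:
        return float(self.scores.at[a, b])

    @property
    def groups(self) -> dict[str, str]:
        return dict(gc.AA_GROUP)


def _from_alignment_matrix(arr) -> SubstitutionMatrixModel:
    letters = list(arr.alphabet)
    df = pd.DataFrame(arr, index=letters, columns=letters)
    # drop ambiguity/stop columns (B, Z, X, *) present in distribution files
    keep = [aa for aa in df.index if aa in gc.AA_GROUP]
    if sorted(keep) != sorted(gc.AA_GROUP):
        raise SubstitutionMatrixError(
            "matrix must contain all 20 canonical amino acids"
        )
    df = df.loc[keep, keep].astype(float)
    if not (df.values == df.values.T).all():
        bad = [
            (a, b)
            for a in keep
            for b in keep
            if df.at[a, b] != df.at[b, a]
        ]
        raise SubstitutionMatrixError(f"asymmetric scores, e.g. {bad[:3]}")
    return SubstitutionMatrixModel(scores=df)


def load_matrix(path: str | Path | None = None) -> SubstitutionMatrixModel:
    """Load a substitution matrix in the standard text format.

    With no path, the PAM30 matrix distributed with biopython is used.
    """
    if path is None:
        return _from_alignment_matrix(substitution_matrices.load("PAM30"))
    return _from_alignment_matrix(substitution_matrices.read(str(path)))


def group_average(
    model: SubstitutionMatrixModel, group_a: str, group_b: str
) -> float:
    """Mean off-diagonal score within a group or between two groups, one decimal."""
    for g in (group_a, group_b):
        if g not in gc.AA_GROUPS:
            raise ValueError(f"unknown amino-acid group {g!r}")
    if group_a == group_b:
        pairs = list(combinations(gc.AA_GROUPS[group_a], 2))
    else:
        pairs = [(a, b) for a in gc.AA_GROUPS[group_a] for b in gc.AA_GROUPS[group_b]]
    return round_half_up(sum(model.score(a, b) for a, b in pairs) / len(pairs), 1)


def group_average_table(model: SubstitutionMatrixModel) -> pd.DataFrame:
    """All 4 within-group and 6 between-group averages."""
    rows = []
    for ga, gb in combinations_with_replacement("UCAG", 2):
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "kind": "within" if ga == gb else "between",
                "mean_score": group_average(model, ga, gb),
            }
        )
    return pd.DataFrame(rows)


def overall_average(model: SubstitutionMatrixModel) -> float:
    """Mean score over all 190 unordered off-diagonal pairs, one decimal."""
    pairs = list(combinations(gc.AMINO_ACIDS, 2))
    return round_half_up(sum(model.score(a, b) for a, b in pairs) / len(pairs), 1)
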