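"""The misincorporation intensity matrix and its descriptive statistics.

The central data object is a 61 (sense codon) x 20 (amino acid) table of
ordinal intensities 0-5, where 0 means "no product peak detected" and 1-5
grade the relative LC/MS peak intensity of the misincorporated peptide
against an internal control.  The 61 cognate cells are masked (``NA`` in the
TSV): a codon is never scored against its own amino acid, leaving 1159
scored combinations.

A combination "misdecodes" iff its intensity is >= 1; every frequency in
this package is the share of misdecoding combinations within some universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import genetic_code as gc
from ._util import percent, round_half_up

INTENSITY_LEVELS = (0, 1, 2, 3, 4, 5)


class MatrixValidationError(ValueError):
    """Raised when an intensity table violates the matrix contract."""


@dataclass(frozen=True)
class FrequencyRecord:
    """A misdecoding frequency: combinations with intensity >= 1 over a universe."""

    numerator: int
    denominator: int

    @property
    def frequency(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        """Frequency as a percentage at one-decimal (half-up) precision."""
        return percent(self.numerator, self.denominator)


class IntensityMatrix:
    """Validated 61x20 ordinal intensity table with cognate cells masked.

    Wraps a float DataFrame (NaN at the 61 cognate cells) indexed by sense
    codon in codon-table order, columns the 20 amino acids in group order
    U, C, A, G.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.reindex(index=list(gc.SENSE_CODONS), columns=list(gc.AMINO_ACIDS))
        self._validate(frame)
        self.frame = frame

    @staticmethod
    def _validate(frame: pd.DataFrame) -> None:
        if list(frame.index) != list(gc.SENSE_CODONS) or list(frame.columns) != list(
            gc.AMINO_ACIDS
        ):
            raise MatrixValidationError(
                "matrix must cover the 61 sense codons and 20 amino acids"
            )
        for codon in frame.index:
            for aa in frame.columns:
                value = frame.at[codon, aa]
                cognate = gc.CODON_TO_AA[codon] == aa
                if cognate:
                    if not pd.isna(value):
                        raise MatrixValidationError(
                            f"cognate cell ({codon}, {aa}) must be NA, got {value!r}"
                        )
                    continue
                if pd.isna(value):
                    raise MatrixValidationError(
                        f"noncognate cell ({codon}, {aa}) is missing"
                    )
                if float(value) != int(value) or not 0 <= int(value) <= 5:
                    raise MatrixValidationError(
                        f"cell ({codon}, {aa}) has intensity {value!r}; "
                        "expected an integer in 0..5"
                    )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_events(cls, intensities: dict[tuple[str, str], int]) -> "IntensityMatrix":
        """Build a matrix from a sparse {(codon, aa): intensity>=1} mapping."""
        frame = pd.DataFrame(
            0.0, index=list(gc.SENSE_CODONS), columns=list(gc.AMINO_ACIDS)
        )
        for codon in gc.SENSE_CODONS:
            frame.at[codon, gc.CODON_TO_AA[codon]] = np.nan
        for (codon, aa), value in intensities.items():
            frame.at[codon, aa] = float(value)
        return cls(frame)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        out = self.frame.copy()
        out.insert(0, "codon", out.index)
        text = out.to_csv(sep="\t", index=False, na_rep="NA", float_format="%.0f")
        body = (f"# {header_comment}\n" if header_comment else "") + text
        Path(path).write_text(body)

    # -- cell access -------------------------------------------------------

    def intensity(self, codon: str, amino_acid: str) -> int:
        value = self.frame.at[codon, amino_acid]
        if pd.isna(value):
            raise KeyError(f"({codon}, {amino_acid}) is a cognate (masked) cell")
        return int(value)

    def occurred(self, codon: str, amino_acid: str) -> bool:
        return self.intensity(codon, amino_acid) >= 1

    def events(self) -> list[tuple[str, str]]:
        """All (codon, amino acid) combinations with intensity >= 1."""
        return [pair for pair in gc.combination_universe() if self.occurred(*pair)]

    def total_events(self) -> int:
        return len(self.events())

    def __eq__(self, other) -> bool:
        return isinstance(other, IntensityMatrix) and self.frame.equals(other.frame)


def load_matrix(path: str | Path) -> IntensityMatrix:
    """Read and validate an intensity matrix TSV.

    Format: optional ``#`` comment lines, then a header ``codon`` plus the 20
    one-letter amino-acid columns; 61 data rows; cells integer 0-5 or ``NA``
    at the cognate position.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"codon": str})
    if "codon" not in df.columns:
        raise MatrixValidationError("matrix TSV must have a leading 'codon' column")
    df = df.set_index("codon")
    if sorted(df.index) != sorted(gc.SENSE_CODONS):
        raise MatrixValidationError(
            f"matrix must have exactly the 61 sense codons as rows, got {len(df)}"
        )
    if sorted(df.columns) != sorted(gc.AMINO_ACIDS):
        raise MatrixValidationError(
            "matrix must have exactly the 20 amino-acid columns"
        )
    return IntensityMatrix(df.astype(float))


# -- descriptive statistics ------------------------------------------------


def misincorporation_count(matrix: IntensityMatrix, codon: str) -> int:
    """Number of distinct amino acids misincorporated (intensity >= 1) at a codon."""
    codon = gc.normalize_codon(codon)
    if codon not in matrix.frame.index:
        raise KeyError(f"unknown sense codon {codon!r}")
    row = matrix.frame.loc[codon]
    return int((row >= 1).sum())


def column_average_counts(matrix: IntensityMatrix) -> dict[str, float]:
    """Mean misincorporating amino acids per codon in each column, one decimal."""
    totals: dict[str, list[int]] = {col: [] for col in gc.COLUMNS}
    for codon in gc.SENSE_CODONS:
        totals[gc.column_of(codon)].append(misincorporation_count(matrix, codon))
    return {
        col: round_half_up(sum(counts) / len(counts), 1)
        for col, counts in totals.items()
    }


def cell_universe(column: str, group: str) -> list[tuple[str, str]]:
    """Noncognate combinations of one (codon column, amino-acid group) cell."""
    return [
        (codon, aa)
        for codon, aa in gc.combination_universe()
        if gc.column_of(codon) == column and gc.AA_GROUP[aa] == group
    ]


def group_pair_frequency(
    matrix: IntensityMatrix, column: str, group: str
) -> FrequencyRecord:
    """Misdecoding frequency within one of the 16 (column, group) universes."""
    pairs = cell_universe(column, group)
    hits = sum(matrix.occurred(*p) for p in pairs)
    return FrequencyRecord(hits, len(pairs))


def all_group_pair_frequencies(matrix: IntensityMatrix) -> pd.DataFrame:
    """Fig-2B-style table: numerator/denominator/percent for all 16 cells."""
    rows = []
    for column in gc.COLUMNS:
        for group in "UCAG":
            rec = group_pair_frequency(matrix, column, group)
            rows.append(
                {
                    "column": column,
                    "group": group,
                    "numerator": rec.numerator,
                    "denominator": rec.denominator,
                    "percent": rec.percent,
                }
            )
    return pd.DataFrame(rows)


def intensity_histogram(
    matrix: IntensityMatrix, column: str, group: str
) -> dict[int, int]:
    """Counts of combinations at each intensity level 0..5 for one cell."""
    hist = {level: 0 for level in INTENSITY_LEVELS}
    for pair in cell_universe(column, group):
        hist[matrix.intensity(*pair)] += 1
    return hist


def all_intensity_histograms(matrix: IntensityMatrix) -> pd.DataFrame:
    rows = []
    for column in gc.COLUMNS:
        for group in "UCAG":
            hist = intensity_histogram(matrix, column, group)
            rows.append({"column": column, "group": group, **{f"i{k}": v for k, v in hist.items()}})
    return pd.DataFrame(rows)
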