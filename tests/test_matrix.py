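"""Intensity-matrix I/O, validation and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest

from misdecode import genetic_code as gc
from misdecode.matrix import (
    IntensityMatrix,
    MatrixValidationError,
    all_group_pair_frequencies,
    all_intensity_histograms,
    cell_universe,
    column_average_counts,
    group_pair_frequency,
    intensity_histogram,
    load_matrix,
    misincorporation_count,
)


@pytest.fixture()
def zero_matrix():
    return IntensityMatrix.from_events({})


def test_reference_matrix_shape(reference_matrix):
    frame = reference_matrix.frame
    assert frame.shape == (61, 20)
    assert int(frame.notna().sum().sum()) == 1159


def test_zero_matrix_loads_and_counts(zero_matrix):
    assert zero_matrix.total_events() == 0
    assert misincorporation_count(zero_matrix, "AUG") == 0
    assert column_average_counts(zero_matrix) == {c: 0.0 for c in gc.COLUMNS}


def test_roundtrip_tsv(tmp_path, reference_matrix):
    path = tmp_path / "matrix.tsv"
    reference_matrix.to_tsv(path, header_comment="roundtrip")
    assert load_matrix(path) == reference_matrix


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda f: f.__setitem__("extra", 0), "20 amino-acid"),
        (lambda f: f.update({"F": f["F"].replace(0.0, 6.0)}), "0..5"),
    ],
)
def test_load_rejects_bad_tables(tmp_path, reference_matrix, mutate, message):
    frame = reference_matrix.frame.copy()
    mutate(frame)
    out = frame.copy()
    out.insert(0, "codon", out.index)
    path = tmp_path / "bad.tsv"
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
    with pytest.raises(MatrixValidationError, match=message):
        load_matrix(path)


def test_load_rejects_intensity_in_cognate_cell(tmp_path, reference_matrix):
    frame = reference_matrix.frame.copy()
    frame.at["AUG", "M"] = 3.0
    out = frame.copy()
    out.insert(0, "codon", out.index)
    path = tmp_path / "bad.tsv"
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
    with pytest.raises(MatrixValidationError, match=r"\(AUG, M\)"):
        load_matrix(path)


def test_column_average_counts_on_reference(reference_matrix):
    assert column_average_counts(reference_matrix) == {
        "NUN": 9.4,
        "NCN": 7.6,
        "NAN": 4.2,
        "NGN": 2.3,
    }


@pytest.mark.parametrize(
    "column, group, numerator, denominator, pct",
    [
        ("NUN", "U", 56, 64, 87.5),
        ("NCN", "C", 44, 48, 91.7),
        ("NUN", "C", 48, 64, 75.0),
        ("NCN", "U", 43, 80, 53.8),
        ("NAN", "A", 19, 84, 22.6),
        ("NGN", "G", 8, 47, 17.0),
    ],
)
def test_group_pair_frequencies_on_reference(
    reference_matrix, column, group, numerator, denominator, pct
):
    rec = group_pair_frequency(reference_matrix, column, group)
    assert (rec.numerator, rec.denominator) == (numerator, denominator)
    assert rec.percent == pct


def test_cell_universes_partition_the_1159():
    sizes = [
        len(cell_universe(col, grp)) for col in gc.COLUMNS for grp in "UCAG"
    ]
    assert sum(sizes) == 1159
    seen = set()
    for col in gc.COLUMNS:
        for grp in "UCAG":
            cell = set(cell_universe(col, grp))
            assert not cell & seen
            seen |= cell


def test_histograms_consistent_with_frequencies(reference_matrix):
    total = 0
    for col in gc.COLUMNS:
        for grp in "UCAG":
            hist = intensity_histogram(reference_matrix, col, grp)
            assert sum(hist.values()) == len(cell_universe(col, grp))
            rec = group_pair_frequency(reference_matrix, col, grp)
            assert sum(v for k, v in hist.items() if k >= 1) == rec.numerator
            total += sum(hist.values())
    assert total == 1159


def test_histogram_of_zero_matrix(zero_matrix):
    hist = intensity_histogram(zero_matrix, "NUN", "U")
    assert hist[0] == 64 and all(hist[k] == 0 for k in range(1, 6))


def test_frequencies_invariant_under_label_preserving_permutation(reference_matrix):
    rng = np.random.default_rng(0)
    frame = reference_matrix.frame
    shuffled = frame.loc[
        rng.permutation(frame.index), rng.permutation(frame.columns)
    ]
    permuted = IntensityMatrix(pd.DataFrame(shuffled))
    assert all_group_pair_frequencies(permuted).equals(
        all_group_pair_frequencies(reference_matrix)
    )
    assert all_intensity_histograms(permuted).equals(
        all_intensity_histograms(reference_matrix)
    )
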