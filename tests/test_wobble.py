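"""Codon-anticodon pairing, mismatch enumeration and class statistics."""

import itertools

import pytest

from misdecode import genetic_code as gc
from misdecode.wobble import (
    DEFAULT_WOBBLE_SETS,
    EXPECTED_CLASSES,
    RepertoireError,
    WATSON_CRICK,
    class_frequency_table,
    class_universes,
    decoded_codons,
    load_repertoire,
    mismatch_count,
    mismatch_profile,
    position_match,
    three_mismatch_split,
)


def by_name(repertoire, name):
    return next(iso for iso in repertoire if iso.name == name)


@pytest.mark.parametrize(
    "codon_base, token, position, expected",
    [
        ("G", "U", 2, "G-U"),  # G-U at an inner position is a mismatch, not wobble
        ("A", "cmo5U", 3, None),  # cmo5U reads all four third bases
        ("A", "U", 1, None),  # plain Watson-Crick
        ("U", "G", 3, None),  # U read by G34 wobble
        ("A", "G", 3, "A-G"),
        ("C", "C", 1, "C-C"),
    ],
)
def test_position_match(codon_base, token, position, expected):
    assert position_match(codon_base, token, position) == expected


def test_position_match_rejects_unknown_token():
    with pytest.raises(RepertoireError):
        position_match("A", "xm5U", 3)


def brute_force_decoded(iso):
    """Independent oracle: test all 64 codons base by base."""
    decoded = set()
    for codon in itertools.product(gc.RNA_BASES, repeat=3):
        codon = "".join(codon)
        if codon in gc.STOP_CODONS:
            continue
        ok1 = WATSON_CRICK[codon[0]] == iso.base36
        ok2 = WATSON_CRICK[codon[1]] == iso.base35
        ok3 = codon[2] in DEFAULT_WOBBLE_SETS[iso.base34]
        if ok1 and ok2 and ok3:
            decoded.add(codon)
    return decoded


def test_decoded_codons_against_brute_force(repertoire):
    for iso in repertoire:
        assert decoded_codons(iso) == brute_force_decoded(iso), iso.name


def test_val1_and_val2_decoding(repertoire):
    assert decoded_codons(by_name(repertoire, "Val1")) == {"GUU", "GUC", "GUA", "GUG"}
    assert decoded_codons(by_name(repertoire, "Val2")) == {"GUU", "GUC"}


def test_repertoire_completeness(repertoire):
    covered = set().union(*(decoded_codons(iso) for iso in repertoire))
    assert covered == set(gc.SENSE_CODONS)


def test_incomplete_repertoire_is_rejected(tmp_path):
    import pandas as pd

    df = pd.read_csv(
        __import__("misdecode.wobble", fromlist=["repertoire_path"]).repertoire_path(),
        sep="\t",
    )
    df = df[df["trna_name"] != "Ile2"]  # AUA becomes undecodable
    path = tmp_path / "incomplete.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(RepertoireError, match="AUA"):
        load_repertoire(path)


def test_mismatch_counts_cognate_zero_noncognate_positive(repertoire):
    """min mismatches = 0 for every cognate pair, >= 1 for all 1159 noncognates."""
    for codon in gc.SENSE_CODONS:
        cognate = gc.CODON_TO_AA[codon]
        counts = [
            mismatch_count(codon, iso)
            for iso in repertoire
            if iso.amino_acid == cognate
        ]
        assert min(counts) == 0, codon
    for codon, aa in gc.combination_universe():
        counts = [
            mismatch_count(codon, iso) for iso in repertoire if iso.amino_acid == aa
        ]
        assert min(counts) >= 1, (codon, aa)


def test_uua_val_worked_example(repertoire):
    profile = mismatch_profile("UUA", "V", repertoire)
    assert profile.label == "1/2"
    assert profile.position_marks == ("+", "-", "±")
    assert dict(profile.counts_by_isoacceptor) == {"Val1": 1, "Val2": 2}
    # first-position mismatch kind is U against the anticodon third base C
    assert profile.mismatch_kinds[0] == ("U-C",)


def test_gcg_ser_worked_example(repertoire):
    profile = mismatch_profile("GCG", "S", repertoire)
    assert profile.label == "1/2/3"
    counts = dict(profile.counts_by_isoacceptor)
    # mcmo5UGA and CGA reach 1 mismatch, GGA 2, and GCU alone needs 3
    assert counts["Ser1"] == 1 and counts["Ser2"] == 1
    assert counts["Ser3"] == 2
    assert counts["Ser5"] == 3


def test_mismatch_profile_rejects_cognate(repertoire):
    with pytest.raises(ValueError, match="cognate"):
        mismatch_profile("AUG", "M", repertoire)


def test_class_universes_partition(repertoire):
    universes = class_universes(repertoire)
    assert set(universes) <= set(EXPECTED_CLASSES)
    sizes = {label: len(pairs) for label, pairs in universes.items()}
    assert sum(sizes.values()) == 1159
    all_pairs = [p for pairs in universes.values() for p in pairs]
    assert len(set(all_pairs)) == 1159


def test_class_frequencies_on_reference(reference_matrix, repertoire):
    """Frequency decreases with mismatch count; multi-isoacceptor classes sit higher."""
    table = class_frequency_table(reference_matrix, repertoire)
    pct = {label: rec.percent for label, rec in table.items()}
    assert pct["1"] > pct["2"] > pct["3"]
    assert pct["1/2"] > pct["2/3"]
    assert pct["1/2"] > pct["2"] and pct["2/3"] > pct["3"]
    assert sum(rec.numerator for rec in table.values()) == reference_matrix.total_events()


def test_class_frequencies_near_published(reference_matrix, repertoire):
    """Within 1 point of the published values; the repertoire transcription
    is only anchored by the printed examples, so exact equality is not
    attainable (see methods note)."""
    published = {"1": 49.4, "2": 18.7, "3": 14.7, "1/2": 65.6, "2/3": 29.5, "1/2/3": 40.5}
    table = class_frequency_table(reference_matrix, repertoire)
    for label, expected in published.items():
        assert abs(table[label].percent - expected) <= 1.0, label


def test_three_mismatch_split_on_reference(reference_matrix, repertoire):
    split = three_mismatch_split(reference_matrix, repertoire)
    assert split == {"total": 31, "NUN_NCN": 21, "NAN_NGN": 10}
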