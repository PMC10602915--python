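"""Codon-anticodon pairing over the E. coli isoacceptor repertoire.

Pairing geometry: the anticodon is stored 5'->3' as bases 34/35/36, and
codon position i pairs anticodon position 37-i.  Codon positions 1 and 2
must form strict Watson-Crick pairs; at position 3 the codon base is matched
iff it belongs to the wobble set of the (possibly modified) anticodon base
34.  Modified nucleosides (cmo5U, mcmo5U, mnm5U, mnm5s2U, cmnm5Um, Q, I,
k2C, ac4C, Gm) expand or restrict that set; e.g. cmo5U reads all four third
bases, which is why tRNA-Val1 (cmo5UAC) alone decodes GUU/GUC/GUA/GUG.

For a noncognate (codon, amino acid) combination, each isoacceptor of the
amino acid yields a mismatch count in 1..3; the set of attainable counts,
written "1/2" etc., is the combination's mismatch class.  Over the packaged
repertoire only six classes occur: 1, 2, 3, 1/2, 2/3, 1/2/3.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

from . import genetic_code as gc
from .matrix import FrequencyRecord, IntensityMatrix

#: Watson-Crick partner (codon base -> pairing anticodon base)
WATSON_CRICK = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: default wobble sets: codon third bases read as matched by each base-34 token
DEFAULT_WOBBLE_SETS: dict[str, frozenset[str]] = {
    "G": frozenset("UC"),
    "C": frozenset("G"),
    "A": frozenset("U"),
    "U": frozenset("AG"),
    "cmo5U": frozenset("UCAG"),
    "mcmo5U": frozenset("UCAG"),
    "mnm5U": frozenset("AG"),
    "mnm5s2U": frozenset("AG"),
    "cmnm5Um": frozenset("AG"),
    "Q": frozenset("UC"),
    "I": frozenset("UCA"),
    "k2C": frozenset("A"),
    "ac4C": frozenset("G"),
    "Gm": frozenset("UC"),
}

#: mismatch classes observed over the full combination universe
EXPECTED_CLASSES = ("1", "2", "3", "1/2", "2/3", "1/2/3")


class RepertoireError(ValueError):
    """Raised for malformed or incomplete isoacceptor repertoires."""


class UnexpectedClassError(RuntimeError):
    """A mismatch class outside the six expected labels was produced.

    Raised (never silently binned) so that a modified repertoire that
    creates, say, a "1/3" combination is surfaced to the analyst.
    """


@dataclass(frozen=True)
class Isoacceptor:
    """One tRNA species: anticodon 34/35/36 with its wobble pairing set."""

    amino_acid: str
    name: str
    base34: str
    base35: str
    base36: str
    wobble_set: frozenset[str]

    def __post_init__(self):
        if not self.wobble_set:
            raise RepertoireError(f"{self.name}: empty wobble set")
        for b in (self.base35, self.base36, *self.wobble_set):
            if b not in gc.RNA_BASES:
                raise RepertoireError(f"{self.name}: invalid base {b!r}")

    @property
    def anticodon(self) -> str:
        return self.base34 + self.base35 + self.base36

    def base_at(self, anticodon_position: int) -> str:
        return {34: self.base34, 35: self.base35, 36: self.base36}[anticodon_position]


@dataclass(frozen=True)
class MismatchProfile:
    """Mismatch structure of one noncognate (codon, amino acid) combination.

    ``counts_by_isoacceptor`` maps tRNA name to its mismatch count;
    ``label`` joins the sorted distinct counts with "/"; ``position_marks``
    gives, for codon positions 1-3, "+" (mismatched with every isoacceptor),
    "-" (matched with every isoacceptor) or "±" (depends on the isoacceptor).
    ``mismatch_kinds`` lists per position the distinct (codon base)-(anticodon
    base) mismatch pairs encountered, codon base first.
    """

    codon: str
    amino_acid: str
    counts_by_isoacceptor: tuple[tuple[str, int], ...]
    label: str
    position_marks: tuple[str, str, str]
    mismatch_kinds: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(sorted({c for _, c in self.counts_by_isoacceptor}))


def repertoire_path() -> Path:
    return Path(resources.files("misdecode.data") / "ecoli_isoacceptors.tsv")


def load_repertoire(path: str | Path | None = None) -> tuple[Isoacceptor, ...]:
    """Load an isoacceptor TSV (aa, trna_name, base34, base35, base36, wobble_set).

    Validates repertoire completeness: every sense codon must be decodable
    (zero mismatches) by at least one isoacceptor of its cognate amino acid.
    """
    df = pd.read_csv(path or repertoire_path(), sep="\t", dtype=str)
    required = {"aa", "trna_name", "base34", "base35", "base36", "wobble_set"}
    if missing := required - set(df.columns):
        raise RepertoireError(f"repertoire missing columns {sorted(missing)}")
    isos = tuple(
        Isoacceptor(
            amino_acid=row.aa,
            name=row.trna_name,
            base34=row.base34,
            base35=row.base35,
            base36=row.base36,
            wobble_set=frozenset(row.wobble_set.split(",")),
        )
        for row in df.itertuples()
    )
    missing_aas = set(gc.AA_GROUP) - {iso.amino_acid for iso in isos}
    if missing_aas:
        raise RepertoireError(f"no isoacceptor for amino acid(s) {sorted(missing_aas)}")
    for codon in gc.SENSE_CODONS:
        cognate = gc.CODON_TO_AA[codon]
        if not any(
            mismatch_count(codon, iso) == 0 for iso in isos if iso.amino_acid == cognate
        ):
            raise RepertoireError(
                f"repertoire incomplete: sense codon {codon} ({cognate}) undecodable"
            )
    return isos


@lru_cache(maxsize=1)
def default_repertoire() -> tuple[Isoacceptor, ...]:
    return load_repertoire()


def position_match(
    codon_base: str, anticodon_token: str, position: int
) -> str | None:
    """Pairing verdict at one codon position.

    Returns ``None`` when matched, otherwise the mismatch kind written
    codon-base first (e.g. ``"G-U"``).  Positions 1 and 2 require strict
    Watson-Crick pairing against anticodon bases 36 and 35; position 3 is
    matched iff the codon base lies in the wobble set of the base-34 token,
    since non-Watson-Crick pairs at the wobble position are read as matched.
    """
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1, 2 or 3, got {position}")
    if codon_base not in gc.RNA_BASES:
        raise RepertoireError(f"unknown codon base {codon_base!r}")
    if position in (1, 2):
        if anticodon_token not in gc.RNA_BASES:
            raise RepertoireError(
                f"unknown anticodon base {anticodon_token!r} at position {position}"
            )
        if WATSON_CRICK[codon_base] == anticodon_token:
            return None
        return f"{codon_base}-{anticodon_token}"
    if anticodon_token not in DEFAULT_WOBBLE_SETS:
        raise RepertoireError(f"unknown base-34 token {anticodon_token!r}")
    if codon_base in DEFAULT_WOBBLE_SETS[anticodon_token]:
        return None
    return f"{codon_base}-{anticodon_token}"


def position_verdicts(codon: str, iso: Isoacceptor) -> tuple[str | None, ...]:
    """Mismatch kind (or None) at codon positions 1..3 against one isoacceptor."""
    codon = gc.normalize_codon(codon)
    v1 = (
        None
        if WATSON_CRICK[codon[0]] == iso.base36
        else f"{codon[0]}-{iso.base36}"
    )
    v2 = (
        None
        if WATSON_CRICK[codon[1]] == iso.base35
        else f"{codon[1]}-{iso.base35}"
    )
    v3 = None if codon[2] in iso.wobble_set else f"{codon[2]}-{iso.base34}"
    return (v1, v2, v3)


def mismatch_count(codon: str, iso: Isoacceptor) -> int:
    return sum(v is not None for v in position_verdicts(codon, iso))


def decoded_codons(iso: Isoacceptor) -> frozenset[str]:
    """Sense codons read with zero mismatches by one isoacceptor."""
    return frozenset(c for c in gc.SENSE_CODONS if mismatch_count(c, iso) == 0)


def mismatch_profile(
    codon: str,
    amino_acid: str,
    repertoire: tuple[Isoacceptor, ...] | None = None,
) -> MismatchProfile:
    """Mismatch counts of a noncognate combination across all isoacceptors."""
    codon = gc.normalize_codon(codon)
    repertoire = repertoire or default_repertoire()
    if gc.is_cognate(codon, amino_acid):
        raise ValueError(f"({codon}, {amino_acid}) is a cognate pair")
    isos = [iso for iso in repertoire if iso.amino_acid == amino_acid]
    if not isos:
        raise RepertoireError(f"no isoacceptor for amino acid {amino_acid!r}")
    verdicts = {iso.name: position_verdicts(codon, iso) for iso in isos}
    counts = tuple((name, sum(v is not None for v in vs)) for name, vs in verdicts.items())
    label = "/".join(str(c) for c in sorted({c for _, c in counts}))
    marks = []
    kinds = []
    for pos in range(3):
        pos_verdicts = [vs[pos] for vs in verdicts.values()]
        mismatched = [v for v in pos_verdicts if v is not None]
        if len(mismatched) == len(pos_verdicts):
            marks.append("+")
        elif not mismatched:
            marks.append("-")
        else:
            marks.append("±")
        kinds.append(tuple(dict.fromkeys(mismatched)))
    return MismatchProfile(
        codon=codon,
        amino_acid=amino_acid,
        counts_by_isoacceptor=counts,
        label=label,
        position_marks=tuple(marks),
        mismatch_kinds=tuple(kinds),
    )


@lru_cache(maxsize=4)
def class_universes(
    repertoire: tuple[Isoacceptor, ...] | None = None,
) -> dict[str, list[tuple[str, str]]]:
    """Partition of the 1159 combinations by mismatch class.

    Raises :class:`UnexpectedClassError` if any combination falls outside
    the six expected labels.  Cached per repertoire; treat the result as
    read-only.
    """
    repertoire = repertoire or default_repertoire()
    universes: dict[str, list[tuple[str, str]]] = {}
    unexpected = []
    for codon, aa in gc.combination_universe():
        label = mismatch_profile(codon, aa, repertoire).label
        universes.setdefault(label, []).append((codon, aa))
        if label not in EXPECTED_CLASSES:
            unexpected.append((codon, aa, label))
    if unexpected:
        raise UnexpectedClassError(
            f"{len(unexpected)} combination(s) with unexpected mismatch class, "
            f"e.g. {unexpected[:5]}"
        )
    return {label: universes[label] for label in EXPECTED_CLASSES if label in universes}


def class_frequency_table(
    matrix: IntensityMatrix,
    repertoire: tuple[Isoacceptor, ...] | None = None,
) -> dict[str, FrequencyRecord]:
    """Misdecoding frequency within each mismatch class (Fig-4-style table)."""
    return {
        label: FrequencyRecord(
            sum(matrix.occurred(*p) for p in pairs), len(pairs)
        )
        for label, pairs in class_universes(repertoire).items()
    }


def three_mismatch_split(
    matrix: IntensityMatrix,
    repertoire: tuple[Isoacceptor, ...] | None = None,
) -> dict[str, int]:
    """Misdecoding events in class "3", split by codon column halves.

    Returns total events plus the counts falling in NUN/NCN versus NAN/NGN
    columns.
    """
    pairs = class_universes(repertoire)["3"]
    hits = [p for p in pairs if matrix.occurred(*p)]
    nun_ncn = sum(1 for codon, _ in hits if gc.column_of(codon) in ("NUN", "NCN"))
    return {
        "total": len(hits),
        "NUN_NCN": nun_ncn,
        "NAN_NGN": len(hits) - nun_ncn,
    }
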