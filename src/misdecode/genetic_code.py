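"""Standard genetic code, codon-table columns and amino-acid property constants.

The codon table is the standard (translation table 1) code over the RNA
alphabet.  Two classifications drive the whole analysis:

* every codon belongs to a **column** (NUN/NCN/NAN/NGN) determined by its
  second base;
* every amino acid belongs to a **second-base group** (U/C/A/G), the second
  base of its codons.  Ser is assigned to group C via its UCN codons even
  though AGY also encodes it.

Amino-acid property constants (Kyte-Doolittle hydropathy, Zamyatnin residue
volume, classical pI) ship as a packaged TSV and feed the diversity index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio.Data.CodonTable import unambiguous_rna_by_id

RNA_BASES = ("U", "C", "A", "G")

_TABLE = unambiguous_rna_by_id[1]

#: codon -> one-letter amino acid, standard code, RNA alphabet
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons in codon-table order (UUU, UUC, UUA, UUG, CUU, ... GGG)
SENSE_CODONS: tuple[str, ...] = tuple(
    b1 + b2 + b3
    for b1 in RNA_BASES
    for b2 in RNA_BASES
    for b3 in RNA_BASES
    if b1 + b2 + b3 not in STOP_CODONS
)

#: second-base group -> amino acids (one-letter), in codon-table order
AA_GROUPS: dict[str, tuple[str, ...]] = {
    "U": ("F", "L", "I", "M", "V"),
    "C": ("S", "P", "T", "A"),
    "A": ("Y", "H", "Q", "N", "K", "D", "E"),
    "G": ("C", "W", "R", "G"),
}
AA_GROUP: dict[str, str] = {aa: g for g, aas in AA_GROUPS.items() for aa in aas}

#: canonical amino-acid ordering used for matrix columns: groups U, C, A, G
AMINO_ACIDS: tuple[str, ...] = tuple(aa for g in "UCAG" for aa in AA_GROUPS[g])

#: sentinel returned by :func:`translate` for stop codons
STOP = "STOP"

COLUMNS = ("NUN", "NCN", "NAN", "NGN")


class InvalidCodonError(ValueError):
    """Raised for strings that are not RNA triplets."""


@dataclass(frozen=True)
class AminoAcidRecord:
    """One canonical amino acid with its second-base group and properties.

    hydropathy is the Kyte-Doolittle index (dimensionless), volume the
    residue volume in cubic angstroms, pI the isoelectric point in pH units.
    """

    one_letter: str
    group: str
    hydropathy: float
    volume: float
    pI: float


def normalize_codon(codon: str) -> str:
    """Validate a codon string, transliterating DNA (T) to RNA with a warning."""
    if not isinstance(codon, str) or len(codon) != 3:
        raise InvalidCodonError(f"codon must be a nucleotide triplet, got {codon!r}")
    codon = codon.upper()
    if "T" in codon:
        warnings.warn(
            f"DNA codon {codon!r} transliterated to RNA", UserWarning, stacklevel=3
        )
        codon = codon.replace("T", "U")
    for base in codon:
        if base not in RNA_BASES:
            raise InvalidCodonError(f"non-RNA character {base!r} in codon {codon!r}")
    return codon


def properties_path() -> Path:
    return Path(resources.files("misdecode.data") / "amino_acid_properties.tsv")


@lru_cache(maxsize=None)
def _default_properties() -> dict[str, AminoAcidRecord]:
    return load_properties(properties_path())


def load_properties(path: str | Path) -> dict[str, AminoAcidRecord]:
    """Load an amino-acid property TSV (columns aa, group, hydropathy, volume_A3, pI).

    The table must contain exactly the 20 canonical amino acids with the
    canonical group sizes U:5, C:4, A:7, G:4.
    """
    df = pd.read_csv(path, sep="\t", dtype={"aa": str, "group": str})
    required = {"aa", "group", "hydropathy", "volume_A3", "pI"}
    if missing := required - set(df.columns):
        raise ValueError(f"property table missing columns {sorted(missing)}")
    if sorted(df["aa"]) != sorted(AA_GROUP):
        raise ValueError("property table must contain exactly the 20 canonical amino acids")
    records = {}
    for row in df.itertuples():
        if AA_GROUP[row.aa] != row.group:
            raise ValueError(
                f"amino acid {row.aa} assigned to group {row.group}, "
                f"expected second-base group {AA_GROUP[row.aa]}"
            )
        records[row.aa] = AminoAcidRecord(
            one_letter=row.aa,
            group=row.group,
            hydropathy=float(row.hydropathy),
            volume=float(row.volume_A3),
            pI=float(row.pI),
        )
    return records


def translate(codon: str, properties: dict[str, AminoAcidRecord] | None = None):
    """Standard-code translation of an RNA codon.

    Returns the :class:`AminoAcidRecord` for sense codons and the module
    constant :data:`STOP` for UAA/UAG/UGA.
    """
    codon = normalize_codon(codon)
    if codon in STOP_CODONS:
        return STOP
    aa = CODON_TO_AA[codon]
    return (properties or _default_properties())[aa]


def column_of(codon: str) -> str:
    """Codon-table column (NUN/NCN/NAN/NGN), determined by the second base."""
    codon = normalize_codon(codon)
    return f"N{codon[1]}N"


def is_cognate(codon: str, amino_acid: str) -> bool:
    return CODON_TO_AA.get(normalize_codon(codon)) == amino_acid


@lru_cache(maxsize=1)
def combination_universe() -> tuple[tuple[str, str], ...]:
    """All 1159 noncognate (sense codon, amino acid) combinations.

    61 sense codons x 19 noncognate amino acids each; cognate pairs excluded.
    """
    return tuple(
        (codon, aa)
        for codon in SENSE_CODONS
        for aa in AMINO_ACIDS
        if CODON_TO_AA[codon] != aa
    )
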