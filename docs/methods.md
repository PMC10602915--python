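# Methods

## Scope and data model

The unit of analysis is the noncognate (sense codon, amino acid) combination;
there are 61 × 19 = 1159 of them. An intensity matrix assigns each
combination an ordinal score 0–5; "misdecoding occurred" is defined as
intensity ≥ 1, and every frequency in the package is the share of occurring
combinations within some universe (a column × group cell, a rule class, a
mismatch class). Intensities are treated as purely ordinal: no statistic
weights a 5 differently from a 1, because the underlying peak-intensity
binning thresholds are not specified.

Percentages are printed at one decimal with half-up rounding (9.375 → 9.4);
diversity indexes at three significant figures. Comparisons against expected
published values use a relative tolerance of about 1% for diversity values to
absorb rounding in the published constants, and exact equality at printed
precision for counts and percentages derived from integer tallies.

## Codon–anticodon pairing model

Anticodons are stored 5′→3′ as bases 34/35/36; codon position *i* pairs
anticodon position 37 − *i*. Codon positions 1 and 2 must pair strict
Watson–Crick. Position 3 is matched iff the codon base belongs to the wobble
set of the base-34 token:

| base 34 | reads | note |
|---|---|---|
| G | U, C | standard wobble |
| C | G | |
| A | U | (not present in the packaged repertoire) |
| U (unmodified) | A, G | |
| cmo⁵U, mcmo⁵U | U, C, A, G | 5-oxyacetyl expansion (e.g. tRNA-Val1 reads all GUN) |
| mnm⁵U, mnm⁵s²U, cmnm⁵Um | A, G | |
| Q (queuosine) | U, C | |
| I (inosine) | U, C, A | |
| k²C (lysidine) | A | restricts tRNA-Ile2 to AUA |
| ac⁴C | G | restricts elongator tRNA-Met to AUG |
| Gm | U, C | |

G-U at codon positions 1–2 is always a mismatch (wobble applies only at
position 3); rule 2 is *defined* by such G-U/U-G "mismatches" forming
despite not being Watson–Crick.

The packaged repertoire (`data/ecoli_isoacceptors.tsv`, 40 isoacceptors) is
curated from standard E. coli decoding tables. The exact isoacceptor table
used for the published analysis is available only in supplementary files
that are not machine-readable, so the packaged table is validated against
every anchor the text states: tRNA-Val1 (cmo⁵UAC) decodes GUU/GUC/GUA/GUG;
Ser has the four anticodons GGA, mcmo⁵UGA, CGA, GCU; (UUA, Val) is class
"1/2" with position marks +/−/±; (GCG, Ser) is "1/2/3" with the GCU
anticodon alone at 3 mismatches; the rule universes split 256 + 27 + 876
with the rule-2 subsets sized 14 and 13; repertoire completeness (every
sense codon decodable by a cognate isoacceptor); and only the six mismatch
classes 1, 2, 3, 1/2, 2/3, 1/2/3 occur. Any repertoire edit that produces a
class outside those six raises an error rather than silently binning.

A combination's mismatch class aggregates the **set of attainable counts**
across the amino acid's isoacceptors (not the minimum), since which
isoacceptor causes a given event is not identifiable.

## Rule definitions

Rule 1 membership is purely set-theoretic — codon column ∈ {NUN, NCN} and
amino-acid group ∈ {U, C} — giving the 256-combination universe; "vertical"
when column letter = group letter, "horizontal" otherwise. Rule 2 requires
single-G-U geometry against some isoacceptor: second-position G-U (codon
base 2 = G against anticodon 35 = U) with positions 1 and 3 matched, or
first-position G-U/U-G (codon base 1 G or U against anticodon 36) with
positions 2 and 3 matched, codon base 2 ∈ {A, G}. Combinations whose only
G-U geometry involves *both* positions 1 and 2 are excluded from rule 2
(they are never observed to misdecode) and are kept in OTHER, reported
separately as DOUBLE_GU (7 combinations in this repertoire). Rule-1 and
rule-2 eligibility are disjoint by codon second base; the code asserts this
rather than assuming it.

## The synthetic benchmark matrix

The originally measured per-cell matrix exists only as a figure and a
non-text supplement, so the packaged matrix is **synthetic**: a 0/1
occurrence vector over the 1159 combinations solved by integer programming
(HiGHS via `scipy.optimize.milp`) under equality constraints on every
published aggregate — total events 366; cell counts NUN/U 56, NUN/C 48,
NCN/U 43, NCN/C 44, NAN/A 19, NGN/G 8; column totals 150/122/59/35 (means
9.4/7.6/4.2/2.3); rule-2 positives 11/14 and 7/13; double-G-U positives 0;
31 three-mismatch positives split 21 (NUN/NCN) / 10 (NAN/NGN); the AAC-row
worked example (exactly Ser 4, Ala 1, Lys 2, Asp 2, Gly 1); and the
individually reported events pinned positive. A fixed pseudo-random
objective makes the chosen solution stable; intensities for unpinned
positives come from a fixed-seed uniform draw over 1–5 (the published
per-level histograms are graphical only and nothing downstream depends on
the intensity distribution).

Consequently the benchmark validates the *pipeline arithmetic* — that the
statistics recover the constrained aggregates — not the transcription of
individual cells, which the available text does not permit.

**Known limitation.** The published mismatch-class frequencies
(49.4/18.7/14.7/65.6/29.5/40.5%) are not exactly representable as integer
ratios over this repertoire's class universe sizes (153/341/219/158/245/43),
implying the original supplementary repertoire differs in a few wobble
assignments. The builder fixes class event counts to the closest consistent
integers (76/65/31/104/73/17 → 49.7/19.1/14.2/65.8/29.8/39.5%), keeping the
hard counts (31, 21/10, 366) exact; integration tests assert class
frequencies within 1.0 percentage point. The source text itself prints both
14.7% and 14.9% for the 3-mismatch class; this package reports its computed
value.

## Diversity index and property constants

D(S) = (max−min hydropathy) × (max−min volume) × (max−min pI) over the set;
for a pair each range is the absolute difference; sets of size < 2 are
rejected. The packaged constants are Kyte–Doolittle (1982) hydropathy,
Zamyatnin residue volumes, and the classical pI table (Asp 2.77 … Arg
10.76); this combination reproduces all thirteen published index values
(70.1, 65.5, 1500, 6680, 507; 191, 83.2, 151, 18.3, 148, 3.35; mean 259;
and the 9.0 × 167.7 ranges over all 20), which is the operational test of
the constant tables. The index is monotone under set inclusion (ranges can
only widen), verified by property tests.

For the four (frequency, index) points the package reports Pearson *r* on
(percent, log₁₀ index) **descriptively** and attaches no p-value: with n = 4
a significance statement would be meaningless, and the published analysis
does not specify its correlation statistic.

## PAM30 group analysis

Scores come from the standard PAM30 distribution (via biopython). Averages
use off-diagonal pairs only — C(n,2) unordered pairs within a group,
n_a × n_b pairs between groups, identity scores never included. This is the
only convention that reproduces the published anchors (−1.5, −1.9, −3.6,
−9.7, −6.1, −6.5); a diagonal-inclusive variant is kept in the tests as a
negative control and must fail them. The overall mean equals the
pair-count-weighted combination of the ten group means (identity test).

## Synthetic-data generator

Occurrence is Bernoulli per combination with a probability depending only on
the combination's class — the coarsest model consistent with the summary
statistics the analysis measures. Default probabilities are the published
cell/class frequencies: NUN/U 0.875, NCN/C 0.917, NUN/C 0.750, NCN/U 0.538,
second-position-G-U 0.786, first-position-G-U 0.538, other 0.179. Intensity
given occurrence is categorical over 1–5, uniform by default and
configurable. Randomness comes from a single `numpy.random.default_rng`
(PCG64) generator; combinations are visited in canonical universe order, so
a fixed seed gives byte-identical TSV output, and the seed is recorded in
the output header.

What the generator emulates: the class-dependent occurrence structure and
the resulting coverage statistics; parameter recovery (empirical proportions
with binomial standard errors) closes the loop at 200 replicates within
binomial confidence intervals. What it does not emulate: codon-specific
effects within a class, correlated errors across amino acids at one codon,
intensity–class dependence, and any mechanistic (kinetic or structural)
model of near-cognate selection. Passing tests therefore demonstrate
pipeline correctness and statistical calibration, not biological realism of
individual cells.

## Numerical and interface choices

- RNA alphabet throughout; DNA input is transliterated with a warning.
- Matrix TSV format: `codon` column (61 rows, codon-table order UUU … GGG),
  20 amino-acid columns ordered by group (FLIMV SPTA YHQNKDE CWRG), cells
  integer 0–5 or `NA` exactly at the 61 cognate positions; violations name
  the offending cell.
- Half-up rounding everywhere a printed-precision number is produced.
- Problem sizes: every computation is exhaustive over the 1159 combinations
  (no sampling); the recovery study uses 200 replicate matrices; property
  tests sample 60 random subset pairs. The full suite runs in seconds.
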