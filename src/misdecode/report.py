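"""End-to-end orchestration: run every analysis stage and write a report bundle.

``run_all`` computes the group-pair frequency table, intensity histograms,
column averages, rule coverage, mismatch-class frequencies, diversity
indexes and PAM30 group averages for one intensity matrix, writes each as a
TSV, and (optionally) juxtaposes every summary number against the published
expectation it should reproduce.  Expectations live in a packaged TSV so the
comparison targets are data, auditable and overridable, not code.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import genetic_code as gc
from .diversity import frequency_vs_diversity, group_indexes, pair_diversity_table
from .matrix import (
    IntensityMatrix,
    all_group_pair_frequencies,
    all_intensity_histograms,
    column_average_counts,
    load_matrix,
)
from .pam import group_average, load_matrix as load_pam, overall_average
from .rules import coverage_stats
from .wobble import class_frequency_table, load_repertoire, three_mismatch_split

logger = logging.getLogger("misdecode")


@dataclass
class RunConfig:
    """Paths and flags for a full pipeline run.

    ``matrix_path`` is required; repertoire/properties/PAM paths default to
    the packaged data.  With ``compare=True`` the summary also reports the
    published expectations and a pass/fail verdict per number.
    """

    matrix_path: Path
    out_dir: Path
    repertoire_path: Path | None = None
    properties_path: Path | None = None
    pam_path: Path | None = None
    compare: bool = True
    expectations_path: Path | None = None


def _checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def load_expectations(path: Path | None = None) -> pd.DataFrame:
    if path is None:
        path = Path(resources.files("misdecode.data") / "published_expectations.tsv")
    return pd.read_csv(path, sep="\t")


def compute_summary(
    matrix: IntensityMatrix,
    repertoire,
    properties,
    pam_model,
) -> dict[str, float]:
    """Every headline number of the analysis, keyed as in the expectations TSV."""
    summary: dict[str, float] = {}
    freq = all_group_pair_frequencies(matrix)
    for row in freq.itertuples():
        summary[f"cell_{row.column}_{row.group}_percent"] = row.percent
    for column, mean in column_average_counts(matrix).items():
        summary[f"column_avg_{column}"] = mean
    cov = coverage_stats(matrix, repertoire)
    summary["rule1_percent"] = cov["RULE1"].percent
    summary["rule2_percent"] = cov["RULE2"].percent
    summary["other_percent"] = cov["OTHER"].percent
    summary["rule2_second_gu_percent"] = cov["RULE2_SECOND_GU"].percent
    summary["rule2_first_gu_percent"] = cov["RULE2_FIRST_GU"].percent
    summary["double_gu_percent"] = cov["DOUBLE_GU"].percent
    summary["total_events"] = float(matrix.total_events())
    for label, rec in class_frequency_table(matrix, repertoire).items():
        summary[f"class_{label}_percent"] = rec.percent
    split = three_mismatch_split(matrix, repertoire)
    summary["three_mismatch_events"] = float(split["total"])
    summary["three_mismatch_NUN_NCN"] = float(split["NUN_NCN"])
    for group, value in group_indexes(properties).items():
        summary[f"diversity_{group}"] = value
    for key, value in pair_diversity_table(properties).items():
        summary[f"pair_{key}"] = value
    for g in "UCAG":
        summary[f"pam_within_{g}"] = group_average(pam_model, g, g)
    summary["pam_between_U_C"] = group_average(pam_model, "U", "C")
    summary["pam_overall"] = overall_average(pam_model)
    summary["diversity_freq_pearson_r_log10"] = round(
        frequency_vs_diversity(matrix, properties)["pearson_r_log10"], 3
    )
    return summary


def run_all(config: RunConfig) -> dict[str, float]:
    """Run all stages, write the report bundle, return the summary mapping."""
    out = Path(config.out_dir)
    for path in [config.matrix_path, config.repertoire_path, config.properties_path]:
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    out.mkdir(parents=True, exist_ok=True)

    logger.info("matrix: %s (sha256 %s)", config.matrix_path, _checksum(config.matrix_path))
    matrix = load_matrix(config.matrix_path)
    repertoire = load_repertoire(config.repertoire_path)
    properties = gc.load_properties(config.properties_path or gc.properties_path())
    pam_model = load_pam(config.pam_path)

    logger.info("stage: group-pair frequencies and histograms")
    all_group_pair_frequencies(matrix).to_csv(
        out / "group_frequencies.tsv", sep="\t", index=False
    )
    all_intensity_histograms(matrix).to_csv(
        out / "intensity_histograms.tsv", sep="\t", index=False
    )
    logger.info("stage: rule classification and coverage")
    cov = coverage_stats(matrix, repertoire)
    pd.DataFrame(
        [
            {
                "class": key,
                "events": rec.numerator,
                "universe": rec.denominator,
                "percent": rec.percent,
            }
            for key, rec in cov.items()
        ]
    ).to_csv(out / "rule_coverage.tsv", sep="\t", index=False)
    logger.info("stage: mismatch classes")
    pd.DataFrame(
        [
            {
                "class": label,
                "events": rec.numerator,
                "universe": rec.denominator,
                "percent": rec.percent,
            }
            for label, rec in class_frequency_table(matrix, repertoire).items()
        ]
    ).to_csv(out / "mismatch_classes.tsv", sep="\t", index=False)
    logger.info("stage: diversity and PAM")
    summary = compute_summary(matrix, repertoire, properties, pam_model)
    rows = [{"key": k, "computed": v} for k, v in summary.items()]
    summary_df = pd.DataFrame(rows)
    if config.compare:
        exp = load_expectations(config.expectations_path)
        summary_df = summary_df.merge(exp, on="key", how="left")
        summary_df["status"] = [
            (
                ""
                if pd.isna(row.expected)
                else ("pass" if abs(row.computed - row.expected) <= row.tolerance else "FAIL")
            )
            for row in summary_df.itertuples()
        ]
    summary_df.to_csv(out / "summary.tsv", sep="\t", index=False)
    (out / "summary.txt").write_text(summary_df.to_string(index=False) + "\n")
    logger.info("report written to %s", out)
    return summary
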