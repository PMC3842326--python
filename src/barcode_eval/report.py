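"""Report assembly: per-species results table, summary statistics, and
figure-ready CSV data.

``summarize_results_table`` also works on the packaged study results table,
so the aggregation path (percentages, Wilson intervals, concordance,
correlation with sampling depth) can be replayed on published per-species
indicators without the underlying sequences.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .gap import SpeciesGapResult, gap_discrimination_concordance, gap_results_frame
from .identify import DiscriminationRow
from .stats import StatsError, point_biserial, wilson_ci

PCT = lambda k, n: 100 * k / n  # noqa: E731


def summarize_results_table(
    table: pd.DataFrame,
    indicator_columns: Sequence[str] = ("matK", "rbcL", "nrITS2", "combined"),
    gap_column: str = "gap",
    n_column: str = "n",
    level: float = 0.95,
) -> dict:
    """Aggregate a per-species indicator table into summary statistics.

    Expects one row per species with '+'/'-' indicator columns, a 0/1 gap
    column, and a sample-size column.  Returns percentages (one decimal is a
    display concern; values are full precision) with Wilson intervals, the
    gap-vs-discrimination concordance with both McNemar forms, the
    point-biserial correlation of sample size with gap presence, and the
    discrimination rate among species with two or more samples.
    """
    n_species = len(table)
    out: dict = {"n_species": n_species}
    for col in indicator_columns:
        k = int((table[col] == "+").sum())
        ci = wilson_ci(k, n_species, level=level)
        out[col] = {
            "discriminated": k,
            "pct": PCT(k, n_species),
            "ci_lower_pct": 100 * ci.lower,
            "ci_upper_pct": 100 * ci.upper,
        }
    k_gap = int(table[gap_column].sum())
    ci = wilson_ci(k_gap, n_species, level=level)
    out["multilocus_gap"] = {
        "species_with_gap": k_gap,
        "pct": PCT(k_gap, n_species),
        "ci_lower_pct": 100 * ci.lower,
        "ci_upper_pct": 100 * ci.upper,
    }

    combined_col = indicator_columns[-1]
    gap_flags = {row["species"]: bool(row[gap_column]) for _, row in table.iterrows()}
    disc = {row["species"]: row[combined_col] == "+" for _, row in table.iterrows()}
    conc = gap_discrimination_concordance(gap_flags, disc)
    out["concordance"] = {
        "gap_and_discriminated": conc.both,
        "gap_not_discriminated": conc.gap_only,
        "no_gap_discriminated": conc.disc_only,
        "neither": conc.neither,
        "mcnemar_exact_p": conc.mcnemar_exact.p_value,
        "mcnemar_chi2_p": conc.mcnemar_chi2.p_value if conc.mcnemar_chi2 else None,
    }

    try:
        pb = point_biserial(table[gap_column].astype(int), table[n_column].astype(float))
        out["sample_size_vs_gap"] = {"r_pb": pb.statistic, "p": pb.p_value}
    except StatsError as exc:
        out["sample_size_vs_gap"] = {"error": str(exc)}

    multi = table[table[n_column] >= 2]
    if len(multi):
        k_multi = int((multi[combined_col] == "+").sum())
        out["multi_sample_species"] = {
            "n_species": len(multi),
            "discriminated": k_multi,
            "pct": PCT(k_multi, len(multi)),
        }
    return out


def discrimination_table(
    rows: Sequence[DiscriminationRow],
    marker_set_labels: Sequence[str],
    gap_flags: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-species report table: n, one indicator column per marker set,
    the multilocus gap flag, and the conflated-species list for the largest
    marker set (ordered by conflation frequency)."""
    data = []
    combined = marker_set_labels[-1]
    for r in rows:
        row = {"species": r.species, "n": r.n}
        for label in marker_set_labels:
            row[label] = r.indicators[label]
        if gap_flags is not None:
            row["gap"] = int(gap_flags.get(r.species, False))
        row["conflated"] = ";".join(r.conflated[combined])
        data.append(row)
    return pd.DataFrame(data)


def make_report(
    disc_rows: Sequence[DiscriminationRow],
    disc_summary: pd.DataFrame,
    marker_set_labels: Sequence[str],
    gap_summary: pd.DataFrame | None = None,
    gap_results: Mapping[str, Sequence[SpeciesGapResult]] | None = None,
    qc_rows: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Assemble the full report bundle; optionally write CSV/JSON files.

    Contents: the per-species table (Table-1 shape), the discrimination and
    gap summary frames, the gap-vs-discrimination concordance for the
    largest marker set, scatter data for a quality-vs-complexity figure and
    an intra-vs-inter-distance figure.  Column order is deterministic and
    every number comes from a stage output.
    """
    combined = marker_set_labels[-1]
    gap_flags = None
    bundle: dict = {"summary": {}}
    if gap_results is not None and "multilocus" in gap_results:
        gap_flags = {r.species: r.gap for r in gap_results["multilocus"]}
    table = discrimination_table(disc_rows, marker_set_labels, gap_flags)
    bundle["table"] = table
    bundle["discrimination_summary"] = disc_summary
    if gap_summary is not None:
        bundle["gap_summary"] = gap_summary
    if gap_results is not None:
        bundle["gap_detail"] = pd.concat(
            [gap_results_frame(res) for res in gap_results.values()], ignore_index=True
        )
    if gap_flags is not None:
        disc_flags = {r.species: r.indicators[combined] == "+" for r in disc_rows}
        shared = set(gap_flags) & set(disc_flags)
        conc = gap_discrimination_concordance(
            {s: gap_flags[s] for s in shared}, {s: disc_flags[s] for s in shared}
        )
        bundle["summary"]["concordance"] = {
            "gap_and_discriminated": conc.both,
            "gap_not_discriminated": conc.gap_only,
            "no_gap_discriminated": conc.disc_only,
            "neither": conc.neither,
            "mcnemar_exact_p": conc.mcnemar_exact.p_value,
            "mcnemar_chi2_p": conc.mcnemar_chi2.p_value if conc.mcnemar_chi2 else None,
        }
    bundle["summary"]["discrimination"] = disc_summary.to_dict(orient="records")
    if gap_summary is not None:
        bundle["summary"]["gap"] = gap_summary.to_dict(orient="records")
    if qc_rows is not None and not qc_rows.empty:
        bundle["figure_quality_vs_complexity"] = qc_rows[
            ["specimen_id", "marker", "b_index", "lc"]
        ]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "species_table.csv", index=False)
        disc_summary.to_csv(out_dir / "discrimination_summary.csv", index=False)
        if gap_summary is not None:
            gap_summary.to_csv(out_dir / "gap_summary.csv", index=False)
        if "gap_detail" in bundle:
            bundle["gap_detail"].to_csv(out_dir / "gap_detail.csv", index=False)
        if "figure_quality_vs_complexity" in bundle:
            bundle["figure_quality_vs_complexity"].to_csv(
                out_dir / "figure_quality_vs_complexity.csv", index=False
            )
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(bundle["summary"], fh, indent=2)
    return bundle
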