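"""Per-species barcode-gap analysis.

A species has a *barcode gap* for a marker set when its minimum distance to
any specimen of another species strictly exceeds its maximum within-species
distance.  Singleton species have max_intra = 0 by convention (no within
pair exists), so a singleton has a gap exactly when its nearest
heterospecific neighbour is at non-zero distance.  Ties (min_inter equal to
max_intra) score as no gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import Aligner, DistanceMatrix, distance_matrix, default_aligner
from .records import BarcodeLibrary, BarcodeEvalError
from .stats import TestResult, mcnemar, wilson_ci


class GapError(BarcodeEvalError):
    pass


@dataclass
class SpeciesGapResult:
    species: str
    marker_set: str
    n: int
    max_intra: float
    min_inter: float
    gap: bool


def species_gap(
    dm: DistanceMatrix, species_of: Mapping[str, str]
) -> list[SpeciesGapResult]:
    """Max-intraspecific vs min-interspecific distance per species.

    Every specimen in the matrix must be labeled; at least two species are
    required (otherwise no interspecific pair exists).
    """
    missing = [sid for sid in dm.ids if sid not in species_of]
    if missing:
        raise GapError(f"specimens without species labels: {missing}")
    labels = np.array([species_of[sid] for sid in dm.ids])
    species = sorted(set(labels))
    if len(species) < 2:
        raise GapError("barcode-gap analysis needs at least two species")
    out = []
    for sp in species:
        mask = labels == sp
        n = int(mask.sum())
        within = dm.matrix[np.ix_(mask, mask)]
        max_intra = float(within[np.triu_indices(n, k=1)].max()) if n > 1 else 0.0
        between = dm.matrix[np.ix_(mask, ~mask)]
        min_inter = float(between.min())
        out.append(
            SpeciesGapResult(
                species=sp,
                marker_set=dm.label,
                n=n,
                max_intra=max_intra,
                min_inter=min_inter,
                gap=min_inter > max_intra,
            )
        )
    return out


def gap_results_frame(results: Sequence[SpeciesGapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "marker_set": r.marker_set,
                "n": r.n,
                "max_intra": r.max_intra,
                "min_inter": r.min_inter,
                "gap": int(r.gap),
            }
            for r in results
        ]
    )


def gap_frequencies(
    lib: BarcodeLibrary,
    markers: Sequence[str],
    level: float = 0.95,
    aligner: Aligner | None = None,
) -> tuple[pd.DataFrame, dict[str, list[SpeciesGapResult]]]:
    """Percent of species with a barcode gap, per marker and multilocus.

    Expects a complete-sample library (every specimen carries every marker).
    Returns a summary frame (with Wilson confidence intervals) and the
    per-species results keyed by marker set.
    """
    aligner = aligner or default_aligner()
    species_of = {sid: lib.species_of(sid) for sid in lib.specimens}
    marker_sets: list[tuple[str, Sequence[str]]] = [(m, [m]) for m in markers]
    if len(markers) > 1:
        marker_sets.append(("multilocus", list(markers)))
    rows = []
    per_set: dict[str, list[SpeciesGapResult]] = {}
    for label, mset in marker_sets:
        dm = distance_matrix(lib, mset, aligner=aligner)
        dm.label = label
        results = species_gap(dm, species_of)
        per_set[label] = results
        k = sum(r.gap for r in results)
        n = len(results)
        ci = wilson_ci(k, n, level=level)
        rows.append(
            {
                "marker_set": label,
                "species_with_gap": k,
                "n_species": n,
                "pct": 100 * k / n,
                "ci_lower_pct": 100 * ci.lower,
                "ci_upper_pct": 100 * ci.upper,
            }
        )
    return pd.DataFrame(rows), per_set


@dataclass
class ConcordanceResult:
    """2x2 agreement between gap presence and discrimination success."""

    both: int  # gap and discriminated
    gap_only: int  # gap, not discriminated (discordant b)
    disc_only: int  # no gap, discriminated (discordant c)
    neither: int
    mcnemar_exact: TestResult
    mcnemar_chi2: TestResult | None


def gap_discrimination_concordance(
    gap_flags: Mapping[str, bool], discriminated: Mapping[str, bool]
) -> ConcordanceResult:
    """Cross-tabulate per-species gap flags against discrimination success
    and test the discordant cells with McNemar's test (exact and, when
    defined, chi-square form)."""
    if set(gap_flags) != set(discriminated):
        raise GapError("gap and discrimination vectors cover different species")
    a = b = c = d = 0
    for sp, g in gap_flags.items():
        disc = discriminated[sp]
        if g and disc:
            a += 1
        elif g and not disc:
            b += 1
        elif disc:
            c += 1
        else:
            d += 1
    exact = mcnemar(b, c, mode="exact")
    chi2 = mcnemar(b, c, mode="chi2") if b + c > 0 else None
    return ConcordanceResult(
        both=a, gap_only=b, disc_only=c, neither=d, mcnemar_exact=exact, mcnemar_chi2=chi2
    )
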