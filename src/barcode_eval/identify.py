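"""Reference-database species discrimination and tree-based identification.

The identification rule: every complete sample is queried against a
reference database built from *all* sequences (building the reference from
complete samples only would overestimate success).  A query returns the set
of species owning at least one reference sequence at minimal p-distance
from the query, ties included.  Marker combinations intersect the
per-marker species sets.  A species is scored '+' for a marker set when
every query of every one of its specimens returns exactly that species and
nothing else; otherwise the species it was confused with are reported,
ordered by how often they were returned (ties alphabetical).

Tree-based identification uses the least-inclusive-clade criterion: a
species with two or more samples succeeds when the smallest clade
containing all of its samples contains no sample of any other species.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .distances import Aligner, default_aligner
from .records import BarcodeLibrary, BarcodeEvalError
from .stats import wilson_ci


class DiscriminationError(BarcodeEvalError):
    pass


@dataclass
class Genotype:
    sequence: str
    species: Counter  # species label -> number of reference records
    specimens: list[str] = field(default_factory=list)
    specimen_species: dict = field(default_factory=dict)  # specimen id -> species


class ReferenceDatabase:
    """Deduplicated per-marker registry of distinct sequences.

    Each distinct sequence string is one genotype, annotated with the
    species that own it (with multiplicity) and the contributing specimens.
    """

    def __init__(self, markers: Sequence[str]) -> None:
        self.markers = tuple(markers)
        self._registry: dict[str, dict[str, Genotype]] = {m: {} for m in markers}

    def add(self, marker: str, sequence: str, species: str, specimen_id: str) -> None:
        if marker not in self._registry:
            raise DiscriminationError(f"unknown marker {marker!r}")
        geno = self._registry[marker].get(sequence)
        if geno is None:
            geno = Genotype(sequence=sequence, species=Counter())
            self._registry[marker][sequence] = geno
        geno.species[species] += 1
        geno.specimens.append(specimen_id)
        geno.specimen_species[specimen_id] = species

    def genotypes(self, marker: str) -> list[Genotype]:
        if marker not in self._registry:
            raise DiscriminationError(f"unknown marker {marker!r}")
        return list(self._registry[marker].values())

    def n_genotypes(self, marker: str) -> int:
        return len(self._registry[marker])


def build_reference(lib_all: BarcodeLibrary, markers: Sequence[str] | None = None) -> ReferenceDatabase:
    """Build the reference database from every record in the library."""
    if len(lib_all) == 0:
        raise DiscriminationError("cannot build a reference from an empty library")
    markers = tuple(markers or lib_all.markers)
    ref = ReferenceDatabase(markers)
    for rec in lib_all.records:
        if rec.marker in markers:
            ref.add(rec.marker, rec.sequence, rec.species, rec.specimen_id)
    return ref


@dataclass
class QueryResult:
    specimen_id: str
    marker_set: str
    species: frozenset
    min_distance: float | None


def query(
    ref: ReferenceDatabase,
    sequence: str,
    marker: str,
    aligner: Aligner | None = None,
    specimen_id: str = "",
    exclude_specimen: str | None = None,
) -> QueryResult:
    """Species owning a reference sequence at minimal p-distance (ties kept).

    ``exclude_specimen`` enables leave-one-out querying: that specimen's
    own contribution to the registry is ignored.
    """
    aligner = aligner or default_aligner()
    genotypes = ref.genotypes(marker)
    best: float | None = None
    best_species: set[str] = set()
    for geno in genotypes:
        species = geno.species
        if exclude_specimen is not None and exclude_specimen in geno.specimen_species:
            removed = Counter(
                {geno.specimen_species[exclude_specimen]: geno.specimens.count(exclude_specimen)}
            )
            species = species - removed
            if not species:
                continue
        d = 0.0 if geno.sequence == sequence else aligner.p_distance(geno.sequence, sequence)
        if best is None or d < best:
            best = d
            best_species = set(species)
        elif d == best:
            best_species |= set(species)
    if best is None:
        raise DiscriminationError(f"empty reference for marker {marker!r}")
    return QueryResult(
        specimen_id=specimen_id,
        marker_set=marker,
        species=frozenset(best_species),
        min_distance=best,
    )


def combine(results: Sequence[QueryResult]) -> QueryResult:
    """Intersect per-marker species sets for one specimen.

    The intersection is guaranteed non-empty when the specimen's own records
    are in the reference (self-match returns the true species at every
    marker).  An empty intersection is reported as an error rather than
    silently dropped.
    """
    if not results:
        raise DiscriminationError("no per-marker results to combine")
    sids = {r.specimen_id for r in results}
    if len(sids) > 1:
        raise DiscriminationError(f"results belong to different specimens: {sorted(sids)}")
    species = frozenset.intersection(*(r.species for r in results))
    if not species:
        raise DiscriminationError(
            f"empty intersection for specimen {results[0].specimen_id!r}; "
            f"its own records are probably absent from the reference"
        )
    dists = [r.min_distance for r in results if r.min_distance is not None]
    return QueryResult(
        specimen_id=results[0].specimen_id,
        marker_set="+".join(r.marker_set for r in results),
        species=species,
        min_distance=max(dists) if dists else None,
    )


@dataclass
class DiscriminationRow:
    species: str
    n: int
    indicators: dict  # marker-set label -> '+'/'-'
    conflated: dict  # marker-set label -> ordered list of species


def marker_set_label(mset: Sequence[str]) -> str:
    return "+".join(mset)


def species_discrimination(
    lib_complete: BarcodeLibrary,
    ref: ReferenceDatabase,
    marker_sets: Sequence[Sequence[str]],
    aligner: Aligner | None = None,
    leave_one_out: bool = False,
    level: float = 0.95,
) -> tuple[list[DiscriminationRow], pd.DataFrame]:
    """Score every species for every marker set.

    Returns the per-species rows and a summary frame with the percentage of
    species discriminated (Wilson confidence interval attached) and the
    mean/SD of conflated-set sizes among failed species.
    """
    aligner = aligner or default_aligner()
    labels = [marker_set_label(m) for m in marker_sets]
    # per-specimen per-marker query cache (marker sets share single-marker queries)
    single: dict[tuple[str, str], QueryResult] = {}

    def run_query(sid: str, marker: str) -> QueryResult:
        key = (sid, marker)
        if key not in single:
            rec = lib_complete.get(sid, marker)
            single[key] = query(
                ref,
                rec.sequence,
                marker,
                aligner=aligner,
                specimen_id=sid,
                exclude_specimen=sid if leave_one_out else None,
            )
        return single[key]

    rows: list[DiscriminationRow] = []
    for sp, sids in lib_complete.species_index.items():
        if not sids:
            raise DiscriminationError(f"species {sp!r} has no complete samples")
        indicators: dict[str, str] = {}
        conflated: dict[str, list[str]] = {}
        for mset, label in zip(marker_sets, labels):
            wrong = Counter()
            ok = True
            for sid in sids:
                per_marker = [run_query(sid, m) for m in mset]
                combined = combine(per_marker)
                returned = combined.species
                if returned != {sp}:
                    ok = False
                for other in returned - {sp}:
                    wrong[other] += 1
            indicators[label] = "+" if ok else "-"
            conflated[label] = sorted(wrong, key=lambda s: (-wrong[s], s))
        rows.append(
            DiscriminationRow(
                species=sp, n=len(sids), indicators=indicators, conflated=conflated
            )
        )

    summary_rows = []
    n_species = len(rows)
    for label in labels:
        k = sum(1 for r in rows if r.indicators[label] == "+")
        ci = wilson_ci(k, n_species, level=level)
        fail_sizes = [len(r.conflated[label]) for r in rows if r.indicators[label] == "-"]
        summary_rows.append(
            {
                "marker_set": label,
                "species_discriminated": k,
                "n_species": n_species,
                "pct": 100 * k / n_species,
                "ci_lower_pct": 100 * ci.lower,
                "ci_upper_pct": 100 * ci.upper,
                "mean_conflated": float(np.mean(fail_sizes)) if fail_sizes else 0.0,
                "sd_conflated": float(np.std(fail_sizes, ddof=1))
                if len(fail_sizes) > 1
                else 0.0,
            }
        )
    return rows, pd.DataFrame(summary_rows)


def least_inclusive_clade(
    tree: dendropy.Tree, species_of: Mapping[str, str]
) -> dict[str, str | None]:
    """Monophyly-based identification on a specimen tree.

    For each species with >= 2 samples: '+' when the smallest clade (MRCA)
    containing all of its samples contains no other species' samples, '-'
    otherwise.  Species with a single sample get None (the criterion is not
    applicable to singletons).
    """
    # MRCA queries need a rooted tree; work on a copy so the caller's tree
    # is left untouched.
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    tree.encode_bipartitions()
    leaf_species: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in species_of:
            raise DiscriminationError(f"tree leaf {label!r} has no species mapping")
        leaf_species[label] = species_of[label]
    by_species: dict[str, list[str]] = {}
    for sid, sp in leaf_species.items():
        by_species.setdefault(sp, []).append(sid)
    out: dict[str, str | None] = {}
    taxon_ns = {t.label: t for t in tree.taxon_namespace}
    for sp, sids in sorted(by_species.items()):
        if len(sids) < 2:
            out[sp] = None
            continue
        mrca = tree.mrca(taxa=[taxon_ns[s] for s in sids])
        clade_leaves = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        out[sp] = "+" if all(leaf_species[l] == sp for l in clade_leaves) else "-"
    return out
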