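"""Sequence records, barcode libraries, and readers/writers.

A *barcode library* is a collection of per-specimen, per-marker sequences
together with specimen metadata (species, genus).  The analysis unit of a
barcoding study is the *complete sample*: a specimen for which every
required marker was successfully sequenced.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
GAP_CHARS = frozenset("-.")


class BarcodeEvalError(Exception):
    """Base class for errors raised by this package."""


class LibraryError(BarcodeEvalError):
    """Malformed or inconsistent library input."""


class TreeError(BarcodeEvalError):
    """Malformed tree input or unresolvable leaf labels."""


@dataclass
class SequenceRecord:
    """One specimen x marker sequence.

    ``qualities`` are per-base Phred-scale quality values (QV); ``coverage``
    is the per-position read count of the contig the base call came from.
    Both are optional and, when present, must match the sequence length.
    """

    specimen_id: str
    species: str
    genus: str
    marker: str
    sequence: str
    qualities: tuple[int, ...] | None = None
    coverage: tuple[int, ...] | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise LibraryError(
                f"empty sequence for specimen {self.specimen_id!r} marker {self.marker!r}"
            )
        if not self.species:
            raise LibraryError(f"specimen {self.specimen_id!r} has an empty species label")
        bad = set(self.sequence) - IUPAC_CODES
        if bad & GAP_CHARS:
            raise LibraryError(
                f"sequence for {self.specimen_id!r}/{self.marker!r} contains gap "
                f"characters; supply unaligned sequences (terminal gaps are stripped "
                f"by read_library)"
            )
        if bad:
            raise LibraryError(
                f"invalid nucleotide characters {sorted(bad)} in "
                f"{self.specimen_id!r}/{self.marker!r}"
            )
        if self.qualities is not None:
            self.qualities = tuple(self.qualities)
            if len(self.qualities) != len(self.sequence):
                raise LibraryError(
                    f"qualities length {len(self.qualities)} != sequence length "
                    f"{len(self.sequence)} for {self.specimen_id!r}/{self.marker!r}"
                )
            if any(q < 0 for q in self.qualities):
                raise LibraryError("negative quality value")
        if self.coverage is not None:
            self.coverage = tuple(self.coverage)
            if len(self.coverage) != len(self.sequence):
                raise LibraryError(
                    f"coverage length {len(self.coverage)} != sequence length "
                    f"{len(self.sequence)} for {self.specimen_id!r}/{self.marker!r}"
                )
            if any(c < 1 for c in self.coverage):
                raise LibraryError("coverage values must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


class BarcodeLibrary:
    """Indexed collection of :class:`SequenceRecord`.

    At most one record per (specimen, marker).  Species and genus labels are
    taken from the records and must be internally consistent per specimen.
    """

    def __init__(
        self,
        records: Iterable[SequenceRecord],
        markers: Sequence[str] | None = None,
    ) -> None:
        self._records: dict[tuple[str, str], SequenceRecord] = {}
        self._meta: dict[str, tuple[str, str]] = {}
        seen_markers: list[str] = []
        for rec in records:
            key = (rec.specimen_id, rec.marker)
            if key in self._records:
                raise LibraryError(
                    f"duplicate record for specimen {rec.specimen_id!r} "
                    f"marker {rec.marker!r}"
                )
            prev = self._meta.get(rec.specimen_id)
            if prev is not None and prev != (rec.species, rec.genus):
                raise LibraryError(
                    f"conflicting species/genus metadata for specimen "
                    f"{rec.specimen_id!r}"
                )
            self._records[key] = rec
            self._meta[rec.specimen_id] = (rec.species, rec.genus)
            if rec.marker not in seen_markers:
                seen_markers.append(rec.marker)
        if markers is None:
            self.markers: tuple[str, ...] = tuple(seen_markers)
        else:
            extra = set(seen_markers) - set(markers)
            if extra:
                raise LibraryError(f"records carry markers not in marker list: {sorted(extra)}")
            self.markers = tuple(markers)
        self.import_report: dict[str, list[str]] = {}

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterable[SequenceRecord]:
        return iter(self._records.values())

    @property
    def records(self) -> list[SequenceRecord]:
        return list(self._records.values())

    @property
    def specimens(self) -> list[str]:
        return sorted(self._meta)

    @property
    def species(self) -> list[str]:
        return sorted({sp for sp, _ in self._meta.values()})

    @property
    def species_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for sid, (sp, _) in self._meta.items():
            idx.setdefault(sp, []).append(sid)
        return {sp: sorted(sids) for sp, sids in sorted(idx.items())}

    def species_of(self, specimen_id: str) -> str:
        return self._meta[specimen_id][0]

    def genus_of(self, specimen_id: str) -> str:
        return self._meta[specimen_id][1]

    def n(self, species: str) -> int:
        """Number of specimens of a species present in the library."""
        return sum(1 for sp, _ in self._meta.values() if sp == species)

    def has(self, specimen_id: str, marker: str) -> bool:
        return (specimen_id, marker) in self._records

    def get(self, specimen_id: str, marker: str) -> SequenceRecord:
        try:
            return self._records[(specimen_id, marker)]
        except KeyError:
            raise LibraryError(
                f"no record for specimen {specimen_id!r} marker {marker!r}"
            ) from None

    def records_for_marker(self, marker: str) -> list[SequenceRecord]:
        if marker not in self.markers:
            raise LibraryError(f"unknown marker {marker!r}")
        return [r for (sid, m), r in sorted(self._records.items()) if m == marker]

    def per_marker_counts(self) -> dict[str, int]:
        counts = {m: 0 for m in self.markers}
        for (_, m) in self._records:
            counts[m] += 1
        return counts

    def subset(self, specimen_ids: Iterable[str]) -> "BarcodeLibrary":
        keep = set(specimen_ids)
        recs = [r for (sid, _), r in sorted(self._records.items()) if sid in keep]
        return BarcodeLibrary(recs, markers=self.markers)

    def with_records(self, new_records: Iterable[SequenceRecord]) -> "BarcodeLibrary":
        """New library with additional records appended."""
        return BarcodeLibrary(self.records + list(new_records))


def select_complete_samples(
    lib: BarcodeLibrary, required_markers: Sequence[str]
) -> BarcodeLibrary:
    """Subset to specimens with one record for every required marker.

    Species with no remaining specimen disappear from the species index.
    Idempotent; monotone under specimen addition.
    """
    unknown = set(required_markers) - set(lib.markers)
    if unknown:
        raise LibraryError(f"unknown marker(s): {sorted(unknown)}")
    complete = [
        sid for sid in lib.specimens if all(lib.has(sid, m) for m in required_markers)
    ]
    return lib.subset(complete)


TRUTHY = {"1", "true", "yes", "y"}


def _read_metadata(metadata_path: Path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    required = {"specimen_id", "species"}
    missing = required - set(meta.columns)
    if missing:
        raise LibraryError(f"metadata missing required column(s): {sorted(missing)}")
    if meta["specimen_id"].duplicated().any():
        dups = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise LibraryError(f"duplicate specimen_id in metadata: {dups}")
    return meta


def read_library(
    fasta_paths: Mapping[str, str | Path],
    metadata_path: str | Path,
    strict: bool = True,
    apply_exclusions: bool = True,
) -> BarcodeLibrary:
    """Read one FASTA per marker plus a TSV metadata table.

    The first whitespace-delimited token of each FASTA header is the
    specimen id and must resolve in the metadata table (columns
    ``specimen_id``, ``species``, optional ``genus``, ``exclude``, and
    per-marker ``<marker>_accession``).  Sequences are upper-cased and
    terminal gap characters stripped; internal gaps are rejected.

    With ``strict=False``, FASTA records without metadata are skipped and
    listed in ``library.import_report`` instead of raising.
    """
    metadata_path = Path(metadata_path)
    if not metadata_path.exists():
        raise LibraryError(f"metadata file not found: {metadata_path}")
    meta = _read_metadata(metadata_path)
    meta_by_id = meta.set_index("specimen_id")

    excluded: set[str] = set()
    if apply_exclusions and "exclude" in meta.columns:
        excluded = set(
            meta.loc[meta["exclude"].str.strip().str.lower().isin(TRUTHY), "specimen_id"]
        )

    records: list[SequenceRecord] = []
    report: dict[str, list[str]] = {"unknown_specimens": [], "excluded_specimens": []}
    for marker, path in fasta_paths.items():
        path = Path(path)
        if not path.exists():
            raise LibraryError(f"FASTA file not found for marker {marker!r}: {path}")
        for seqrec in SeqIO.parse(str(path), "fasta"):
            sid = seqrec.id.split()[0]
            if sid in excluded:
                report["excluded_specimens"].append(sid)
                continue
            if sid not in meta_by_id.index:
                if strict:
                    raise LibraryError(
                        f"FASTA id {sid!r} (marker {marker!r}) is absent from the "
                        f"metadata table"
                    )
                report["unknown_specimens"].append(sid)
                continue
            row = meta_by_id.loc[sid]
            species = row["species"].strip()
            genus = str(row.get("genus", "")).strip() or species.split()[0]
            acc_col = f"{marker}_accession"
            accession = str(row[acc_col]).strip() or None if acc_col in meta.columns else None
            seq = str(seqrec.seq).upper().strip("-.")
            records.append(
                SequenceRecord(
                    specimen_id=sid,
                    species=species,
                    genus=genus,
                    marker=marker,
                    sequence=seq,
                    accession=accession,
                )
            )
    lib = BarcodeLibrary(records, markers=list(fasta_paths))
    lib.import_report = report
    return lib


def write_library(lib: BarcodeLibrary, out_dir: str | Path) -> dict[str, Path]:
    """Write one FASTA per marker plus ``metadata.tsv``; returns paths.

    Round-trips bit-exactly through :func:`read_library`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for marker in lib.markers:
        p = out_dir / f"{marker}.fasta"
        with open(p, "w") as fh:
            for rec in lib.records_for_marker(marker):
                fh.write(f">{rec.specimen_id}\n{rec.sequence}\n")
        paths[marker] = p
    acc_cols = [f"{m}_accession" for m in lib.markers]
    rows = []
    for sid in lib.specimens:
        row = {
            "specimen_id": sid,
            "species": lib.species_of(sid),
            "genus": lib.genus_of(sid),
        }
        for m, col in zip(lib.markers, acc_cols):
            row[col] = lib.get(sid, m).accession or "" if lib.has(sid, m) else ""
        rows.append(row)
    meta_path = out_dir / "metadata.tsv"
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path
    return paths


def load_results_table() -> pd.DataFrame:
    """Packaged transcription of the study's per-species results table.

    One row per species of the complete sample (97 rows): ``n``, the four
    discrimination indicators (``matK``, ``rbcL``, ``nrITS2``, ``combined``;
    '+'/'-'), the multilocus barcode-gap flag (``gap``; 0/1), and the most
    frequently conflated species (semicolon-separated; ``conflated_truncated``
    marks lists the source printed with a trailing "et al.").
    """
    ref = importlib.resources.files("barcode_eval.data").joinpath(
        "table1_complete_samples.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"n": int, "gap": int}).fillna("")
    return df


def read_tree(
    newick_path: str | Path, library: BarcodeLibrary | None = None
) -> dendropy.Tree:
    """Read a Newick tree whose leaf labels are specimen ids.

    If a library is given, every leaf must resolve to a specimen in it.
    """
    newick_path = Path(newick_path)
    if not newick_path.exists():
        raise TreeError(f"tree file not found: {newick_path}")
    try:
        tree = dendropy.Tree.get(
            path=str(newick_path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick in {newick_path}: {exc}") from exc
    if library is not None:
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        unmatched = sorted(leaves - set(library.specimens))
        if unmatched:
            raise TreeError(f"tree leaves not found in library: {unmatched}")
    return tree
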