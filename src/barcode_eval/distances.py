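"""Pairwise global alignment, uncorrected p-distance, and indel coding.

Distances are uncorrected p-distances: the number of unambiguous nucleotide
differences divided by the total number of aligned positions.  Columns
containing a gap or an ambiguity code count toward the denominator but never
toward the numerator.  Every pair of sequences is aligned independently
(never via a multiple alignment), mirroring per-pair alignment of barcode
sequences; the multilocus distance pools difference and column counts over
markers, which is equivalent to aligning a concatenation marker by marker.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

if TYPE_CHECKING:
    import dendropy

from .records import BarcodeLibrary, BarcodeEvalError

UNAMBIGUOUS = frozenset("ACGT")


class AlignmentError(BarcodeEvalError):
    pass


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap scoring for global alignment.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  With
    ``free_end_gaps`` terminal gaps are unpenalised, which is the right
    default for barcode amplicons trimmed to slightly different extents.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5
    free_end_gaps: bool = True


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned strings differ in length")

    def __len__(self) -> int:
        return len(self.aligned_a)


class Aligner:
    """Global pairwise aligner with memoised difference/column counts.

    Ties among co-optimal alignments are broken deterministically (first
    traceback path of the underlying dynamic program).  Identical sequences
    short-circuit to the trivial gapless alignment.
    """

    def __init__(self, params: AlignmentParams | None = None) -> None:
        self.params = params or AlignmentParams()
        p = self.params
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = p.match
        a.mismatch_score = p.mismatch
        a.open_gap_score = p.gap_open
        a.extend_gap_score = p.gap_extend
        if p.free_end_gaps:
            if hasattr(a, "open_end_gap_score"):
                a.open_end_gap_score = 0.0
                a.extend_end_gap_score = 0.0
            else:  # older Bio.Align attribute names
                a.end_open_gap_score = 0.0
                a.end_extend_gap_score = 0.0
        self._aligner = a
        self._count_cache: dict[tuple[str, str], tuple[int, int]] = {}

    def align(self, a: str, b: str) -> PairwiseAlignment:
        if not a or not b:
            raise AlignmentError("cannot align an empty sequence")
        if a == b:
            return PairwiseAlignment(a, b, float(len(a) * self.params.match))
        aln = self._aligner.align(a, b)[0]
        return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))

    def diff_counts(self, a: str, b: str) -> tuple[int, int]:
        """(unambiguous differences, aligned columns) for a pair; memoised."""
        if a == b:
            return 0, len(a)
        key = (a, b) if a <= b else (b, a)
        hit = self._count_cache.get(key)
        if hit is None:
            aln = self.align(key[0], key[1])
            hit = alignment_diff_counts(aln)
            self._count_cache[key] = hit
        return hit

    def p_distance(self, a: str, b: str) -> float:
        d, n = self.diff_counts(a, b)
        return d / n


_DEFAULT_ALIGNER: Aligner | None = None


def default_aligner() -> Aligner:
    global _DEFAULT_ALIGNER
    if _DEFAULT_ALIGNER is None:
        _DEFAULT_ALIGNER = Aligner()
    return _DEFAULT_ALIGNER


def pairwise_align(a: str, b: str, params: AlignmentParams | None = None) -> PairwiseAlignment:
    """Optimal global alignment of two sequences under affine gap scoring."""
    return Aligner(params).align(a, b) if params is not None else default_aligner().align(a, b)


def alignment_diff_counts(aln: PairwiseAlignment) -> tuple[int, int]:
    diffs = sum(
        1
        for x, y in zip(aln.aligned_a, aln.aligned_b)
        if x != y and x in UNAMBIGUOUS and y in UNAMBIGUOUS
    )
    return diffs, len(aln)


def p_distance(aln: PairwiseAlignment) -> float:
    """Uncorrected p-distance of an alignment.

    Numerator: columns where both symbols are unambiguous nucleotides and
    differ.  Denominator: all alignment columns.
    """
    if len(aln) == 0:
        raise AlignmentError("zero-length alignment")
    d, n = alignment_diff_counts(aln)
    return d / n


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise p-distances with ordered specimen ids."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise AlignmentError("distance matrix shape does not match id count")

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.matrix[i, j])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))


def _pooled_counts(
    lib: BarcodeLibrary,
    markers: Sequence[str],
    sid_a: str,
    sid_b: str,
    aligner: Aligner,
) -> tuple[int, int]:
    diffs = cols = 0
    for m in markers:
        for sid in (sid_a, sid_b):
            if not lib.has(sid, m):
                raise AlignmentError(f"specimen {sid!r} is missing marker {m!r}")
        d, n = aligner.diff_counts(lib.get(sid_a, m).sequence, lib.get(sid_b, m).sequence)
        diffs += d
        cols += n
    return diffs, cols


def multilocus_distance(
    lib: BarcodeLibrary,
    markers: Sequence[str],
    sid_a: str,
    sid_b: str,
    aligner: Aligner | None = None,
) -> float:
    """Pooled p-distance over markers: sum(diffs) / sum(aligned columns)."""
    aligner = aligner or default_aligner()
    d, n = _pooled_counts(lib, markers, sid_a, sid_b, aligner)
    return d / n


def distance_matrix(
    lib: BarcodeLibrary,
    markers: str | Sequence[str],
    aligner: Aligner | None = None,
) -> DistanceMatrix:
    """All-pairs p-distance matrix for one marker or a pooled marker set.

    Every specimen must carry every requested marker (use
    :func:`~barcode_eval.records.select_complete_samples` first).
    """
    if isinstance(markers, str):
        markers = [markers]
    aligner = aligner or default_aligner()
    ids = tuple(lib.specimens)
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = multilocus_distance(lib, markers, ids[i], ids[j], aligner)
        mat[i, j] = mat[j, i] = d
    label = markers[0] if len(markers) == 1 else "multilocus"
    return DistanceMatrix(ids=ids, matrix=mat, label=label)


# ---------------------------------------------------------------------------
# Simple indel coding
# ---------------------------------------------------------------------------


@dataclass
class IndelCharacterMatrix:
    """Binary gap-presence characters, one per distinct internal gap span.

    Spans are half-open ``[start, end)`` in 1-based alignment coordinates.
    States: '1' the row has exactly this gap span, '0' it does not, '-' the
    span is strictly inside a longer gap of the row (inapplicable).
    """

    ids: tuple[str, ...]
    events: tuple[tuple[int, int], ...]
    states: list[str]  # one string of 0/1/- per id, len == len(events)

    def to_frame(self):
        import pandas as pd

        cols = [f"gap_{s}_{e}" for s, e in self.events]
        return pd.DataFrame(
            [list(row) for row in self.states], index=list(self.ids), columns=cols
        )


def _gap_spans(row: str) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    """Internal gap spans (0-based half-open) and the (lead, tail) extents."""
    n = len(row)
    lead = n - len(row.lstrip("-"))
    tail = n - len(row.rstrip("-"))
    spans = []
    i = lead
    end_core = n - tail
    while i < end_core:
        if row[i] == "-":
            j = i
            while j < end_core and row[j] == "-":
                j += 1
            spans.append((i, j))
            i = j
        else:
            i += 1
    return spans, (lead, n - tail)


def simple_indel_coding(msa: Mapping[str, str] | Iterable[tuple[str, str]]) -> IndelCharacterMatrix:
    """Code alignment gaps as binary presence/absence characters.

    Each distinct internal gap span (identical start and end across rows)
    becomes one character.  A row whose own gap strictly contains a
    character's span is scored inapplicable ('-') for that character, as is
    a row whose terminal (leading/trailing) missing region covers the span.
    Terminal gaps themselves are treated as missing data, not as characters.
    """
    items = list(msa.items()) if isinstance(msa, Mapping) else list(msa)
    if not items:
        return IndelCharacterMatrix(ids=(), events=(), states=[])
    length = len(items[0][1])
    if any(len(row) != length for _, row in items):
        raise AlignmentError("ragged alignment: rows differ in length")

    per_row: dict[str, tuple[list[tuple[int, int]], tuple[int, int]]] = {
        sid: _gap_spans(row) for sid, row in items
    }
    events = sorted({span for spans, _ in per_row.values() for span in spans})
    states: list[str] = []
    for sid, _row in items:
        spans, (lead, core_end) = per_row[sid]
        span_set = set(spans)
        chars = []
        for (s, e) in events:
            if (s, e) in span_set:
                chars.append("1")
            elif s >= lead and e <= core_end and not any(
                a <= s and e <= b and (a, b) != (s, e) for a, b in spans
            ):
                chars.append("0")
            else:
                # strictly nested in a longer gap, or under a terminal gap
                chars.append("-")
        states.append("".join(chars))
    # report events in 1-based coordinates
    events_1b = tuple((s + 1, e + 1) for s, e in events)
    return IndelCharacterMatrix(
        ids=tuple(sid for sid, _ in items), events=events_1b, states=states
    )


def nj_tree(dm: DistanceMatrix) -> "dendropy.Tree":
    """Neighbor-joining tree from a distance matrix (convenience builder).

    Input rows are sorted by specimen id before the join so ties resolve
    deterministically.  Requires at least three specimens.
    """
    import dendropy
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    if len(dm.ids) < 3:
        raise AlignmentError("neighbor joining needs at least 3 specimens")
    order = sorted(range(len(dm.ids)), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]
    mat = dm.matrix[np.ix_(order, order)]
    tree = skbio_nj(SkbioDM(mat, ids=ids))
    import io

    buf = io.StringIO()
    tree.write(buf, format="newick")
    return dendropy.Tree.get(
        data=buf.getvalue(), schema="newick", preserve_underscores=True
    )
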