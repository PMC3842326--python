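"""Synthetic barcode libraries with analytically known ground truth.

The generator emulates the sampling design of a multi-genus barcode
reference library: a handful of genera, 2-20 species per genus, 1-3
individuals per species, several unlinked markers a few hundred bases long,
small between-species divergence, near-zero within-species divergence, and
the two empirically observed failure modes — multilocus genotypes shared
across species boundaries, and absence of variation.

Substitutions follow a Jukes-Cantor-style scheme (uniformly chosen sites,
uniform replacement base): downstream distances are uncorrected p-distances,
so nothing finer is needed.  Indels enter only through explicit homopolymer
insertions applied uniformly to all sequences of a marker, which keeps every
sequence of a marker the same length and makes the expected distances,
conflation sets, and gap flags computable exactly from the generated
genotype strings (no simulation noise).  Genotype sharing copies the full
marker sequences, guaranteeing distance zero; specimens of species involved
in sharing receive no intraspecific mutations so the shared genotype stays
exactly shared.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import BarcodeLibrary, BarcodeEvalError, SequenceRecord

BASES = np.array(list("ACGT"))


class SimulationError(BarcodeEvalError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for one synthetic library.

    Divergences are substitutions per site; individuals per species is an
    inclusive range.  ``shared_genotype_pairs`` lists (species_a, species_b)
    index pairs forced to share one multilocus genotype.
    ``quality_profile`` is (fraction of positions with QV >= 30, coverage
    distribution over small contig sizes).
    """

    n_species: int = 10
    individuals_per_species: tuple[int, int] = (1, 3)
    markers: tuple[tuple[str, int], ...] = (
        ("matK", 770),
        ("rbcL", 607),
        ("nrITS2", 425),
    )
    n_genera: int = 2
    interspecific_divergence: float = 0.02
    intraspecific_divergence: float = 0.002
    shared_genotype_pairs: tuple[tuple[int, int], ...] = ()
    homopolymer_insertions: tuple[tuple[str, str, int], ...] = ()
    quality_profile: tuple[float, tuple[tuple[int, float], ...]] = (
        0.935,
        ((1, 0.1), (2, 0.8), (3, 0.1)),
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise SimulationError("n_species must be >= 1")
        lo, hi = self.individuals_per_species
        if not 1 <= lo <= hi:
            raise SimulationError("individuals_per_species must be a range with 1 <= lo <= hi")
        for d in (self.interspecific_divergence, self.intraspecific_divergence):
            if not 0 <= d <= 0.75:
                raise SimulationError("divergences must lie in [0, 0.75]")
        if not self.markers:
            raise SimulationError("at least one marker required")
        for name, length in self.markers:
            if length < 1:
                raise SimulationError(f"marker {name!r} has non-positive length")
            if self.interspecific_divergence > 0 and round(
                self.interspecific_divergence * length
            ) < 1:
                raise SimulationError(
                    f"interspecific divergence {self.interspecific_divergence} rounds to "
                    f"zero substitutions on marker {name!r} (length {length}): infeasible"
                )
        for a, b in self.shared_genotype_pairs:
            if not (0 <= a < self.n_species and 0 <= b < self.n_species) or a == b:
                raise SimulationError(f"invalid shared genotype pair ({a}, {b})")
        for marker, base, run in self.homopolymer_insertions:
            if marker not in {m for m, _ in self.markers}:
                raise SimulationError(f"homopolymer insertion names unknown marker {marker!r}")
            if base not in "ACGT" or run < 1:
                raise SimulationError("homopolymer insertions need a base in ACGT and run >= 1")
        frac, cov_dist = self.quality_profile
        if not 0 <= frac <= 1:
            raise SimulationError("quality fraction must lie in [0, 1]")
        probs = [p for _, p in cov_dist]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-9:
            raise SimulationError("coverage distribution must be a probability distribution")
        if any(c < 1 for c, _ in cov_dist):
            raise SimulationError("coverage values must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated library.

    Carries the exact sequence of every specimen x marker plus the species
    map; conflation sets, discrimination indicators, and gap statistics are
    derived by exhaustive exact set logic / Hamming counting over these
    strings, valid because all sequences of a marker share one length and
    contain no ambiguity codes.
    """

    markers: tuple[str, ...]
    species_of: dict  # specimen id -> species
    sequences: dict  # (specimen id, marker) -> sequence string

    @property
    def specimens(self) -> list[str]:
        return sorted(self.species_of)

    @property
    def species(self) -> list[str]:
        return sorted(set(self.species_of.values()))

    # -- identification truth (exact-match set logic) ----------------------

    def _match_sets(self, marker_set: Sequence[str]) -> dict[str, frozenset]:
        """Specimen -> species returned by a minimal-distance query.

        With every query present in the reference, the minimal distance is
        zero (self-match) and the returned set is exactly the species owning
        an identical sequence at every marker of the set.
        """
        out = {}
        for sid in self.specimens:
            sets = []
            for m in marker_set:
                seq = self.sequences[(sid, m)]
                sets.append(
                    frozenset(
                        self.species_of[other]
                        for other in self.specimens
                        if self.sequences[(other, m)] == seq
                    )
                )
            out[sid] = frozenset.intersection(*sets)
        return out

    def expected_conflation(self, marker_set: Sequence[str]) -> dict[str, set]:
        """Species -> set of other species any of its specimens conflates with."""
        matches = self._match_sets(marker_set)
        conf: dict[str, set] = {sp: set() for sp in self.species}
        for sid, returned in matches.items():
            sp = self.species_of[sid]
            conf[sp] |= set(returned) - {sp}
        return conf

    def expected_indicators(
        self, marker_sets: Sequence[Sequence[str]]
    ) -> dict[str, dict[str, str]]:
        """Species -> {marker-set label -> '+'/'-'} under the all-queries rule."""
        out: dict[str, dict[str, str]] = {sp: {} for sp in self.species}
        for mset in marker_sets:
            label = "+".join(mset)
            conf = self.expected_conflation(mset)
            for sp in self.species:
                out[sp][label] = "+" if not conf[sp] else "-"
        return out

    # -- gap truth (Hamming distances on equal-length strings) -------------

    def _pooled_distance(self, a: str, b: str, marker_set: Sequence[str]) -> float:
        diffs = cols = 0
        for m in marker_set:
            sa, sb = self.sequences[(a, m)], self.sequences[(b, m)]
            diffs += sum(x != y for x, y in zip(sa, sb))
            cols += len(sa)
        return diffs / cols

    def expected_gap(
        self, marker_set: Sequence[str]
    ) -> dict[str, tuple[float, float, bool]]:
        """Species -> (max_intra, min_inter, gap flag), exact."""
        sids = self.specimens
        if len(self.species) < 2:
            raise SimulationError("gap truth needs at least two species")
        out = {}
        for sp in self.species:
            own = [s for s in sids if self.species_of[s] == sp]
            others = [s for s in sids if self.species_of[s] != sp]
            max_intra = max(
                (self._pooled_distance(a, b, marker_set) for a, b in itertools.combinations(own, 2)),
                default=0.0,
            )
            min_inter = min(
                self._pooled_distance(a, b, marker_set) for a in own for b in others
            )
            out[sp] = (max_intra, min_inter, min_inter > max_intra)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "markers": list(self.markers),
                "species_of": self.species_of,
                "sequences": {f"{sid}\t{m}": s for (sid, m), s in self.sequences.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        obj = json.loads(text)
        return cls(
            markers=tuple(obj["markers"]),
            species_of=obj["species_of"],
            sequences={
                tuple(k.split("\t")): v for k, v in obj["sequences"].items()
            },
        )


def expected_discrimination(
    truth: SyntheticTruth, marker_sets: Sequence[Sequence[str]]
) -> dict[str, dict[str, str]]:
    """Analytic oracle for the discrimination rule (exhaustive set logic)."""
    return truth.expected_indicators(marker_sets)


def _substitute(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute at n_sub distinct uniformly chosen sites (JC-style)."""
    out = seq.copy()
    if n_sub == 0:
        return out
    sites = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    for i in sites:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def generate_library(cfg: SyntheticConfig) -> tuple[BarcodeLibrary, SyntheticTruth]:
    """Generate a library plus its ground truth; deterministic given seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # species names spread over genera
    genera = [f"Genus{chr(ord('A') + g)}" for g in range(cfg.n_genera)]
    species_names = []
    for i in range(cfg.n_species):
        genus = genera[i % cfg.n_genera]
        species_names.append((f"{genus} sp{i:02d}", genus))

    # sharing pairs define connected components (chains like A~B, B~C put
    # all three species on one genotype); the lowest index of each component
    # is the representative whose genotype the others copy
    parent = list(range(cfg.n_species))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in cfg.shared_genotype_pairs:
        ra, rb = find(a), find(b)
        lo_r, hi_r = sorted((ra, rb))
        parent[hi_r] = lo_r
    shared_with = {
        i: find(i) for i in range(cfg.n_species) if find(i) != i
    }
    sharing_species = {i for pair in cfg.shared_genotype_pairs for i in pair}

    # per-marker species genotypes
    genotypes: dict[tuple[int, str], np.ndarray] = {}
    for name, length in cfg.markers:
        root = rng.choice(BASES, size=length)
        n_sub = round(cfg.interspecific_divergence * length)
        for attempt in range(100):
            cand = {}
            for i in range(cfg.n_species):
                if i in shared_with:
                    continue
                cand[i] = _substitute(root, n_sub, rng)
            keys = ["".join(c) for c in cand.values()]
            if cfg.interspecific_divergence == 0 or len(set(keys)) == len(keys):
                break
        else:
            raise SimulationError(
                f"could not generate distinct species genotypes for marker {name!r}"
            )
        for b, a in shared_with.items():
            cand[b] = cand[a].copy()
        for i in range(cfg.n_species):
            genotypes[(i, name)] = cand[i]

    # uniform homopolymer insertions (same position in every sequence of the marker)
    insert_at: dict[str, list[tuple[int, str]]] = {}
    for marker, base, run in cfg.homopolymer_insertions:
        length = dict(cfg.markers)[marker]
        pos = int(rng.integers(0, length + 1))
        insert_at.setdefault(marker, []).append((pos, base * run))

    lo, hi = cfg.individuals_per_species
    records: list[SequenceRecord] = []
    species_of: dict[str, str] = {}
    sequences: dict[tuple[str, str], str] = {}
    for i, (sp_name, genus) in enumerate(species_names):
        n_ind = int(rng.integers(lo, hi + 1))
        for k in range(n_ind):
            sid = f"sp{i:02d}_ind{k}"
            species_of[sid] = sp_name
            for name, length in cfg.markers:
                geno = genotypes[(i, name)]
                if cfg.intraspecific_divergence > 0 and i not in sharing_species:
                    n_sub = int(rng.binomial(length, cfg.intraspecific_divergence))
                    seq_arr = _substitute(geno, n_sub, rng)
                else:
                    seq_arr = geno
                seq = "".join(seq_arr)
                # apply insertions right-to-left so positions stay valid
                for pos, run in sorted(insert_at.get(name, []), reverse=True):
                    seq = seq[:pos] + run + seq[pos:]
                sequences[(sid, name)] = seq
                records.append(
                    SequenceRecord(
                        specimen_id=sid,
                        species=sp_name,
                        genus=genus,
                        marker=name,
                        sequence=seq,
                    )
                )

    lib = BarcodeLibrary(records, markers=[m for m, _ in cfg.markers])
    truth = SyntheticTruth(
        markers=tuple(m for m, _ in cfg.markers),
        species_of=species_of,
        sequences=sequences,
    )
    return lib, truth


def inject_quality(lib: BarcodeLibrary, cfg: SyntheticConfig) -> BarcodeLibrary:
    """Attach per-base quality values and coverage from the config profile.

    Each position gets QV >= 30 with the profile's probability (high calls
    are drawn from 30-60, low calls from 3-29); coverage is drawn from the
    profile's distribution.  Deterministic given the config seed.
    """
    frac, cov_dist = cfg.quality_profile
    if not 0 <= frac <= 1:
        raise SimulationError("quality fraction must lie in [0, 1]")
    cov_values = np.array([c for c, _ in cov_dist])
    cov_probs = np.array([p for _, p in cov_dist])
    rng = np.random.default_rng(cfg.seed + 1)
    new_records = []
    for rec in sorted(lib.records, key=lambda r: (r.specimen_id, r.marker)):
        if rec.qualities is not None:
            raise SimulationError(
                f"record {rec.specimen_id}/{rec.marker} already carries qualities"
            )
        L = len(rec.sequence)
        high = rng.random(L) < frac
        qv = np.where(high, rng.integers(30, 61, size=L), rng.integers(3, 30, size=L))
        cov = rng.choice(cov_values, size=L, p=cov_probs)
        new_records.append(
            SequenceRecord(
                specimen_id=rec.specimen_id,
                species=rec.species,
                genus=rec.genus,
                marker=rec.marker,
                sequence=rec.sequence,
                qualities=tuple(int(q) for q in qv),
                coverage=tuple(int(c) for c in cov),
                accession=rec.accession,
            )
        )
    return BarcodeLibrary(new_records, markers=lib.markers)
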