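import numpy as np
import pytest

from barcode_eval import BarcodeLibrary, SequenceRecord


def make_record(sid, species, marker, seq, genus=None, **kw):
    return SequenceRecord(
        specimen_id=sid,
        species=species,
        genus=genus or species.split()[0],
        marker=marker,
        sequence=seq,
        **kw,
    )


def library_from_specs(specs):
    """specs: list of (specimen_id, species, {marker: sequence})."""
    records = []
    for sid, species, seqs in specs:
        for marker, seq in seqs.items():
            records.append(make_record(sid, species, marker, seq))
    return BarcodeLibrary(records)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_marker_library():
    """Three species x two specimens, two markers, hand-built genotypes."""
    a = "ACGTTGCAACGGTGCATCAG"
    b = "ACGTTGCAACTGTGCATCAG"  # 1 interior diff from a
    c = "ACGTTCCAATGGTACATGAG"  # 4 interior diffs from a
    return library_from_specs(
        [
            ("s1", "Genus alpha", {"m1": a, "m2": a}),
            ("s2", "Genus alpha", {"m1": a, "m2": a}),
            ("s3", "Genus beta", {"m1": b, "m2": b}),
            ("s4", "Genus beta", {"m1": b, "m2": b}),
            ("s5", "Genus gamma", {"m1": c, "m2": c}),
        ]
    )
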