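"""Sector partitioning: coordinate arithmetic, losslessness, identity."""

import numpy as np
import pytest
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from drbstr.panel import pad_to_alignment
from drbstr.partition import (
    DEFAULT_SCHEME,
    SchemeError,
    SectorScheme,
    concat_sectors,
    pairwise_identity,
    partition_alignment,
)


def make_alignment(rows):
    return MultipleSeqAlignment(
        SeqRecord(Seq(s), id=f"r{i}", description="") for i, s in enumerate(rows)
    )


def random_alignment(rng, n_rows, n_cols):
    alphabet = np.array(list("ACGT-"))
    return make_alignment(
        "".join(alphabet[rng.integers(0, 5, size=n_cols)]) for _ in range(n_rows)
    )


def test_default_scheme_widths_match_published_arithmetic(default_panel):
    records, _, cfg = default_panel
    aln = pad_to_alignment(records, cfg)
    part = partition_alignment(aln, DEFAULT_SCHEME)
    widths = {name: part[name].get_alignment_length() for name in DEFAULT_SCHEME.names}
    assert widths == {
        "intron1": 15,
        "exon2": 270,
        "intron2A": 40,
        "intron2R": 785,
        "intron2B": 268,
    }


def test_partition_is_lossless_and_single_sector_is_identity():
    rng = np.random.default_rng(5)
    for _ in range(5):
        ncols = int(rng.integers(10, 60))
        aln = random_alignment(rng, 4, ncols)
        scheme_cols = sorted(rng.choice(np.arange(1, ncols), size=2, replace=False))
        scheme = SectorScheme(
            sectors=(
                ("a", 1, int(scheme_cols[0])),
                ("b", int(scheme_cols[0]) + 1, int(scheme_cols[1])),
                ("c", int(scheme_cols[1]) + 1, ncols),
            )
        )
        part = partition_alignment(aln, scheme)
        rebuilt = concat_sectors(part, ("a", "b", "c"))
        assert [str(r.seq) for r in rebuilt] == [str(r.seq) for r in aln]
        single = SectorScheme(sectors=(("all", 1, ncols),))
        whole = partition_alignment(aln, single)["all"]
        assert [str(r.seq) for r in whole] == [str(r.seq) for r in aln]


def test_narrow_alignment_raises_naming_sector():
    aln = random_alignment(np.random.default_rng(0), 3, 1000)
    with pytest.raises(SchemeError, match="intron2R"):
        partition_alignment(aln, DEFAULT_SCHEME)


def test_scheme_ranges_must_be_contiguous():
    with pytest.raises(SchemeError):
        SectorScheme(sectors=(("a", 1, 10), ("b", 12, 20)))
    with pytest.raises(SchemeError):
        SectorScheme(sectors=(("a", 2, 10),))


def test_concat_intron_ab_width_and_unknown_sector(default_panel):
    records, _, cfg = default_panel
    part = partition_alignment(pad_to_alignment(records, cfg), DEFAULT_SCHEME)
    ab = concat_sectors(part, ("intron2A", "intron2B"))
    assert ab.get_alignment_length() == 308  # 40 + 268 sites
    exon = concat_sectors(part, ("exon2",))
    assert [str(r.seq) for r in exon] == [str(r.seq) for r in part["exon2"]]
    with pytest.raises(SchemeError, match="nope"):
        concat_sectors(part, ("nope",))


def test_identity_identical_rows_and_simple_mismatch():
    ident = pairwise_identity(make_alignment(["ACGT", "ACGT"]))
    assert ident.mean == 100.0 and ident.se == 0.0
    ident = pairwise_identity(make_alignment(["ACGT", "ACGA"]))
    assert ident.mean == pytest.approx(75.0)


def test_identity_requires_two_rows():
    with pytest.raises(ValueError):
        pairwise_identity(make_alignment(["ACGT"]))


def test_identity_matches_counting_oracle_and_is_permutation_invariant():
    rng = np.random.default_rng(17)
    aln = random_alignment(rng, 5, 120)
    stat = pairwise_identity(aln)
    # column-by-column counting oracle over all pairs
    rows = [str(r.seq) for r in aln]
    vals = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            matches = comparable = 0
            for a, b in zip(rows[i], rows[j]):
                if a == "-" or b == "-":
                    continue
                comparable += 1
                matches += a == b
            vals.append(100.0 * matches / comparable)
    assert stat.mean == pytest.approx(np.mean(vals), abs=1e-9)
    assert stat.sd == pytest.approx(np.std(vals, ddof=1), abs=1e-9)
    shuffled = make_alignment(rows[::-1])
    assert pairwise_identity(shuffled).mean == pytest.approx(stat.mean, abs=1e-9)


def test_zero_comparable_columns_warns_and_scores_zero():
    aln = make_alignment(["A---", "---T", "ACGT"])
    with pytest.warns(UserWarning):
        stat = pairwise_identity(aln)
    assert stat.n_pairs == 3
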