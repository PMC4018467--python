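"""Sector partitioning of aligned DRB amplicons and per-sector identity.

The amplicon alignment is split by column coordinates into five named
sectors — intron 1, exon 2, the alignable intron-2 sectors A and B, and
the repeat (STR) sector between them.  Coordinates are 1-based inclusive
externally (the convention of the published partition list, "positions
16-285: 270 sites"); slicing is 0-based half-open internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment


class SchemeError(ValueError):
    """Sector scheme inconsistent with itself or with the alignment."""


@dataclass(frozen=True)
class SectorScheme:
    """Ordered named sectors with 1-based inclusive column ranges."""

    sectors: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, end in self.sectors:
            if start != prev_end + 1:
                raise SchemeError(
                    f"sector '{name}' starts at {start}, expected {prev_end + 1} "
                    "(ranges must be contiguous and increasing)"
                )
            if end < start:
                raise SchemeError(f"sector '{name}': end {end} < start {start}")
            prev_end = end

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.sectors)

    @property
    def total_columns(self) -> int:
        return self.sectors[-1][2]

    def width(self, name: str) -> int:
        for n, start, end in self.sectors:
            if n == name:
                return end - start + 1
        raise SchemeError(f"unknown sector '{name}'")

    def range(self, name: str) -> tuple[int, int]:
        for n, start, end in self.sectors:
            if n == name:
                return start, end
        raise SchemeError(f"unknown sector '{name}'")


#: The published five-sector scheme for the 1,378-column amplicon alignment.
DEFAULT_SCHEME = SectorScheme(
    sectors=(
        ("intron1", 1, 15),
        ("exon2", 16, 285),
        ("intron2A", 286, 325),
        ("intron2R", 326, 1110),
        ("intron2B", 1111, 1378),
    )
)


@dataclass(frozen=True)
class SectorPartition:
    """Per-sector sub-alignments; concatenating them restores the input."""

    scheme: SectorScheme
    sectors: dict[str, MultipleSeqAlignment]
    source_id: str = ""

    def __getitem__(self, name: str) -> MultipleSeqAlignment:
        return self.sectors[name]


@dataclass(frozen=True)
class IdentityStat:
    """Mean percent identity over all unordered row pairs of a sector."""

    sector: str
    n_pairs: int
    mean: float  # percent
    se: float
    sd: float


def partition_alignment(
    alignment: MultipleSeqAlignment, scheme: SectorScheme = DEFAULT_SCHEME
) -> SectorPartition:
    """Split an alignment into the scheme's sectors (lossless)."""
    ncol = alignment.get_alignment_length()
    if ncol < scheme.total_columns:
        for name, start, end in scheme.sectors:
            if end > ncol:
                raise SchemeError(
                    f"alignment has {ncol} columns; sector '{name}' needs columns "
                    f"{start}-{end}"
                )
    sectors = {
        name: alignment[:, start - 1 : end] for name, start, end in scheme.sectors
    }
    return SectorPartition(scheme=scheme, sectors=sectors)


def concat_sectors(partition: SectorPartition, names) -> MultipleSeqAlignment:
    """Concatenate named sectors in scheme order (e.g. intron 2 A+B)."""
    order = [n for n in partition.scheme.names if n in set(names)]
    unknown = set(names) - set(partition.scheme.names)
    if unknown:
        raise SchemeError(f"unknown sector(s): {sorted(unknown)}")
    out = partition.sectors[order[0]]
    for n in order[1:]:
        out = out + partition.sectors[n]
    return out


def pairwise_identity(
    sub_alignment: MultipleSeqAlignment, sector: str = "", gap_policy: str = "pairwise"
) -> IdentityStat:
    """Mean +- SE percent identity over all C(n,2) row pairs.

    With the default ``pairwise`` gap policy, columns where either
    sequence of a pair has a gap are excluded from both numerator and
    denominator; a pair with no comparable column scores 0% identity
    with a warning.  ``all`` compares every column, counting a
    gap/base mismatch as a difference.
    """
    n = len(sub_alignment)
    if n < 2:
        raise ValueError("pairwise identity needs at least 2 rows")
    if gap_policy not in ("pairwise", "all"):
        raise ValueError(f"unknown gap_policy '{gap_policy}'")
    mat = np.array([list(str(rec.seq).upper()) for rec in sub_alignment])
    is_gap = mat == "-"
    idents = []
    for i, j in combinations(range(n), 2):
        if gap_policy == "pairwise":
            ok = ~(is_gap[i] | is_gap[j])
            m = int(ok.sum())
            if m == 0:
                warnings.warn(
                    f"rows {i} and {j} share no comparable columns; identity set to 0"
                )
                idents.append(0.0)
                continue
            matches = int((mat[i][ok] == mat[j][ok]).sum())
            idents.append(100.0 * matches / m)
        else:
            idents.append(100.0 * float((mat[i] == mat[j]).mean()))
    arr = np.asarray(idents)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return IdentityStat(
        sector=sector,
        n_pairs=len(arr),
        mean=float(arr.mean()),
        se=sd / np.sqrt(len(arr)) if len(arr) > 1 else 0.0,
        sd=sd,
    )


def identity_report(partition: SectorPartition, combined=(("intron2A+B", ("intron2A", "intron2B")),)) -> pd.DataFrame:
    """Per-sector identity table, plus combined sectors (default A+B)."""
    rows = []
    for name in partition.scheme.names:
        st = pairwise_identity(partition[name], sector=name)
        rows.append((st.sector, st.n_pairs, st.mean, st.se, st.sd))
    for label, names in combined:
        st = pairwise_identity(concat_sectors(partition, names), sector=label)
        rows.append((st.sector, st.n_pairs, st.mean, st.se, st.sd))
    return pd.DataFrame(rows, columns=["sector", "n_pairs", "mean", "se", "sd"])
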