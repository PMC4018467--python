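"""Imperfect short-tandem-repeat detection and STR 3-sector decomposition.

Detection follows MSDB-style validity thresholds: a mononucleotide run
is valid at 12 or more units, and di- to hexanucleotide runs at 4 or
more units.  "Imperfect" search is defined here as greedy maximal
perfect runs of the same canonical motif merged across interruptions of
at most ``max_gap`` nt (default 4 = two dinucleotide units), subject to
a minimum purity; this reproduces (GA)y tracts interrupted by CT motifs
as single runs.  Coordinates are 1-based inclusive; scanning is
strand-specific; N breaks runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

MIN_MONO_DEFAULT = 12
MIN_MULTI_DEFAULT = 4
MAX_GAP_DEFAULT = 4
MIN_PURITY_DEFAULT = 0.85


@dataclass(frozen=True)
class RepeatRun:
    """One (possibly interrupted) repeat run.

    ``copies`` is real-valued span/unit_len; validity thresholds apply to
    its floor.  ``purity`` is the fraction of span bases inside perfect
    tilings of the motif; ``interruptions`` counts merged gaps.
    """

    motif: str  # canonical rotation
    unit_len: int
    start: int  # 1-based inclusive
    end: int
    copies: float
    purity: float
    interruptions: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest rotation, e.g. GA -> AG."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def _perfect_runs(seq: str, unit_len: int) -> list[tuple[int, int, str]]:
    """Maximal perfect runs (0-based [start, end) spans) of period unit_len.

    A run starting at i extends while s[j] == s[j-unit_len]; only runs of
    at least 2 full units with a primitive motif are candidates.  The
    span includes any partial trailing unit.  N breaks runs.
    """
    n = len(seq)
    runs = []
    i = 0
    while i + 2 * unit_len <= n:
        motif = seq[i : i + unit_len]
        if "N" in motif or not _is_primitive(motif):
            i += 1
            continue
        j = i + unit_len
        while j < n and seq[j] == seq[j - unit_len] and seq[j] != "N":
            j += 1
        if j - i >= 2 * unit_len:
            # maximality on the left: skip starts inside a reported run
            runs.append((i, j, canonical_rotation(motif)))
            i = j - unit_len + 1  # next candidate may share a partial tail
        else:
            i += 1
    # drop runs fully contained in an earlier run of the same canonical motif
    out = []
    for r in runs:
        if out and out[-1][2] == r[2] and r[1] <= out[-1][1]:
            continue
        out.append(r)
    return out


def _merge_runs(
    seq: str, runs: list[tuple[int, int, str]], max_gap: int
) -> list[tuple[int, int, str, int, int]]:
    """Merge same-motif runs separated by <= max_gap nt of known bases.

    Returns (start, end, motif, matched_bases, interruptions) 0-based
    half-open spans.  Gaps containing N are never bridged.
    """
    merged: list[list] = []
    by_motif: dict[str, list] = {}
    for start, end, motif in sorted(runs):
        prev = by_motif.get(motif)
        if (
            prev is not None
            and start >= prev[1]
            and start - prev[1] <= max_gap
            and "N" not in seq[prev[1] : start]
        ):
            prev[3] += end - start
            prev[4] += 1
            prev[1] = end
        else:
            cur = [start, end, motif, end - start, 0]
            merged.append(cur)
            by_motif[motif] = cur
    return [tuple(m) for m in merged]


def find_repeats(
    sequence: str,
    min_mono: int = MIN_MONO_DEFAULT,
    min_multi: int = MIN_MULTI_DEFAULT,
    max_gap: int = MAX_GAP_DEFAULT,
    min_purity: float = MIN_PURITY_DEFAULT,
) -> list[RepeatRun]:
    """Detect valid imperfect repeat runs (motif sizes 1-6), non-overlapping.

    Overlaps between candidate runs of different motifs are resolved in
    favour of the longer span; ties by smaller start, then smaller motif.
    """
    if min_mono < 1 or min_multi < 1:
        raise ValueError("thresholds must be >= 1")
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence alphabet must be within ACGTN")
    if not seq:
        return []

    candidates: list[RepeatRun] = []
    for unit_len in range(1, 7):
        perfect = _perfect_runs(seq, unit_len)
        # merged imperfect chains compete with their constituent perfect
        # runs: if a chain fails purity, a clean sub-run can still stand
        pool = _merge_runs(seq, perfect, max_gap) + [
            (s, e, m, e - s, 0) for s, e, m in perfect
        ]
        for start, end, motif, matched, interruptions in pool:
            span = end - start
            copies = span / unit_len
            purity = matched / span
            threshold = min_mono if unit_len == 1 else min_multi
            if int(copies) >= threshold and purity >= min_purity:
                candidates.append(
                    RepeatRun(
                        motif=motif,
                        unit_len=unit_len,
                        start=start + 1,
                        end=end,
                        copies=copies,
                        purity=purity,
                        interruptions=interruptions,
                    )
                )

    candidates.sort(key=lambda r: (-r.span, r.start, r.motif))
    chosen: list[RepeatRun] = []
    for run in candidates:
        if all(run.end < c.start or run.start > c.end for c in chosen):
            chosen.append(run)
    return sorted(chosen, key=lambda r: r.start)


@dataclass(frozen=True)
class StrAnnotation:
    """3-sector decomposition of an STR sector: initial / central / final."""

    id: str
    initial: tuple[int, int]  # 1-based inclusive; (s, s-1) encodes empty
    central: tuple[int, int]
    final: tuple[int, int]
    initial_seq: str
    central_seq: str
    final_seq: str
    central_motif: str
    central_copies: float
    interruptions: int
    has_central: bool

    @property
    def total_length(self) -> int:
        return len(self.initial_seq) + len(self.central_seq) + len(self.final_seq)


def decompose_str(
    sequence: str,
    runs: list[RepeatRun] | None = None,
    seq_id: str = "",
    central_motif: str = "GA",
    **scan_kwargs,
) -> StrAnnotation:
    """Split an STR sector into initial / central / final sub-sectors.

    The central sector is the detected run richest in the central motif
    (a pure (GA)y tract, or a compound run such as a (GACT)-periodic
    stretch arising from dense CT interruptions); initial and final are
    whatever flanks it.  A run qualifies when it carries at least four
    central-motif units; otherwise the whole sequence becomes the
    initial sector and ``has_central`` is False.
    """
    seq = sequence.upper()
    if runs is None:
        runs = find_repeats(seq, **scan_kwargs)
    core = None
    core_units = 0
    for run in runs:
        units = seq[run.start - 1 : run.end].count(central_motif)
        if units > core_units or (units == core_units and core and run.span > core.span):
            core, core_units = run, units
    n = len(seq)
    if core is None or core_units < 4:
        return StrAnnotation(
            id=seq_id,
            initial=(1, n),
            central=(n + 1, n),
            final=(n + 1, n),
            initial_seq=seq,
            central_seq="",
            final_seq="",
            central_motif=central_motif,
            central_copies=0.0,
            interruptions=0,
            has_central=False,
        )
    return StrAnnotation(
        id=seq_id,
        initial=(1, core.start - 1),
        central=(core.start, core.end),
        final=(core.end + 1, n),
        initial_seq=seq[: core.start - 1],
        central_seq=seq[core.start - 1 : core.end],
        final_seq=seq[core.end :],
        central_motif=central_motif,
        central_copies=core.copies if core.motif == canonical_rotation(central_motif) else float(core_units),
        interruptions=core.interruptions,
        has_central=True,
    )


def str_report(annotations: list[StrAnnotation]) -> pd.DataFrame:
    """One row per sequence: lengths of the three sectors plus run stats."""
    if not annotations:
        raise ValueError("need at least one annotation")
    rows = [
        (
            a.id,
            a.total_length,
            len(a.initial_seq),
            len(a.central_seq),
            len(a.final_seq),
            a.central_motif,
            round(a.central_copies, 2),
            a.interruptions,
            a.has_central,
        )
        for a in annotations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "total_length",
            "initial_len",
            "central_len",
            "final_len",
            "central_motif",
            "central_copies",
            "interruptions",
            "has_central",
        ],
    )


def runs_table(seq_id: str, runs: list[RepeatRun]) -> pd.DataFrame:
    rows = [
        (seq_id, r.motif, r.unit_len, r.start, r.end, round(r.copies, 2), round(r.purity, 3), r.interruptions)
        for r in runs
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "motif", "unit_len", "start", "end", "copies", "purity", "interruptions"],
    )


def runs_to_bed(seq_id: str, runs: list[RepeatRun]) -> str:
    """BED (0-based half-open) export of runs."""
    lines = [
        f"{seq_id}\t{r.start - 1}\t{r.end}\t{r.motif}x{r.copies:.1f}\t{int(r.purity * 1000)}\t+"
        for r in runs
    ]
    return "\n".join(lines) + ("\n" if lines else "")
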