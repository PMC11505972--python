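"""The merging pipeline: validate, forwardize, align adjacent pairs, splice.

The pipeline mirrors how walking sequencing is read in practice.  Signal
quality in a Sanger trace is best in the middle of the read and decays
toward the ends, and the walking primer for the next reaction is designed
200–300 bases before the end of the previous read.  The overlap between
adjacent reads therefore pairs the (degrading) tail of the previous read
with the (clean) middle of the next one.  Once the first run of ``n``
consecutive matching bases pins down the overlap, the merged sequence takes
everything up to and including the run from the previous read and
everything after the run from the next read, so each overlap is contributed
exactly once and subsequent bases come from the higher-quality read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Callable, Sequence as TypingSequence

from sangermerge.align import (
    DEFAULT_SCORING,
    MatchRun,
    PairwiseAlignment,
    ScoringScheme,
    find_n_consecutive,
    format_needle_srspair,
    global_align,
    longest_match_run,
)
from sangermerge.errors import InputSetError, InsufficientOverlapError, ParameterError, SangermergeError
from sangermerge.seqio import Direction, Read, Sequence, reverse_complement, write_sequence

DEFAULT_CONSECUTIVE_MATCHES = 50
MIN_CONSECUTIVE_MATCHES = 10
MAX_CONSECUTIVE_MATCHES = 1000


@dataclass(frozen=True)
class MergeParams:
    """Tunable parameters of a merge run.

    ``consecutive_matches`` is the length of the first uninterrupted run of
    identical aligned bases required to declare the overlap between two
    adjacent reads (the GUI-era "Consecutive Matches" knob; default 50,
    lowered to e.g. 35–40 to rescue short overlaps).
    """

    consecutive_matches: int = DEFAULT_CONSECUTIVE_MATCHES
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        n = self.consecutive_matches
        if not isinstance(n, int) or isinstance(n, bool):
            raise ParameterError(f"Consecutive Matches must be an integer (got {n!r})")
        if n < MIN_CONSECUTIVE_MATCHES or n > MAX_CONSECUTIVE_MATCHES:
            raise ParameterError(
                f"Consecutive Matches must be between {MIN_CONSECUTIVE_MATCHES} and "
                f"{MAX_CONSECUTIVE_MATCHES} (got {n}); runs shorter than "
                f"{MIN_CONSECUTIVE_MATCHES} bases are too likely to occur by chance"
            )


@dataclass(frozen=True)
class BoundaryPair:
    """Splice coordinates for one adjacent read pair.

    ``prev_cut`` is the 0-based exclusive end of the previous (forwardized)
    read's contribution; ``next_cut`` is the 0-based inclusive start of the
    next read's contribution.  Both sit at the end of the detected match
    run, so the run itself is contributed once, taken from the previous
    read.
    """

    pair_index: int
    prev_cut: int
    next_cut: int
    run: MatchRun


@dataclass
class MergeResult:
    """Everything a merge run produced, ready to write out."""

    merged: Sequence
    boundaries: list[BoundaryPair]
    forwardized: list[Sequence]
    pair_reports: list[str]
    log_text: str
    read_names: list[str] = field(default_factory=list)


def check_file_list_count(reads: TypingSequence[Read]) -> None:
    """At least two reads are required before a merge can be attempted."""
    if len(reads) < 2:
        raise InputSetError(
            f"need at least two sequence files to merge (got {len(reads)})"
        )


def check_and_convert(raw_value: str | int) -> int:
    """Parse and range-check a user-supplied Consecutive Matches value."""
    if isinstance(raw_value, bool):
        raise ParameterError(f"Consecutive Matches must be an integer (got {raw_value!r})")
    if isinstance(raw_value, int):
        n = raw_value
    else:
        text = str(raw_value).strip()
        if not re.fullmatch(r"[+-]?\d+", text):
            raise ParameterError(
                f"Consecutive Matches must be an integer between {MIN_CONSECUTIVE_MATCHES} "
                f"and {MAX_CONSECUTIVE_MATCHES} (got {raw_value!r})"
            )
        n = int(text)
    MergeParams(consecutive_matches=n)  # reuse the range check
    return n


def forwardize(reads: TypingSequence[Read]) -> list[Sequence]:
    """Convert every read to the forward strand, preserving order.

    Forward (F) reads pass through unchanged; reverse (R) reads are
    reverse-complemented so that all reads are collinear with the target.
    """
    out = []
    for read in reads:
        if read.direction == Direction.F:
            out.append(Sequence(read.sequence))
        else:
            out.append(reverse_complement(read.sequence))
    return out


def align_to_get_boundaries(
    prev: Sequence | str,
    next: Sequence | str,
    params: MergeParams,
    *,
    pair_index: int = 0,
    name_prev: str = "prev",
    name_next: str = "next",
) -> tuple[BoundaryPair, PairwiseAlignment]:
    """Align one adjacent pair and derive its splice boundary.

    Globally aligns *prev* against *next*, finds the first run of
    ``params.consecutive_matches`` consecutive identity columns, and places
    both cuts at the end of that run.  Raises
    :class:`InsufficientOverlapError` when no qualifying run exists.
    """
    n = params.consecutive_matches
    aln = global_align(prev, next, params.scoring)
    run = find_n_consecutive(aln, n)
    if run is None:
        raise InsufficientOverlapError(
            pair_index=pair_index,
            n=n,
            longest_run=longest_match_run(aln),
            name_a=name_prev,
            name_b=name_next,
        )
    boundary = BoundaryPair(pair_index=pair_index, prev_cut=run.a_end, next_cut=run.b_end, run=run)
    return boundary, aln


def splice(forward_seqs: TypingSequence[Sequence | str], boundaries: TypingSequence[BoundaryPair]) -> Sequence:
    """Stitch forwardized sequences at the given boundaries.

    The first read contributes ``[:prev_cut_0]`` (up to and including its
    overlap run), each middle read ``i`` contributes
    ``[next_cut_{i-1} : prev_cut_i]``, and the last read contributes
    ``[next_cut_last:]`` — so every overlap region appears exactly once,
    taken from the earlier read of its pair.
    """
    if len(boundaries) != len(forward_seqs) - 1:
        raise SangermergeError(
            f"boundary count ({len(boundaries)}) must be one less than sequence count ({len(forward_seqs)})"
        )
    for b, prev, nxt in zip(boundaries, forward_seqs, forward_seqs[1:]):
        if not (0 < b.prev_cut <= len(prev)) or not (0 <= b.next_cut <= len(nxt)):
            raise SangermergeError(
                f"splice boundary for pair {b.pair_index} out of range: "
                f"prev_cut={b.prev_cut} (len {len(prev)}), next_cut={b.next_cut} (len {len(nxt)})"
            )
    if not boundaries:
        return Sequence(str(forward_seqs[0]))
    for earlier, later in zip(boundaries, boundaries[1:]):
        # the shared middle read must start contributing before it stops
        if earlier.next_cut > later.prev_cut:
            raise SangermergeError(
                f"inconsistent boundaries for read {later.pair_index}: pair "
                f"{earlier.pair_index} starts its contribution at {earlier.next_cut} but pair "
                f"{later.pair_index} ends it at {later.prev_cut}; the reads are not in walking order"
            )
    parts = [str(forward_seqs[0])[: boundaries[0].prev_cut]]
    for prev_b, next_b, seq in zip(boundaries, boundaries[1:], forward_seqs[1:]):
        parts.append(str(seq)[prev_b.next_cut : next_b.prev_cut])
    parts.append(str(forward_seqs[-1])[boundaries[-1].next_cut :])
    return Sequence("".join(parts))


def merge_sanger(reads: TypingSequence[Read], params: MergeParams | None = None) -> MergeResult:
    """Run the full pipeline on an ordered read set.

    Validates the read set, forwardizes it, aligns each adjacent pair in the
    user-supplied order to locate its splice boundary, stitches the merged
    sequence, and collects per-pair srspair reports plus a timestamped log
    narrating every step.
    """
    params = params or MergeParams()
    check_file_list_count(reads)
    for read in reads:
        if not isinstance(read.direction, Direction):
            raise InputSetError(f"read {read.name!r} has no F/R direction set")

    log: list[str] = []

    def log_line(msg: str) -> None:
        log.append(f"[{datetime.now().strftime('%Y-%m-%d %H:%M:%S')}] {msg}")

    log_line(f"merge started: {len(reads)} sequence files, Consecutive Matches = {params.consecutive_matches}")
    for read in reads:
        src = read.source_path or "(in memory)"
        log_line(f"input {read.order_index}: {src} [{read.direction.value}] {len(read.sequence)} bases")
        log_line(f"  sequence: {read.sequence}")

    forward_seqs = forwardize(reads)
    for read, fwd in zip(reads, forward_seqs):
        if read.direction == Direction.R:
            log_line(f"reverse-complemented {read.name} ({len(fwd)} bases, forward strand)")

    names = [read.name for read in reads]
    boundaries: list[BoundaryPair] = []
    reports: list[str] = []
    for i, (prev, nxt) in enumerate(zip(forward_seqs, forward_seqs[1:])):
        boundary, aln = align_to_get_boundaries(
            prev, nxt, params, pair_index=i, name_prev=names[i], name_next=names[i + 1]
        )
        boundaries.append(boundary)
        reports.append(format_needle_srspair(aln, names[i], names[i + 1], params.scoring))
        log_line(
            f"pair {i} ({names[i]} vs {names[i + 1]}): alignment length {aln.alignment_length}, "
            f"identity {aln.identity_count}/{aln.alignment_length} ({aln.identity_pct:.1f}%), "
            f"gaps {aln.gap_count}"
        )
        run = boundary.run
        log_line(
            f"  first {run.n}-base match run at alignment columns [{run.aln_start}, {run.aln_end}); "
            f"cut previous at {boundary.prev_cut}, next continues from {boundary.next_cut}"
        )

    merged = splice(forward_seqs, boundaries)
    log_line(f"merged sequence length: {len(merged)}")
    log_line(f"merged sequence: {merged}")

    return MergeResult(
        merged=merged,
        boundaries=boundaries,
        forwardized=forward_seqs,
        pair_reports=reports,
        log_text="\n".join(log) + "\n",
        read_names=names,
    )


def write_run_artifacts(
    result: MergeResult,
    first_input_dir: str | Path,
    clock: Callable[[], datetime] = datetime.now,
) -> Path:
    """Write the run's process artifacts next to the first input file.

    Creates a folder named ``merged_sequence`` + timestamp (``YYYYMMDDHHMMSS``)
    inside *first_input_dir* containing the run log, one forwardized sequence
    file per read, one srspair report per adjacent pair, and the merged
    sequence (seq format).  If two runs land on the same second, a ``_1``,
    ``_2``, ... suffix keeps them from colliding.
    """
    base_dir = Path(first_input_dir)
    stamp = clock().strftime("%Y%m%d%H%M%S")
    out_dir = base_dir / f"merged_sequence{stamp}"
    suffix = 0
    while out_dir.exists():
        suffix += 1
        out_dir = base_dir / f"merged_sequence{stamp}_{suffix}"
    out_dir.mkdir(parents=True)

    (out_dir / "log.txt").write_text(result.log_text, encoding="utf-8")
    names = result.read_names or [f"read_{i}" for i in range(len(result.forwardized))]
    for name, fwd in zip(names, result.forwardized):
        write_sequence(fwd, out_dir / f"{name}_forwardized.seq", "seq")
    for (a, b), report in zip(zip(names, names[1:]), result.pair_reports):
        (out_dir / f"{a}_vs_{b}.needle").write_text(report, encoding="utf-8")
    write_sequence(result.merged, out_dir / "merged_sequence.seq", "seq")
    return out_dir
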