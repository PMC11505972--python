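"""Global pairwise alignment, consecutive-match-run detection, and reporting.

Adjacent walking reads are aligned end to end with the Needleman–Wunsch
algorithm under an affine gap model (Biopython's ``Align.PairwiseAligner``
does the dynamic programming).  The overlap between two adjacent reads is
then declared at the *first* run of ``n`` alignment columns that are all
identities — a run interrupted by even a single mismatch or gap does not
qualify.  Reports are written in the plain-text srspair layout familiar from
the EMBOSS ``needle`` program, so the per-pair artifacts are directly
comparable with needle output.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

from Bio import Align

from sangermerge.errors import ParameterError
from sangermerge.seqio import Sequence

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and affine gap penalties.

    An internal gap of length ``L`` costs ``gap_open + (L - 1) * gap_extend``:
    the opening position pays ``gap_open``, each additional position pays
    ``gap_extend``.  End gaps are free, as in EMBOSS needle's default
    (``endweight`` off) — essential here, because two adjacent walking reads
    agree only in their overlap and penalizing the long unaligned flanks
    would shred the alignment into spurious internal gaps.  The defaults
    (match +5, mismatch -4, gap open 10, gap extend 0.5) are the classic
    needle DNA settings (EDNAFULL-like), so alignments agree with what a
    needle user expects.
    """

    match_score: float = 5.0
    mismatch_score: float = -4.0
    gap_open_penalty: float = 10.0
    gap_extend_penalty: float = 0.5

    def __post_init__(self) -> None:
        if not self.match_score > self.mismatch_score:
            raise ParameterError(
                f"match score ({self.match_score}) must exceed mismatch score ({self.mismatch_score})"
            )
        if not (self.gap_open_penalty >= self.gap_extend_penalty >= 0):
            raise ParameterError(
                f"gap penalties must satisfy open >= extend >= 0 "
                f"(got open={self.gap_open_penalty}, extend={self.gap_extend_penalty})"
            )

    def to_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = self.match_score
        aligner.mismatch_score = self.mismatch_score
        aligner.open_gap_score = -self.gap_open_penalty
        aligner.extend_gap_score = -self.gap_extend_penalty
        aligner.end_gap_score = 0.0  # needle endweight=false
        return aligner


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of two sequences plus derived statistics.

    ``match_line`` uses the needle vocabulary: ``|`` identity, ``.``
    mismatch, `` `` (space) under a gap.  Comparison is case-insensitive and
    any column involving a non-ACGT character (N or an ambiguity code)
    counts as a mismatch.
    """

    gapped_a: str
    gapped_b: str
    match_line: str
    score: float

    @property
    def alignment_length(self) -> int:
        return len(self.gapped_a)

    @property
    def identity_count(self) -> int:
        return self.match_line.count("|")

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identity_count / self.alignment_length

    @property
    def gap_count(self) -> int:
        return sum(1 for a, b in zip(self.gapped_a, self.gapped_b) if a == GAP or b == GAP)

    def ungapped_a(self) -> str:
        return self.gapped_a.replace(GAP, "")

    def ungapped_b(self) -> str:
        return self.gapped_b.replace(GAP, "")


@dataclass(frozen=True)
class MatchRun:
    """The first window of ``n`` consecutive identity columns.

    ``aln_start``/``aln_end`` are 0-based half-open alignment-column
    coordinates; ``a_start``/``a_end`` and ``b_start``/``b_end`` are the
    corresponding half-open spans in the ungapped sequences.  A run of
    matches contains no gaps, so all three spans have length ``n`` and the
    sliced subsequences of A and B are character-identical.
    """

    n: int
    aln_start: int
    aln_end: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int


def _build_match_line(gapped_a: str, gapped_b: str) -> str:
    cols = []
    for a, b in zip(gapped_a, gapped_b):
        if a == GAP or b == GAP:
            cols.append(" ")
        elif a == b and a in "ACGT":
            cols.append("|")
        else:
            cols.append(".")
    return "".join(cols)


def global_align(a: Sequence | str, b: Sequence | str, scoring: ScoringScheme = DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch) alignment of *a* and *b*.

    Returns the first optimal alignment in Biopython's deterministic
    traceback order, which prefers aligning residues over opening gaps; the
    choice among co-optimal alignments is therefore reproducible run to run.
    """
    a, b = str(a), str(b)
    if not a or not b:
        raise ParameterError("global_align requires two non-empty sequences")
    aligner = scoring.to_aligner()
    result = aligner.align(a, b)
    best = result[0]
    gapped_a, gapped_b = best[0], best[1]
    return PairwiseAlignment(
        gapped_a=gapped_a,
        gapped_b=gapped_b,
        match_line=_build_match_line(gapped_a, gapped_b),
        score=best.score,
    )


def find_n_consecutive(aln: PairwiseAlignment, n: int) -> MatchRun | None:
    """Locate the leftmost window of exactly ``n`` consecutive identity columns.

    Returns ``None`` when no such window exists.  Sequence coordinates are
    derived by counting non-gap characters: a gap column advances the
    alignment coordinate but not the coordinate of the gapped row.
    """
    if n < 1:
        raise ParameterError(f"consecutive-match run length must be >= 1 (got {n})")
    run = 0
    a_pos = 0
    b_pos = 0
    # (a_pos, b_pos) before each column; remember them at potential run starts
    for col, (ca, cb, m) in enumerate(zip(aln.gapped_a, aln.gapped_b, aln.match_line)):
        if m == "|":
            run += 1
            if run == 1:
                run_a_start, run_b_start, run_col_start = a_pos, b_pos, col
        else:
            run = 0
        if ca != GAP:
            a_pos += 1
        if cb != GAP:
            b_pos += 1
        if run == n:
            return MatchRun(
                n=n,
                aln_start=run_col_start,
                aln_end=run_col_start + n,
                a_start=run_a_start,
                a_end=run_a_start + n,
                b_start=run_b_start,
                b_end=run_b_start + n,
            )
    return None


def longest_match_run(aln: PairwiseAlignment) -> int:
    """Length of the longest run of identity columns (0 if none)."""
    best = run = 0
    for m in aln.match_line:
        run = run + 1 if m == "|" else 0
        best = max(best, run)
    return best


def alignment_stats(aln: PairwiseAlignment) -> tuple[float, int, int, int]:
    """Return ``(identity_pct, identity_count, gap_count, alignment_length)``."""
    return (aln.identity_pct, aln.identity_count, aln.gap_count, aln.alignment_length)


def _stat_line(label: str, count: int, length: int) -> str:
    # the fraction field ends at a fixed column, as needle prints it
    frac = f"{count}/{length}"
    pct = 100.0 * count / length if length else 0.0
    return f"{label}{frac:>{21 - len(label)}} ({pct:4.1f}%)"


def format_needle_srspair(
    aln: PairwiseAlignment,
    name_a: str,
    name_b: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    *,
    block_width: int = 50,
    timestamp: datetime | None = None,
) -> str:
    """Render *aln* as an EMBOSS srspair-style plain-text report.

    The report has a ``#``-commented header with the sequence names, gap
    penalties, length, identity, gap and score statistics, followed by
    ``block_width``-column alignment blocks.  Row coordinates in the blocks
    are 1-based inclusive positions in the *ungapped* sequences (the needle
    convention); gap characters do not advance them.
    """
    ts = timestamp or datetime.now()
    header = [
        "########################################",
        "# Program: sangermerge",
        f"# Rundate: {ts.strftime('%a %d %b %Y %H:%M:%S')}",
        "# Align_format: srspair",
        "########################################",
        "",
        "#=======================================",
        "#",
        "# Aligned_sequences: 2",
        f"# 1: {name_a}",
        f"# 2: {name_b}",
        "# Matrix: EDNAFULL",
        f"# Gap_penalty: {scoring.gap_open_penalty}",
        f"# Extend_penalty: {scoring.gap_extend_penalty}",
        "#",
        f"# Length: {aln.alignment_length}",
        _stat_line("# Identity:", aln.identity_count, aln.alignment_length),
        _stat_line("# Gaps:", aln.gap_count, aln.alignment_length),
        f"# Score: {aln.score}",
        "#",
        "#",
        "#=======================================",
        "",
    ]

    lines = header
    a_pos = 0  # residues of A consumed so far
    b_pos = 0
    name_w = 13
    for start in range(0, aln.alignment_length, block_width):
        seg_a = aln.gapped_a[start : start + block_width]
        seg_b = aln.gapped_b[start : start + block_width]
        seg_m = aln.match_line[start : start + block_width]
        a_res = len(seg_a) - seg_a.count(GAP)
        b_res = len(seg_b) - seg_b.count(GAP)
        a_from = a_pos + 1 if a_res else a_pos
        b_from = b_pos + 1 if b_res else b_pos
        a_pos += a_res
        b_pos += b_res
        lines.append(f"{name_a[:name_w]:<{name_w}} {a_from:>6} {seg_a} {a_pos:>6}")
        lines.append(" " * (name_w + 8) + seg_m)
        lines.append(f"{name_b[:name_w]:<{name_w}} {b_from:>6} {seg_b} {b_pos:>6}")
        lines.append("")

    lines.append("#---------------------------------------")
    lines.append("#---------------------------------------")
    return "\n".join(lines) + "\n"
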