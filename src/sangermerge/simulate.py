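"""Synthetic walking-sequencing read generator with ground truth.

Emulates the geometry of primer-walking Sanger sequencing: a chain of reads
of ~700–900 bases tiled across a reference, each overlapping the previous
read by a couple of hundred bases (the walking primer is designed 200–300
bases before the end of the previous read).  Reads flagged R are stored
reverse-complemented, exactly as a reverse-strand trace's base caller would
report them.  Optional substitution errors are confined to a terminal
window of each read, modelling the signal decay at the ends of a Sanger
trace; error positions and true splice coordinates are recorded before
corruption, so tests can assert reconstruction exactly.

What this generator does *not* model: chromatogram traces and quality
scores, indel errors (available only as an opt-in mode), homopolymer
slippage, or vector/primer contamination.  Passing tests on these fixtures
demonstrate the merge logic, not base-calling robustness.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from sangermerge.errors import ParameterError
from sangermerge.seqio import Direction, Read, Sequence, reverse_complement, write_sequence

_BASES = "ACGT"


@dataclass(frozen=True)
class WalkingSimSpec:
    """Geometry and noise parameters for one simulated walking run.

    ``directions`` fixes the number of reads and their strands.
    ``overlap_range`` is inclusive on both ends.  ``end_error_rate`` is the
    per-base substitution probability applied only within the last
    ``error_window`` bases of each read (in forward orientation); the rest
    of the read is error-free, as the middle of a Sanger trace effectively
    is.  The final read is truncated at the reference end when the tiling
    overshoots, as the last walking reaction runs off the template.
    """

    reference_length: int = 2000
    read_length: int = 800
    overlap_range: tuple[int, int] = (200, 300)
    directions: tuple[Direction, ...] = (Direction.F, Direction.R, Direction.F, Direction.R)
    end_error_rate: float = 0.0
    error_window: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.overlap_range
        if not (1 <= lo <= hi):
            raise ParameterError(f"overlap_range must satisfy 1 <= min <= max (got {self.overlap_range})")
        if self.read_length <= hi:
            raise ParameterError(
                f"read_length ({self.read_length}) must exceed the maximum overlap ({hi})"
            )
        if len(self.directions) < 2:
            raise ParameterError("at least two reads are required")
        if not (0.0 <= self.end_error_rate <= 1.0):
            raise ParameterError(f"end_error_rate must be a probability (got {self.end_error_rate})")
        if self.reference_length < self.read_length:
            raise ParameterError(
                f"reference_length ({self.reference_length}) must be at least read_length ({self.read_length})"
            )


@dataclass
class SimulatedReadSet:
    """A reference, the reads sampled from it, and the ground truth.

    ``truth_boundaries[i]`` is the ``(prev_cut, next_cut)`` pair that, fed
    to :func:`sangermerge.merge.splice` on the error-free forwardized reads,
    reconstructs ``spanned_reference`` exactly.  ``error_positions[i]``
    lists the 0-based forward-orientation positions within read ``i`` where
    a substitution was injected.
    """

    reference: Sequence
    reads: list[Read]
    truth_boundaries: list[tuple[int, int]]
    read_offsets: list[int]
    error_positions: list[list[int]] = field(default_factory=list)

    @property
    def spanned_reference(self) -> Sequence:
        """The reference span covered by the read chain."""
        end = self.read_offsets[-1] + len(self.reads[-1].sequence)
        return Sequence(str(self.reference)[self.read_offsets[0] : end])


def random_reference(length: int, seed: int) -> Sequence:
    """A uniform i.i.d. random DNA sequence; deterministic under *seed*."""
    if length < 1:
        raise ParameterError(f"reference length must be >= 1 (got {length})")
    rng = random.Random(seed)
    return Sequence("".join(rng.choice(_BASES) for _ in range(length)))


def simulate_walking_reads(spec: WalkingSimSpec, reference: Sequence | None = None) -> SimulatedReadSet:
    """Sample an ordered walking read set from a (possibly fresh) reference.

    Reads tile the reference left to right; consecutive overlaps are drawn
    uniformly from ``spec.overlap_range``.  Reads flagged R are stored
    reverse-complemented.  Deterministic under ``spec.seed``.
    """
    rng = random.Random(spec.seed)
    ref = reference if reference is not None else random_reference(spec.reference_length, rng.randrange(2**31))
    ref_len = len(ref)

    starts = [0]
    overlaps = []
    for _ in range(len(spec.directions) - 1):
        ov = rng.randint(*spec.overlap_range)
        overlaps.append(ov)
        starts.append(starts[-1] + spec.read_length - ov)

    if starts[-1] >= ref_len:
        raise ParameterError(
            f"infeasible geometry: read {len(starts) - 1} would start at {starts[-1]} "
            f"but the reference has only {ref_len} bases"
        )

    forward_reads: list[str] = []
    for i, s in enumerate(starts):
        end = min(s + spec.read_length, ref_len)
        frag = str(ref)[s:end]
        prev_end = starts[i - 1] + len(forward_reads[i - 1]) if i else None
        if i and prev_end - s < 1:
            raise ParameterError(
                f"infeasible geometry: reads {i - 1} and {i} do not overlap after truncation"
            )
        forward_reads.append(frag)

    # ground truth, recorded before any error injection: the previous read
    # contributes up to its end, the next read from the end of the overlap
    truth_boundaries = []
    for i, ov in enumerate(overlaps):
        prev_end = starts[i] + len(forward_reads[i])
        true_ov = prev_end - starts[i + 1]
        truth_boundaries.append((len(forward_reads[i]), true_ov))

    error_positions: list[list[int]] = []
    corrupted: list[str] = []
    for frag in forward_reads:
        positions = []
        if spec.end_error_rate > 0:
            window_start = max(0, len(frag) - spec.error_window)
            frag_list = list(frag)
            for pos in range(window_start, len(frag)):
                if rng.random() < spec.end_error_rate:
                    frag_list[pos] = rng.choice([b for b in _BASES if b != frag_list[pos]])
                    positions.append(pos)
            frag = "".join(frag_list)
        error_positions.append(positions)
        corrupted.append(frag)

    reads = []
    for i, (frag, direction) in enumerate(zip(corrupted, spec.directions)):
        seq = Sequence(frag)
        if direction == Direction.R:
            seq = reverse_complement(seq)
        reads.append(Read(sequence=seq, direction=direction, order_index=i))

    return SimulatedReadSet(
        reference=Sequence(ref),
        reads=reads,
        truth_boundaries=truth_boundaries,
        read_offsets=starts,
        error_positions=error_positions,
    )


def write_read_files(
    readset: SimulatedReadSet, directory: str | Path, format: str = "seq"
) -> list[Path]:
    """Write one file per read plus a plain-text truth file.

    Returns the read file paths in merge order.  The truth file records the
    reference, per-read offsets, true splice boundaries, and injected error
    positions so an external run can be checked against ground truth.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for read in readset.reads:
        p = directory / f"read_{read.order_index:02d}_{read.direction.value}.{format}"
        write_sequence(read.sequence, p, format)
        read.source_path = str(p)
        paths.append(p)

    write_sequence(readset.reference, directory / "reference.seq", "seq")
    truth_lines = [f"reference\t{directory / 'reference.seq'}"]
    for read, offset, errors in zip(readset.reads, readset.read_offsets, readset.error_positions or [[]] * len(readset.reads)):
        truth_lines.append(
            f"read\t{read.order_index}\t{read.direction.value}\toffset={offset}\terrors={','.join(map(str, errors)) or '-'}"
        )
    for i, (prev_cut, next_cut) in enumerate(readset.truth_boundaries):
        truth_lines.append(f"boundary\t{i}\tprev_cut={prev_cut}\tnext_cut={next_cut}")
    (directory / "truth.tsv").write_text("\n".join(truth_lines) + "\n", encoding="utf-8")
    return paths
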