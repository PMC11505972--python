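"""Plain-text sequence I/O and strand operations.

Sanger sequencing providers hand back base calls as bare text (``.seq`` or
``.txt``) or as single-record FASTA.  All three dialects are plain text; the
only structural difference is the FASTA header line.  Sequences are
normalized on input: uppercased, with whitespace, line breaks, and digits
stripped (so text copied out of numbered sequence viewers parses cleanly).

The accepted alphabet is A/C/G/T plus N and the IUPAC ambiguity codes that
Sanger base callers emit for mixed peaks; downstream alignment treats any
non-ACGT character as a mismatch.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

from sangermerge.errors import SequenceFileError

#: Characters accepted after normalization: the four bases, N, and the IUPAC
#: ambiguity codes (R Y S W K M B D H V).
ALLOWED_ALPHABET = frozenset("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV",
    "TGCANYRSWMKVHDB",
)

_STRIP = frozenset(" \t\r\n\v\f0123456789")


class Sequence(str):
    """A normalized DNA sequence.

    Subclasses :class:`str`, so slicing, concatenation and comparison behave
    as for plain strings (and return plain strings).  Construction normalizes
    the input text — uppercases it and strips whitespace and digits — then
    validates every remaining character against :data:`ALLOWED_ALPHABET`.
    Normalization is idempotent: ``Sequence(Sequence(x)) == Sequence(x)``.
    """

    def __new__(cls, text: str, *, source: str | None = None) -> "Sequence":
        bases = normalize_bases(text, source=source)
        return super().__new__(cls, bases)

    @property
    def bases(self) -> str:
        return str(self)


def normalize_bases(text: str, *, source: str | None = None) -> str:
    """Uppercase *text*, drop whitespace and digits, validate the alphabet.

    Raises :class:`SequenceFileError` naming the offending character and its
    position (0-based, in the cleaned sequence) if a character outside the
    accepted alphabet remains.
    """
    cleaned = "".join(c for c in text if c not in _STRIP).upper()
    for pos, c in enumerate(cleaned):
        if c not in ALLOWED_ALPHABET:
            where = f" in {source}" if source else ""
            raise SequenceFileError(
                f"invalid character {c!r} at sequence position {pos}{where}; "
                f"expected one of {''.join(sorted(ALLOWED_ALPHABET))}"
            )
    return cleaned


class Direction(str, enum.Enum):
    """Sequencing direction of a read: forward (F) or reverse (R)."""

    F = "F"
    R = "R"

    @classmethod
    def parse(cls, token: str) -> "Direction":
        try:
            return cls(token.strip().upper())
        except ValueError:
            raise SequenceFileError(
                f"invalid sequencing direction {token!r}: expected 'F' (forward) or 'R' (reverse)"
            ) from None


@dataclass
class Read:
    """One input sequencing file: its sequence, direction, and ordering.

    ``order_index`` is the 0-based position in the user-supplied file order;
    the merge pipeline aligns adjacent reads in exactly this order (the order
    reflects the walking-primer design, it is never inferred).
    """

    sequence: Sequence
    direction: Direction
    source_path: str = ""
    order_index: int = 0

    @property
    def name(self) -> str:
        """Display name: the file stem, or a positional fallback."""
        if self.source_path:
            return Path(self.source_path).stem
        return f"read_{self.order_index}"


def read_sequence(path: str | Path, format: str = "auto") -> Sequence:
    """Read one DNA sequence from a plain-text file.

    ``format`` is one of ``seq``, ``fasta``, ``txt``, or ``auto``.  With
    ``auto`` the dialect is inferred from the first non-blank character: a
    leading ``>`` means FASTA, anything else is raw text (``seq``/``txt`` are
    indistinguishable).  FASTA files must contain exactly one record; its
    header is discarded and the remaining lines are concatenated.
    """
    path = Path(path)
    if format not in ("seq", "fasta", "txt", "auto"):
        raise SequenceFileError(f"unknown sequence format {format!r}: expected seq, fasta, txt, or auto")
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise SequenceFileError(f"cannot read sequence file {path}: {exc}") from exc

    stripped = text.lstrip()
    if format == "auto":
        format = "fasta" if stripped.startswith(">") else "txt"

    if format == "fasta":
        if not stripped.startswith(">"):
            raise SequenceFileError(f"{path} is not FASTA: missing '>' header line")
        body_lines = []
        n_records = 0
        for line in stripped.splitlines():
            if line.startswith(">"):
                n_records += 1
            else:
                body_lines.append(line)
        if n_records > 1:
            raise SequenceFileError(
                f"{path} contains {n_records} FASTA records; exactly one sequence per file is expected"
            )
        body = "".join(body_lines)
    else:
        body = text

    seq = Sequence(body, source=str(path))
    if len(seq) == 0:
        raise SequenceFileError(f"empty sequence in {path}: file contains no bases after normalization")
    return seq


def write_sequence(seq: Sequence | str, path: str | Path, format: str = "seq", *, line_width: int = 60) -> None:
    """Write *seq* to *path* in ``seq``, ``fasta``, or ``txt`` format.

    FASTA output gets a single header line derived from the output file stem
    and is wrapped at ``line_width`` (default 60) columns; ``seq`` and ``txt``
    output is the bare sequence with one trailing newline.  A sequence
    written in any of the three formats reads back identically.
    """
    path = Path(path)
    if format not in ("seq", "fasta", "txt"):
        raise SequenceFileError(f"unknown sequence format {format!r}: expected seq, fasta, or txt")
    s = str(seq)
    if not s:
        raise SequenceFileError(f"refusing to write an empty sequence to {path}")
    if format == "fasta":
        lines = [f">{path.stem}"]
        lines.extend(s[i : i + line_width] for i in range(0, len(s), line_width))
        payload = "\n".join(lines) + "\n"
    else:
        payload = s + "\n"
    try:
        path.write_text(payload, encoding="utf-8")
    except OSError as exc:
        raise SequenceFileError(f"cannot write sequence file {path}: {exc}") from exc


def reverse_complement(seq: Sequence | str) -> Sequence:
    """Watson–Crick complement in reversed order.

    N maps to N; IUPAC ambiguity codes map to their complementary ambiguity
    sets (R<->Y, K<->M, B<->V, D<->H; S and W are self-complementary).  The
    operation is an involution and preserves length.
    """
    return Sequence(str(seq).translate(_COMPLEMENT)[::-1])
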