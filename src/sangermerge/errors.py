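"""Exception hierarchy shared across the pipeline."""


class SangermergeError(Exception):
    """Base class for all errors raised by this package."""


class SequenceFileError(SangermergeError):
    """A sequence file could not be read, parsed, or written."""


class ParameterError(SangermergeError):
    """A user-supplied parameter is out of range or malformed."""


class InputSetError(SangermergeError):
    """The set of input reads violates the pipeline preconditions."""


class InsufficientOverlapError(SangermergeError):
    """No run of the required number of consecutive matching bases was found
    in the alignment of an adjacent read pair.

    Carries enough context (pair index, requested run length, longest run
    observed) for the caller to suggest lowering the consecutive-matches
    parameter.
    """

    def __init__(self, pair_index: int, n: int, longest_run: int, name_a: str, name_b: str):
        self.pair_index = pair_index
        self.n = n
        self.longest_run = longest_run
        self.name_a = name_a
        self.name_b = name_b
        super().__init__(
            f"insufficient overlap between adjacent reads {name_a!r} and {name_b!r} "
            f"(pair {pair_index}): no run of {n} consecutive matching bases found "
            f"(longest run observed: {longest_run}). If these reads do overlap with "
            f"fewer matching bases, lower the Consecutive Matches parameter "
            f"(e.g. down to 35 or 40) and retry."
        )
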