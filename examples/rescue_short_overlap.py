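"""Rescue a pair of reads whose overlap is shorter than the default 50 bases.

When forward and reverse walking chains meet in the middle of a gene, the
junction overlap can fall below the default Consecutive Matches threshold.
Lowering the threshold (here to 40) lets the pair merge; the result can then
be merged with the remaining reads as usual.
"""

import random

from sangermerge import InsufficientOverlapError, MergeParams, merge_sanger
from sangermerge.seqio import Direction, Read, Sequence

rng = random.Random(3)
reference = "".join(rng.choice("ACGT") for _ in range(355))
overlap = 45  # true overlap between the two reads
prev = Sequence(reference[:200])
nxt = Sequence(reference[200 - overlap :])
reads = [
    Read(sequence=prev, direction=Direction.F, order_index=0),
    Read(sequence=nxt, direction=Direction.F, order_index=1),
]

try:
    merge_sanger(reads, MergeParams(consecutive_matches=50))
except InsufficientOverlapError as exc:
    print(f"default threshold failed as expected:\n  {exc}")

result = merge_sanger(reads, MergeParams(consecutive_matches=40))
print(f"\nwith Consecutive Matches = 40: merged {len(result.merged)} bases")
print(f"merged equals the reference: {str(result.merged) == reference}")
# The 45-base overlap holds no 50-base match run, but it holds a 40-base one.
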