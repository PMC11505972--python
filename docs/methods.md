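# Methods

## The merging model

`sangermerge` assumes its inputs are a *walking chain*: reads listed in the
order the sequencing reactions were performed, each overlapping its
predecessor, with per-read strand tags (F/R) supplied by the user. The
order and strand are experimental facts; the program never infers them, and
a wrong order or tag is surfaced as an insufficient-overlap failure rather
than silently reshuffled.

The pipeline has four stages.

**Forwardization.** R reads are reverse-complemented (IUPAC ambiguity codes
complement to their partner codes; N stays N). After this every read is
collinear with the target.

**Pairwise alignment.** Each adjacent pair of forwardized reads is aligned
end to end with the Needleman–Wunsch algorithm under an affine gap model
(Biopython's `Align.PairwiseAligner` in global mode does the dynamic
programming). Scoring defaults are the EMBOSS needle DNA values — match
+5, mismatch −4, gap open 10, gap extend 0.5 (an internal gap of length
*L* costs 10 + 0.5·(L−1)) — and, crucially, **end gaps are free**, needle's
default `endweight` behaviour. Free end gaps are not a cosmetic choice:
two adjacent 800-base reads agree only over their ~200–300-base overlap,
and if the long unrelated flanks were charged for end gaps the optimal
global alignment would shred them into dozens of internal gaps chasing
chance matches, destroying the contiguous overlap run the next stage looks
for. With free end gaps the optimal alignment staggers the two reads so
the true overlap aligns column for column. Among co-optimal alignments the
first alignment in the aligner's deterministic traceback order is taken, so
reports are reproducible run to run. Comparison is case-insensitive and
any column involving a non-ACGT character (N or an ambiguity code) counts
as a mismatch — a deliberately conservative stance, since an ambiguous base
call should not anchor an overlap.

**Overlap detection.** The splice boundary is the *first* (leftmost) run of
`consecutive_matches` = *n* identity columns in the alignment. Because a
qualifying run contains no gaps, its span is the same length *n* in
alignment columns and in both ungapped reads. Taking the first rather than
the longest run keeps more of the next read — the read whose signal is
still clean at that point — in the merged product.

**Splicing.** With boundaries `(prev_cut_i, next_cut_i)` placed at the run
end in the previous and next read respectively, the merged sequence is

```
fwd[0][:prev_cut_0]
+ fwd[i][next_cut_{i-1} : prev_cut_i]   for each middle read i
+ fwd[k-1][next_cut_{k-2}:]
```

Each overlap is contributed exactly once, from the earlier read of its
pair (inside the run the two reads are identical by construction, so the
donor choice is observable only if a sequencing error falls inside the run
itself). Middle reads are cut on both sides; this is required for chains
of three or more reads because the detected run sits near the *start* of
each overlap, so the stretch between one pair's run and the previous read's
physical end must not be contributed twice. A consistency check rejects
boundary sets in which a middle read would stop contributing before it
starts — the signature of reads supplied out of walking order.

Merging is associative over the chain: merging `[r1..rk]` in one call is
byte-identical to merging `[r1, r2]` first and then the product with
`[r3..rk]`, which is exactly the rescue workflow below.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `consecutive_matches` | 50 | length (bases) of the first uninterrupted identity run that declares an overlap; accepted range 10–1000 |
| `match_score` / `mismatch_score` | +5 / −4 | per-column alignment scores |
| `gap_open_penalty` / `gap_extend_penalty` | 10 / 0.5 | affine internal gap cost; end gaps free |

The default of 50 is deliberately strict: in unrelated ~800-base random
sequences, shared runs of 50 bases essentially never occur by chance, so a
detected boundary is a real overlap. When a forward and a reverse walking
chain meet with a junction overlap shorter than 50, lowering the parameter
(typically to 35 or 40) rescues the pair; the floor of 10 exists because
much shorter shared runs do arise by chance between unrelated reads of this
length, and a spurious boundary is worse than an explicit failure.

## The synthetic walking generator

`sangermerge.simulate` emulates walking-sequencing geometry: reads of a
fixed length (default 800) tile a uniform-random reference left to right,
with each consecutive overlap drawn uniformly from a range (default
200–300, matching where walking primers are designed). Reads tagged R are
stored reverse-complemented, exactly as a reverse-strand trace's base
caller would emit them. The final read is truncated at the reference end
when the tiling overshoots — the last reaction simply runs off the insert —
which also lets a four-read chain span a 2000-base reference. Optional
substitution errors are confined to a terminal window of each read
(default 10 bases), modelling end-of-trace signal decay; error positions
and true splice coordinates are recorded before corruption, so tests can
assert reconstruction exactly.

What the generator does *not* model: chromatograms and quality scores,
indel sequencing errors (substitutions only by default; coordinate truth
would shift under indels), homopolymer slippage, and vector or primer
contamination. Green tests on these fixtures therefore demonstrate the
correctness of the merging logic — forwardization, overlap detection,
splice arithmetic, artifact layout — not robustness to base-calling
artifacts in real traces.

## Numerical and formatting choices

- Internal coordinates are uniformly 0-based half-open; the srspair report
  writer is the single place where needle's 1-based inclusive convention
  appears. A report block containing no residues of a row repeats the
  previous coordinate, as needle does.
- srspair reports use 50-column blocks, `|`/`.`/space match-line symbols,
  and `count/length (pct%)` statistics lines, so they diff cleanly against
  EMBOSS needle output on the same pair.
- Sequence files are normalized on input (uppercase; whitespace and digits
  stripped) and validated against the IUPAC alphabet with the offending
  character and position reported. FASTA output wraps at 60 columns with a
  header derived from the file stem; a round trip through any supported
  format is the identity.
- The run-artifact folder is `merged_sequence` + `YYYYMMDDHHMMSS`; two runs
  within the same second get `_1`, `_2`, … suffixes rather than
  overwriting.
- Degenerate inputs fail loudly: empty files, multi-record FASTA, fewer
  than two reads, missing strand tags, out-of-range thresholds, and
  boundary sets out of walking order all raise typed errors with the file,
  pair, or constraint named.

## Problem sizes in the test-suite

The reconstruction scenarios use 2000-base references with 800-base reads
(the realistic geometry), and the bulk property loops use a scaled
600-base/250-base geometry so that hundreds of full merges run in seconds.
The alignment oracle — exhaustive enumeration of every global alignment,
scored independently of the implementation — is exercised on 500 random
pairs of length ≤ 6, where enumeration is exact and cheap; run detection
is checked against a naive window scan on 1000 random alignments.

## Known limitations

- Reads must be supplied in walking order; the tool does not assemble
  unordered fragments (that is a contig assembler's job).
- No consensus calling: in each overlap the earlier read's bases win inside
  the run and the later read's after it, with no quality weighting.
- A sequencing error *inside* the detected run is accepted verbatim from
  the previous read; with the default n = 50 this is rare but not
  impossible in a degraded tail.
- `.ab1` chromatograms are out of scope; inputs are plain-text base calls.
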