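# sangermerge

Merge ordered, overlapping Sanger sequencing files into one full-length
sequence.

A single Sanger reaction reliably calls roughly 700+ bases, so genes longer
than that are sequenced by *primer walking*: each new sequencing primer is
designed 200–300 bases before the end of the previous read, producing a
chain of reads in which every adjacent pair overlaps. `sangermerge` stitches
such a chain back together so the result can be compared against the target
gene sequence in a single alignment. It is aimed at cloning and molecular
biology labs that receive plain-text base calls (`seq`, `fasta`, or `txt`
files) from a sequencing facility.

## Method

Given reads $r_1, \dots, r_k$ in walking order, each tagged forward (F) or
reverse (R):

1. **Forwardize** — reverse-complement every R read, so all reads are
   collinear with the target.
2. **Align adjacent pairs** — each pair $(r_i, r_{i+1})$ is aligned globally
   (Needleman–Wunsch, Biopython's `Align.PairwiseAligner`) with
   EMBOSS-needle DNA scoring: match $+5$, mismatch $-4$, affine gap penalty
   $10 + 0.5\,(L-1)$ for an internal gap of length $L$, end gaps free.
3. **Find the overlap** — the boundary is the *first* run of $n$ consecutive
   identity columns in the alignment ($n$ = "Consecutive Matches",
   default 50). A run interrupted by a single mismatch or gap does not
   qualify. The biochemical rationale: signal quality decays toward the end
   of a read, so once $n$ bases pair continuously, the previous read is in
   its degrading tail while the next read is still in its clean middle.
4. **Splice** — the previous read contributes everything up to and including
   the run; the next read contributes everything after it. Each overlap
   appears exactly once, and downstream bases always come from the
   higher-quality (later) read.

If a pair has no $n$-base run — for instance where a forward and a reverse
walking chain meet with a short junction overlap — the merge fails with an
explicit message; lowering `--matches` (e.g. to 35 or 40) rescues such
pairs, and the rescued product can be merged with the remaining reads.

## Worked example

Generate a synthetic walking run (3 reads of 800 bases over a 2000-base
reference, one read on the reverse strand) and merge it:

```bash
python examples/merge_walking_reads.py   # library API version, 4 reads
sangermerge --in read_00_F.seq:F --in read_01_R.seq:R --in read_02_F.seq:F \
            --out merged.seq --summary
```

The log streams to standard error and narrates every step:

```
merge started: 3 sequence files, Consecutive Matches = 50
input 0: demo/read_00_F.seq [F] 800 bases
...
reverse-complemented read_01_R (800 bases, forward strand)
pair 0 (read_00_F vs read_01_R): alignment length 1381, identity 219/1381 (15.9%), gaps 1162
  first 50-base match run at alignment columns [581, 631); cut previous at 631, next continues from 50
pair 1 (read_01_R vs read_02_F): alignment length 1350, identity 250/1350 (18.5%), gaps 1100
  first 50-base match run at alignment columns [550, 600); cut previous at 600, next continues from 50
merged sequence length: 1931
```

and `--summary` prints one machine-readable line on standard output:

```json
{"merged_length": 1931, "n_reads": 3, "boundaries": [{"pair": 0, "prev_cut": 631, "next_cut": 50}, {"pair": 1, "prev_cut": 600, "next_cut": 50}]}
```

Reading it: the two 800-base reads of pair 0 overlap by ~220 bases, so only
~16% of the end-to-end alignment columns are identities — the rest are the
free end gaps flanking the overlap. The first 50-base match run ends at
base 631 of read 0, so read 0 contributes bases 1–631 and read 1 continues
from base 51 of its overlap, giving a 1931-base merged sequence. A
timestamped folder `merged_sequence20261002070437/` appears next to the
first input, holding the log, each forwardized read, one needle-style
`.needle` report per adjacent pair, and the merged sequence — the full audit
trail of the merge.

Exit codes: 0 success, 2 usage error, 3 I/O error, 4 insufficient overlap.

Other examples: `examples/rescue_short_overlap.py` (the lowered-threshold
rescue) and `examples/alignment_report.py` (srspair report anatomy).

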