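"""Align two overlapping fragments and print a needle-style srspair report.

The same report is written to the run-artifact folder for every adjacent
read pair during a merge, so users can audit exactly where the overlap was
declared.
"""

from sangermerge import find_n_consecutive, format_needle_srspair, global_align

prev = "ATTGACCTGGAAACGTTGCAAGTCCAGATTTCGCAG"
nxt = "AAGTCCAGATTTCGCAGGGATCCTTAAGCTTCAATG"  # shares a 17-base overlap

aln = global_align(prev, nxt)
run = find_n_consecutive(aln, 10)
print(f"first 10-base match run: alignment columns [{run.aln_start}, {run.aln_end}), "
      f"bases [{run.a_start}, {run.a_end}) of prev and [{run.b_start}, {run.b_end}) of next\n")
print(format_needle_srspair(aln, "prev", "next"))
# The '#' header summarizes identity/gap statistics; each 50-column block
# shows both sequences with 1-based ungapped coordinates and the match line.
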