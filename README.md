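# fluopeer

Design and in-silico verification of fluorescent prime/base-editing
reporters, pegRNAs and nicking guides — plus quantification of editing
outcomes from flow-cytometry event tables and amplicon sequencing reads.

## The problem

Prime editing installs precise substitutions, insertions and deletions via a
Cas9 nickase–reverse transcriptase guided by a pegRNA (spacer + scaffold +
3′ extension, where the extension is a reverse-transcriptase template, RTT,
followed by a primer binding site, PBS). Editing efficiency varies wildly
between pegRNA designs and editor variants, so before committing a
hard-to-edit locus (e.g. in patient-derived organoids) one wants to *rank*
candidate designs cheaply. A fluorescent reporter plasmid does this: a
45–100 nt genomic window is cloned between a GFP and a Cherry cassette
(GFP–P2A–insert–P2A–Cherry, one reading frame). Pre-edit, the insert blocks
Cherry through an in-frame stop codon or a reading-frame shift; successful
editing removes the block, so Cherry/GFP signal reports editing of the
reporter with the *same* pegRNA that targets the genome.

This package implements the computational substrate of that workflow:

- **`seqcore`** — validated DNA sequences, edit specifications
  (`sub/ins/del`, 1-based coordinates), frame-aware translation and
  stop-codon scanning, editor profiles (PE2, NG-PE2, SpG-PE2, SpRY-PE2,
  ABE8e).
- **`pam_scan`** — protospacer/PAM enumeration (IUPAC patterns, both
  strands) in a −10..+4 bp window around an edit, and batch PAM censuses
  over variant flank tables.
- **`pegrna_design`** — pegRNA/epegRNA candidates under the standard
  constraints (PBS 9–15 nt with ≥5 G/C, RTT 10–20 nt, flap covering the
  edit plus downstream homology), PE3/PE3b nicking guides, and Golden Gate
  cloning oligos.
- **`reporter_design`** — reporter inserts (native or added stop/frameshift
  disruptions), six-frame base-editing reporters, SalI/Acc65I cloning
  oligos, PAM-variant panels (e.g. the 16-member 4-nt PAM panel).
- **`edit_sim`** — deterministic prime-editing simulation (site match →
  nick → PBS anneal → flap synthesis → flap resolution), base-editing
  window conversion, and restriction/ligation checking.
- **`quant`** — Cherry/GFP ratio scores and enrichment fractions from CSV
  event tables; intended-edit/indel percentages from amplicon reads within
  a ±R bp comparison window around the nick; Spearman/Pearson rank
  correlation of condition scorings.
- **`fixtures`** — seeded synthetic targets, FACS event tables and read
  sets with planted truth, so everything is testable offline.

Every design is verified end-to-end before it is returned: simulating the
prime edit on the pre-edit insert must reproduce the designed post-edit
insert exactly, and the translated construct must switch from Cherry-off to
Cherry-on.

## Worked example

Design a reporter for an A→C substitution at position 130 of a 200-nt
target, with the PAM-flexible SpRY prime editor:

```sh
fluopeer fixtures target --seed 1001 -o target.fa   # demo target
fluopeer design-reporter --target target.fa --edit sub:130:A>C --editor SpRY-PE2
```

```
window	93..152 (+)
frame_offset	0
disruption	added_frameshift@52
pre_edit	GTACTACGAAACCTAAAGCCCAACCCAGCTGAACCTCACGGTGTCTGTATAAGCTGCACAA
post_edit	GTACTACGAAACCTAAAGCCCAACCCAGCTGAACCTCCCGGTGTCTGTATAGCTGCACAA
top_oligo	TCGACCGTACTACGAAACCTAAAGCCCAACCCAGCTGAACCTCACGGTGTCTGTATAAGCTGCACAAG
bottom_oligo	GTACCTTGTGCAGCTTATACAGACACCGTGAGGTTCAGCTGGGTTGGGCTTTAGGTTTCGTAGTACGG
```

The designer chose a 60-nt window (positions 93–152 of the target, plus
strand), added a 1-nt frameshift insertion at insert position 52 — inside
the RTT-rewritten span, clear of the PAM and protospacer seed — so the
61-nt pre-edit insert reads out of frame (Cherry off). The simulated prime
edit removes the inserted base and installs A→C, giving the 60-nt in-frame,
stop-free post-edit insert (Cherry on). The oligos carry the 5′ `TCGACC`/3′
`G` (top) and 5′ `GTACC`/3′ `GG` (bottom) flanks for ligation into a
SalI/Acc65I-cut backbone.

The matching pegRNA candidates:

```sh
fluopeer design-pegrna --target target.fa --edit sub:130:A>C --editor SpRY-PE2 | head -3
```

```
spacer                pbs           rtt              pbs_len rtt_len gc_count nick_to_edit
CAACCCAGCTGAACCTCACG  GAGGTTCAGCTG  CTATACAGACACCGG  12      15      7        0
CAACCCAGCTGAACCTCACG  GAGGTTCAGCTG  TATACAGACACCGG   12      14      7        0
```

All constraint-satisfying (PBS length, G/C content, RTT reach, simulator
verification) candidates are returned, ordered by a documented heuristic
(PBS ≈ 12, mid-range RTT); there is no efficiency model. Quantification
commands (`quant-facs`, `quant-reads`, `rank`) score the resulting
experiments; e.g. `quant-reads` reports prime-editing efficiency as
100 × intended reads / above-minimum-frequency reads, with indels counted
inside a window of 2R bp around the nick.

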