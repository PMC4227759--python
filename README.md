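# paperclip

Design toolkit for **PaperClip assembly** — a multipart DNA assembly method in
which the order of parts is directed by reusable double-stranded bridging
oligonucleotides called **Clips**. The package designs the four Clip
oligonucleotides per part, plans the ligations that encode any desired part
order, inserts short intervening sequences, predicts the assembled circular
plasmid in silico, and validates designs against the method's homology and
seam constraints. It is written for synthetic biologists planning multipart
constructs and for pipeline authors who need a scriptable design layer.

## The method in brief

Every DNA part is equipped once with four oligonucleotides:

| oligo | structure | length |
|-------|-----------|--------|
| UF (upstream forward) | `seam + part[1..40]` | 43 nt |
| UR (upstream reverse) | `rc(part[1..37])` | 37 nt |
| DF (downstream forward) | last 40 nt of the part (trimmed if it starts with the seam on either strand) | 40 − t nt |
| DR (downstream reverse) | `seam' + rc(last (|DF|−3) nt)` | 40 − t nt |

where the *seam* is a 3-base sequence, `GCC` by default (`seam'` = `GGC`, its
reverse complement), and `rc` is reverse complementation. UF+UR anneal into
the *Upstream half-Clip* (5′ `GCC` overhang at the external end, 3-base 3′
overhang internally); DF+DR anneal into the *Downstream half-Clip*
(5′ `GGC` externally, a non-seam 3-base 5′ overhang internally). Ligating the
Downstream half-Clip of part *i* to the Upstream half-Clip of part *j*
through the complementary seam overhangs yields the Clip that places *j*
after *i*. A library of *n* parts therefore needs only 4*n* oligos
(+2 per part that should also be usable flipped) to assemble the parts in
*any* circular order; the UF/DR oligos double as the PCR primers that add
terminal seams to each part. Every junction of the final construct carries
the 3-base seam — `GCC` encodes an innocuous alanine in protein fusions, and
a `CTA` seam ("BrickClip") emulates BioBrick RFC10 junctions. Short elements
(RBSs, linkers, tags) are inserted between two parts as four extra oligos
forming two duplexes joined by 5-base complementary sticky ends.

Because assembly is homology-directed, constructs must not contain repeated
parts or more than 40 bases of identical sequence anywhere; the validator
screens for this (both strands, including internal and inverted repeats),
for seam-valued internal overhangs, and for reading-frame effects of seams
inside CDS fusions.

## Worked example

Three parts: a 600-bp synthetic vector backbone and the two built-in toy
parts (`TOY1`, a 60-nt ORF; `TOY2`, 44 nt, whose 40-nt suffix begins `GCC`
and therefore exercises the trimming rule).

```bash
$ paperclip design parts.fasta -o oligos.csv
wrote 12 oligos for 3 parts to oligos.csv

$ head -4 oligos.csv
oligo_name,role,part_id,sequence,length,phosphorylation_5prime,notes
TOY1_UF,UF,TOY1,GCCATGAAAGTTCTGACCGAAGATCAGCGTAAAGCACTGGCAG,43,True,also serves as PCR amplification primer
TOY1_UR,UR,TOY1,CCAGTGCTTTACGCTGATCTTCGGTCAGAACTTTCAT,37,True,
TOY1_DF,DF,TOY1,TCAGCGTAAAGCACTGGCAGAAGTTCTGCGTGAAACCTAA,40,True,

$ paperclip plan parts.fasta --order vector1,TOY1,TOY2 --name demo -o plan/
planned 3 elements, 3 clips, 3 ligation tubes → plan

$ paperclip simulate plan/
demo: 713 bp circular, 3 seam junctions → plan/demo.fasta, plan/demo.gb

$ paperclip validate plan/
Validation: PASSED (0 finding(s))

$ paperclip count plan/
Parts in library:            3
Distinct oligonucleotides:   12
  of which PCR primers:      6 (UF and DR of each part)
Distinct half-Clips:         6
Distinct Clips across plans: 3
Plan demo: clips vector1--TOY1, TOY1--TOY2, TOY2--vector1
```

`TOY1_UF` is `GCC` + the first 40 bases of TOY1 (43 nt); the predicted
circle is 600 + 60 + 44 + 3×3 = 713 bp — each of the three junctions
(including backbone↔part) contributes one 3-base `GCC` seam, annotated as a
feature in `plan/demo.gb` (circular topology). `paperclip protocol plan/`
renders the bench worksheet (half-Clips at 14 μM each, 16 °C for 1 h,
65 °C/20 min inactivation; annealing at 40 μM per oligo). Flipped parts are
written `~id` in `--order`, intervening sequences `id:IS=<seq>`.

The same workflow is available as a library (`paperclip.design_part_oligos`,
`plan_assembly`, `simulate_assembly`, `validate_design`, …); see the
docstrings and `docs/methods.md`.

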