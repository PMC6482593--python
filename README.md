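# circsplice-shift

Analysis pipeline for circular RNA (circRNA) induction in activated
endothelial cells, built for transcriptomics researchers who have
back-splice junction call tables (CIRCexplorer2- or CIRI-style) from two
conditions and want to ask how circRNA changes relate to host-gene mRNA
changes and to three biogenesis-associated genomic features.

The motivating system is human aortic endothelial cells (HAECs) activated
by the proatherogenic lysophospholipid lysophosphatidylcholine (LPC), where
a set of 77 circRNAs changes significantly and mostly *inversely* to the
host mRNA — a signature of back-splicing competing with canonical splicing.

## What it computes

Given per-condition junction tables, an mRNA fold-change table, flanking
intron sequences, a 4DGenome-schema chromatin interaction table, and
circular transcript sequences:

1. **Six-group classification.** Junctions detected in both conditions get
   a read ratio r = reads_treated/reads_control; log2 r is tested against an
   empirical 95% interval (mean ± 2·SD), and significant circRNAs are
   crossed with mRNA classes from a housekeeping-gene interval, yielding six
   groups (circ↑/↓ × mRNA↑/=/↓).
2. **Exact direction-bias test.** The imbalance of n up among u changed
   genes is scored with the exact sign-test tail
   p = Σ_{i=n..u} C(u,i) / 2^u, in exact integer arithmetic.
3. **Flanking-intron homology.** Smith–Waterman alignment of each 5′ intron
   against the reverse complement of its 3′ intron; raw scores become bit
   scores S′ = (λS − ln K)/ln 2 and pairwise E-values E = m·n·2^(−S′);
   pairs are significant at E < 1e−20, and bit scores (zero-filled) are
   compared across the six groups by ANOVA and Kruskal–Wallis.
4. **Chromatin interaction distances.** Signed anchor−partner start
   distances (positive = anchor downstream), compared across groups per
   side with Kolmogorov–Smirnov, Hodges–Lehmann, Fligner–Policello,
   Ansari–Bradley and Dwass–Steel–Critchlow–Fligner tests, plus Gaussian
   KDE summaries on an automatically selected signed transformation.
5. **Coding potential.** Circular ORF detection on the doubled sequence
   (junction-crossing and rolling-circle frames included), exact circular
   Kozak-consensus (GCCRCCATGG) scanning, IRES filtering (R-value > 1.54
   with pseudoknot), and peptide classification against a reference protein
   set (BLOSUM62, E-value bands near-perfect/partial/none).

A seeded `synthetic_data` module generates all five inputs with planted,
truth-tracked structure, so the whole pipeline is testable without any
downloads; `datasets` ships the published desk-scale summary tables (the
77 classified circRNAs, housekeeping and spliceosome fold changes, and 53
flanking-intron bit scores).

## Worked example

Desk-scale, from the packaged tables:

```python
from circsplice_shift import datasets, direction_bias_p
from circsplice_shift.diffexp import classify_circ, compare_exon_counts

table = datasets.load_circ_six_groups()
calls = [classify_circ(x, datasets.CIRC_LOG2_CI) for x in table["log2_ratio"]]
n_up, n_down = calls.count("up"), calls.count("down")
print(f"significant circRNAs: {len(table)}  up: {n_up}  down: {n_down}")
print(f"direction bias p (>= {max(n_up,n_down)} of {len(table)}): "
      f"{direction_bias_p((len(table), max(n_up, n_down))):.4f}")
anova_p, kw_p = compare_exon_counts(table)
print(f"exon-count ANOVA p: {anova_p:.3f}   Kruskal-Wallis p: {kw_p:.5f}")
```

prints

```
significant circRNAs: 77  up: 51  down: 26
direction bias p (>= 51 of 77): 0.0029
exon-count ANOVA p: 0.788   Kruskal-Wallis p: 0.46309
```

— 51 of the 77 changed circRNAs are upregulated, an imbalance unlikely
under equal chance (p = 0.0029), while exon counts do not differ across the
six groups (both tests non-significant).

End-to-end on synthetic data from the command line:

```
circsplice-shift simulate --seed 7 --out simdemo
```

```
circsplice-shift summary
========================
junction calls: control 1200, treated 1200, merged 1000
significant circRNAs: 72 (7.2% of merged)
  up 41 (56.9%), down 31 (43.1%)
group sizes: {'down_down': 10, 'down_unchanged': 19, 'down_up': 2, 'up_down': 11, 'up_unchanged': 23, 'up_up': 7}
direction bias [circ_up_vs_down]: n=41 of u=72, p=0.1444
...
flanking-intron homology: 53/77 significant (68.8%)
circular ORFs: 76/77 sequences (98.7%); Kozak hits 0; IRES pass 26
```

The merged count (1000), significant fraction (~7%), homology fraction
(68.8%) and zero Kozak background reflect the generator's defaults, which
emulate the observed data scale; every stage also writes its full table
under `simdemo/`. Subcommands `classify`, `homology`, `interactions`,
`orfs` and `run` (YAML config) expose the stages individually on real
input files.

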