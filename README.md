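# lea-profiler

Sequence-based characterisation of **late embryogenesis abundant (LEA)
proteins** — the hydrophilic, largely disordered protectants that
desiccation-tolerant plants (and seeds, nematodes, brine shrimp)
accumulate to keep membranes and proteins intact as water leaves the cell.
The package is aimed at researchers who have a translated transcriptome or
proteome plus Pfam domain annotations and want the standard desk analysis
of its LEA complement: family and subgroup classification, physicochemical
profiles, conserved-motif architectures, dehydrin segments, amphipathic
helix analysis, a radical-scavenging score, and desiccation
differential-expression summaries.

## What it computes

* **Classification** — a ≥ 100 aa length filter, then the best Pfam LEA
  domain per protein (e ≤ 1e-5) mapped to one of seven families (LEA1–LEA5,
  dehydrins, seed maturation proteins), refined to subgroups from the
  architecture of 28 built-in consensus motifs (M1.1–M7.2).
* **Physicochemical profiles** — length, Mw, pI (Bjellqvist/ProtParam
  convention), GRAVY = (1/N)·Σᵢ h(sᵢ) on the Kyte–Doolittle scale,
  residue-category percentages, and the hydrophilin flag
  (Gly > 6 % ∧ GRAVY < −1).
* **Dehydrin segments** — the K-segment grammar `KKG[_N][MF]M[DE]KIKEK`,
  the Y-segment `DEYGNP`, and merged maximal S-serine runs.
* **Amphipathicity** — the Eisenberg hydrophobic moment
  μH = |Σₙ Hₙ e^(i n δ)| / N at δ = 100°/residue on the Fauchère–Pliska
  scale (HeliQuest convention), 11-residue best-window scan, wheel-face
  segmentation and the A-type helix flag, plus a Kyte–Doolittle
  transmembrane-candidate window scan.
* **HRSA** — an additive per-residue hydroxyl-radical scavenging score
  (ordinal default table encoding the published tier order
  Trp > Phe,Leu > Ile > His > Arg > Val > Lys,Tyr,Pro > Gln,Thr,Ser >
  Glu,Ala,Gly,Asn,Asp).
* **Differential expression** — strict filtering (FDR < 0.05,
  |log2 FC| > 2) and up/down direction summaries per subgroup, with a
  packaged 88-gene desiccated-vs-hydrated reference table.
* **Synthetic data** — a seeded generator of LEA-like proteomes (seven
  families, 318 proteins by default, consensus motifs embedded, family
  GRAVY/length targets hit in expectation) so the whole pipeline is
  testable with no downloads.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

Generate a synthetic proteome under the default study conditions and run
the analysis steps:

```bash
python analysis/01_simulate.py --seed 42
python analysis/02_classify.py
python analysis/06_deg_summary.py
```

which prints

```
simulated 318 proteins (seed=42): {'LEA2': 127, 'LEA4': 96, 'DEH': 25,
  'LEA1': 24, 'LEA3': 18, 'SMP': 17, 'LEA5': 11}
classified 318 proteins; family recovery 100.0 %, subgroup recovery 100.0 %
family  count  gravy_mean  gravy_se gravy_group  pi_mean
  LEA1     24   -0.906232  0.042431           d 9.191499
  LEA2    127   -0.086558  0.013603           a 5.411182
  LEA3     18   -0.564108  0.040880           c 6.234862
  LEA4     96   -0.982747  0.020086           d 5.618786
  LEA5     11   -0.952448  0.041684           d 6.363556
   DEH     25   -1.403368  0.033842           e 6.739340
   SMP     17   -0.239742  0.035872           b 4.763481
published table: 88 genes, 76 % up / 24 % down; strict filter retains 86
  (drops the printed 1.99 and -2.00 rows)
DEH1 up: 6, DEH2 up: 1
```

Reading this: the generator honoured the per-family counts; classification
from domains + motifs recovered every truth label (the annotations are
clean by construction — see the methods note); per-family mean GRAVY lands
on the generative targets (dehydrins −1.40 ± 0.03, the hydrophobic LEA2
group near −0.09), with Tukey grouping letters separating the families;
and the packaged desiccation DEG table splits 76 % upregulated / 24 %
downregulated, with six DEH1 and one DEH2 genes up and none down.

The same steps are available as a CLI over your own files:

```bash
lea-profiler simulate --seed 42 -o outdir/
lea-profiler classify outdir/proteome.faa --domains outdir/domains.tsv -o families.tsv
lea-profiler run outdir/proteome.faa --domains outdir/domains.tsv \
    --deg-table outdir/deg.tsv -o report/
```

`lea-profiler run` writes the full bundle (families, physchem, motifs,
segments, helix, hrsa, fig1 scatter data, DEG summary, run log), each file
stamped with a hash of the threshold configuration.

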