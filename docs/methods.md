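# Methods

`lea-profiler` characterises late embryogenesis abundant (LEA) proteins from
sequence alone: family and subgroup classification, physicochemical
profiling, conserved-motif and dehydrin-segment detection, helical-wheel
amphipathicity, an additive hydroxyl-radical scavenging score, and
differential-expression summaries. This note records the models, parameter
choices and numerical conventions, and what the synthetic test material does
and does not demonstrate.

## Classification model

A protein enters the analysis if it has at least 100 residues (shorter
translated ORFs are treated as fragments). Family assignment consumes an
externally produced Pfam domain-annotation table (`protein_id`, `pfam_id`,
`evalue`); running hmmscan/BLAST is out of scope. Annotations qualify at an
HMM e-value ≤ 1e-5; among qualifying LEA domains the lowest e-value wins,
with ties broken by the canonical family order LEA1 … SMP. The default
accession map is

| Pfam | family | | Pfam | family |
|------|--------|-|------|--------|
| PF03760 | LEA1 | | PF00477 | LEA5 |
| PF03168 | LEA2 | | PF00257 | dehydrin (DEH) |
| PF03242 | LEA3 | | PF04927 | SMP |
| PF02987 | LEA4 | | | |

Published family tables occasionally swap the dehydrin/SMP rows; the map is
a plain dict argument and can be overridden per dataset.

Subgroups are refined from the motif architecture. The registry holds 28
MEME-derived consensus motifs (M1.1–M7.2). Because the discovery tool's
position weight matrices are not available, scanning matches the degenerate
consensus by per-position identity (default threshold 0.8; exact-match mode
via `min_identity=1.0`); presence/absence is the downstream signal, and hits
are taken greedily left-to-right, non-overlapping, with higher identity
winning at a shared start. Subgroup rules fire most-specific first
(e.g. the five-motif LEA2.1 set before the three-motif LEA2.2 set; DEH1's
determinant M6.3 before the generic dehydrin motifs). If no rule fires the
label is `<family>.0`. LEA5 has no published subdivision, so its motifs map
back to the family label. The SMP mapping — M7.1 only → SMP2, M7.1+M7.2 →
SMP3, M7.2 only → SMP1 — follows the published representative proteins
(an M7.1-only SMP2 member, an M7.1+M7.2 SMP3 member) and is configurable.

## Physicochemical quantities

* **GRAVY** is the arithmetic mean of Kyte–Doolittle hydropathies. The
  scale choice is validated: it reproduces the published consensus-motif
  GRAVY values to the printed three decimals for every motif whose printed
  value is internally consistent (one motif, M4.1, prints −1.617 but
  recomputes to −1.510 under every standard scale we tried; the registry
  keeps the printed value as a reference field and the engine reports the
  recomputed one).
* **Molecular weight** sums average-isotopic residue masses plus one water
  (ProtParam convention), reported in kDa.
* **pI** solves the Henderson–Hasselbalch net charge for zero using the
  Bjellqvist pK set (ProtParam's), bisection over the full pH 0–14 bracket
  to 1e-4. The Bjellqvist terminal pKs depend on the first and last
  residue, so pI is composition-determined only up to the termini —
  permutations of the interior leave it unchanged.
* **Composition categories** default to charged {D,E,K,R}, polar
  {S,T,N,Q,C,H,Y}, nonpolar {G,A,V,L,I,P,M,F,W}, aromatic {F,W,Y,H}. The
  sets deliberately overlap (published category percentages sum past 100 %,
  so the original partition cannot have been disjoint); His is excluded
  from "charged", which matches the worked 20-of-50 charged count on the
  M1.1 consensus. All sets are configurable.
* **Hydrophilin flag**: Gly > 6 % AND GRAVY < −1.0, both strict. The
  looser GRAVY < +1 bound that appears in parts of the literature admits
  nearly every LEA protein and is available by passing `gravy_max=1.0`.
* **Net formal charge** is (#K + #R) − (#D + #E); His neutral by default
  (consistent with the published +3 worked example of a helix carrying four
  Lys, one Arg, one Glu, one Asp).
* `X` (unknown) residues contribute nothing to any scored quantity and are
  excluded from composition denominators.

## Dehydrin segments

The K/Y/S segment grammars are literal: K = `KKG[_N][MF]M[DE]KIKEK` (one
optional N), Y = exact `DEYGNP`, S = maximal runs matching any of
SGSSSSSSS, TGSSSSSS, S×7, S×8 with overlapping matches merged. The
grammars are applied as written — the M6.4 consensus begins `KGL…` and so
carries no full K-segment under the strict grammar even though it is
biologically K-segment-like; tests assert the literal behaviour.

## Helical-wheel analysis

An ideal α-helix advances δ = 100° per residue (configurable for 3-10
helices). The hydrophobic moment is the Eisenberg magnitude
μH = |Σₙ Hₙ·e^(inδ)| / N on the Fauchère–Pliska octanol scale (the
HeliQuest convention); the default window is 11 residues and
`scan_best_window` maximises μH over all windows (ties → smallest start).
Faces are maximal contiguous arcs, in wheel-angle order, of hydrophobic
residues {A,V,L,I,M,F,W,C}, of {K,R}, and of {D,E}; a window showing all
three is flagged A-type. The transmembrane-candidate scan is a
deliberately simple hydropathy heuristic — windows of 19 residues with mean
Kyte–Doolittle hydropathy ≥ 1.6, greedy by descending mean — a screening
aid, not a topology predictor.

## HRSA score

The protein score is the sum (default; mean available) of per-residue
hydroxyl-radical scavenging rates. The measured rate constants behind the
published per-protein values are not redistributable, so the shipped table
is ordinal only: the nine published tiers (Trp > Phe,Leu > Ile > His >
Arg > Val > Lys,Tyr,Pro > Gln,Thr,Ser > Glu,Ala,Gly,Asn,Asp) carry values
9…1, and the unranked Cys and Met sit at 5.0. With this table only
rank-type statements (ordering, monotonicity) are meaningful; absolute
published score ranges are not reproducible without the measured rates and
are not claimed. A quantitative YAML table can be supplied.

## Differential expression

Tables carry log2(DL/HL) (desiccated vs hydrated leaves) and BH-adjusted
p-values. The filter is strict on both bounds: fdr < 0.05 and |log2fc| >
2 (0.005 is exposed for the stricter convention some pipelines use).
Direction summaries count log2fc > 0 as up and < 0 as down; zero is
counted neither and warned about. Report percentages use round-half-up.
The packaged 88-gene reference table is a verbatim transcription; two of
its printed rows (1.99 and −2.00) fail the strict threshold and are
dropped by the filter — the discrepancy is preserved, not corrected.

## Synthetic data

The generator emulates the study conditions: seven families with counts
24/127/18/96/11/25/17 (318 proteins), truncated-normal lengths with the
published family means and SD = SE·√n, i.i.d. background residues, and the
family's consensus motifs embedded verbatim at non-overlapping random
positions (LEA1: M1.1+M1.2; LEA2: M2.1+M2.2+M2.6; LEA3: M3.1+M3.2; LEA4:
M4.1+M4.2; LEA5: M5.1+M5.2; DEH: M6.1+M6.2+M6.3; SMP: M7.1). Each record
is annotated with its true family's accession at e-value 1e-10.

Background compositions are solved deterministically at
profile-construction time: a hand-set base composition expressing the
family's described residue character is mixed with a hydrophobic or
hydrophilic adjuster so that the whole protein — background plus the
expected motif footprint at the family's mean length — hits the published
family GRAVY mean exactly in expectation (GRAVY is linear in the mixture
weight, so the solve is closed-form). Sampled cohorts land within a few
hundredths of the targets (e.g. dehydrin mean GRAVY ≈ −1.39 to −1.46 over
200 draws against the −1.40 target).

The generator does **not** emulate positional dependence, paralogy, motif
degeneracy, annotation noise, or length/pI correlation structure. A 100 %
family-recovery result on this material therefore demonstrates that the
classification plumbing is correct, not that the pipeline is robust to
noisy real annotations. Synthetic DEG tables assign directions by count
rounding (requested fractions are exact up to integers), magnitudes
|N(5,2)|+2 up, −(|N(2,1)|+2) down, N(0,0.5) null, FDR uniform (0,0.01) for
non-null and (0,1) for null rows.

All randomness flows from one `numpy` Generator per dataset, seeded
explicitly; identical seeds give byte-identical outputs.

## Problem sizes and numerical conventions

Tests and the acceptance script run on desk-scale problems chosen to keep
estimates stable: 318-protein proteomes for recovery checks, 200-protein
cohorts for composition means, 100 random windows for the moment oracle,
20 random 100-mers for the pI oracle. Coordinates are 0-based half-open
internally and 1-based inclusive in report tables. Report rounding: three
decimals for GRAVY, one for pI/Mw/percentages. Tukey grouping letters use
statsmodels' pairwise HSD with a greedy compact-letter-display insertion;
NaN p-values (zero pooled variance between identical groups) are treated
as not significant; families with fewer than two members are excluded from
the post hoc and report their SE as missing.

## Known limitations

* Motif scanning by consensus identity is blunter than PWM scoring; the
  0.8 threshold was chosen for presence/absence robustness, not site-level
  accuracy.
* The ordinal HRSA table supports only rank comparisons.
* The TMH scan has no evidence model and will flag any sufficiently
  hydrophobic stretch.
* Subgroup labels for proteins whose motif content matches no rule fall
  back to `<family>.0` rather than attempting nearest-rule assignment.
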