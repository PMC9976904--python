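# agmotif

Quantitative analyses around purine-rich 5'UTR motifs and the DEAD-box
helicase eIF4A1: where AG-rich (R10) motifs sit in transcripts, whether RNA
structure changes locally downstream of them when the helicase is
inhibited, which proteins' translation rates depend on the helicase, and
the in-vitro enzymology of the helicase itself. Every stage ships with a
seeded synthetic-data generator and truth table, so the full pipeline runs
and is testable without any external downloads.

## Who this is for

RNA biologists and computational groups analysing

* **DMS/Structure-seq reactivity** (two-line "react" files, one value per
  nucleotide, `NA` at G/T positions) around sequence motifs,
* **TMT pulsed-SILAC** proteomics time courses for translation-rate
  kinetics, and
* **helicase enzymology** curves (unwinding, ATPase, binding titrations,
  subunit-mixing experiments, AUC, luciferase reporters).

## The models

**Motif windows.** R10 motifs are 10-nt windows of 100% purine ({A,G})
with at most 7 of any one base (excluding near-homopolymers), resolved
non-overlapping by a greedy left-to-right scan, and kept only when ≥ 50 nt
from their region's boundaries. DMS reactivity reads out
single-strandedness at A/C, so for 20-nt windows at 31–50 nt up/downstream
of each motif the change ΔDMS = mean(treated) − mean(control) classifies
the window: ΔDMS < 0 is a *gain* of structure, > 0 a *loss*. Motif windows
are compared with matched random windows (20-nt sliding grid, 10-nt step,
same edge constraints, same count per transcript) by a paired two-sided
Wilcoxon test.

**Translation rates.** With a heavy-label pulse, the fraction heavy
F_H = I_heavy/(I_heavy + I_light) follows first-order labelling kinetics;
its linearisation ln F_H = k·t + offset is fitted by OLS to give the
apparent translation rate k (per hour) with an F-test against k = 0.
Proteins with slope p ≥ 0.1 in either condition are removed; the per-protein
rate difference is z-tested from the two slope standard errors and BH FDRs
computed across proteins: FDR < 0.1 ⇒ helicase-dependent, FDR > 0.7 ⇒
independent.

**Enzymology.** Unwinding progress F(t) = A(1 − e^(−k·t)) (initial rate
A·k); Hill titrations y = y_max·cʰ/(K₁/₂ʰ + cʰ); single-exponential decay
half-lives ln2/k; ATPase rate −slope(A340)/ε with ε(NADH) = 0.62 mM⁻¹;
relative FRET F₆₆₅/(F₅₆₅ + F₆₆₅); subunit poisoning activity = (1 − f)ⁿ
against the noncooperative line x + y = 1; AUC partial specific volume
ṽ = (n·M_P·ṽ_P + M_R·ṽ_R)/(n·M_P + M_R); reporter translation rates as
maximum sliding-window slopes (in vitro) or the slope of FL/RL vs time (in
cells); and total cellular mRNA concentration copies/(N_A·V).

## Worked example

```sh
python examples/structure_windows.py
```

prints (seed 7):

```
filter counts: {'transcripts_input': 100, 'transcripts_selected': 100,
'motifs_5UTR': 103, 'motifs_CDS': 223, 'motifs_3UTR': 106, 'random_windows': 432}
region       side      p_value  median_motif  median_random  n_motif  n_random
  5UTR   upstream 4.368859e-01     -0.001192      -0.003103      101       101
  5UTR downstream 9.543256e-17     -0.160134      -0.030664      103       103
  ...
```

The downstream motif windows show a median ΔDMS near −0.15 (the planted
structure gain) at p ≈ 1e-16, while upstream windows and random windows
stay flat — the asymmetric, localized structure change the analysis is
built to detect. `examples/psilac_rates.py` and
`examples/enzymology_fits.py` do the same for the other two arms, e.g.

```
titration: K_1/2 2.00 uM, Hill h 2.00 (h > 1: cooperative, multiple subunits)
wt/inactive mixing: best model poisoned_n with n = 3 subunits per active complex
total cellular mRNA concentration: 0.205 uM (< 1 uM)
```

## Command line

A thin CLI wraps the library: `agmotif simulate
transcriptome|reactivity|psilac|enzymology --seed N --out DIR`, `agmotif
structure run`, `agmotif psilac run`, and `agmotif enzymology
fit-progress|fit-hill|fit-mixing|atpase-rate|reporter-rate`. Every pipeline
run writes a `manifest.json` with the config hash, seed, input checksums
and per-stage filter counts.

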