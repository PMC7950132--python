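# hdxquant

Differential hydrogen–deuterium exchange mass spectrometry (HDX-MS) analysis
and diGly-remnant ubiquitylation-site quantification, packaged with a forward
simulator of amide-exchange kinetics and isotope envelopes so that every stage
of the analysis can be validated against known ground truth without any
instrument data.

## Who this is for

Structural mass spectrometrists and method developers who need a transparent,
scriptable reimplementation of the standard peptide-level HDX-MS workflow
(centroid uptake → back-exchange correction → replicate statistics →
differential state calls → residue-level maps), and of label-free
ubiquitylation-site occupancy from diGly evidence tables — plus a simulator
that produces realistic synthetic inputs for both.

## The model and statistics

**Exchange kinetics (EX2).** Each backbone amide exchanges with solvent
deuterium at an observed rate *k*<sub>obs</sub> = *k*<sub>int</sub>/*P*, where
*k*<sub>int</sub> is the sequence-, pD- and temperature-dependent intrinsic
rate of the unstructured chain (computed from the standard poly-DL-alanine
reference factors) and *P* ≥ 1 is the protection factor. The deuterated
fraction after labeling time *t* is 1 − e<sup>−*k*<sub>obs</sub>*t*</sup>.

**The observable.** A peptide's deuterium uptake is the shift of its isotope
envelope's intensity-weighted mean mass (centroid) relative to the
undeuterated control, divided by the H→D mass difference (1.00628 Da):

> D = (centroid<sub>deut</sub> − centroid<sub>control</sub>) / 1.00628

The simulator builds natural envelopes from elemental composition and
convolves an exact Poisson-binomial deuteron-count distribution onto them, so
the round trip D = Σ per-amide fractions holds to numerical precision.

**Back exchange.** A single global factor *b*, estimated as one minus the mean
fractional uptake of fully disordered terminal peptides at the longest
timepoint (120 s); corrected uptake = raw / (1 − *b*), clipped into
[0, max exchangeable amides].

**Differential calls.** Per shared peptide: a two-way ANOVA (state × exposure)
on replicate uptake plus a pooled-variance t-test at each timepoint
(15/30/45/60/120 s, three technical replicates, mean ± SEM). A peptide is
called increased/decreased only when the ANOVA state effect *and* at least one
per-timepoint t-test fall below α = 0.05; verdicts are projected onto residues
by consensus over covering peptides.

**diGly occupancy.** Trypsin leaves a 114.04 Da Gly-Gly remnant on a
ubiquitylated lysine. After score filtering (−10 log P > 15), occupancy of
lysine K is

> occ(K) = Σ area(peptides with digly at K) / Σ area(peptides covering K),

with the denominator counting every covering peptide (exhaustive acetylation
blocks unmodified lysines, so each covered lysine carries either acetyl or
digly). DiGly positions on ubiquitin itself report chain linkage (K48, K63,
…).

## Worked example

Define a 60-residue protein with a protected core (log₁₀ *P* = 2 over residues
15–45) in two states; in the `bound` state residues 25–35 lose one log unit of
protection. Save as `demo.yml`:

```yaml
sequence: MKTWQENVRLAGDSIKPLHEAFYQCGTNDVLSRIMEAWKHGLPDTVQNSYRCFELIKAGD
states:
  - name: apo
    protection:
      - {start: 15, end: 45, log10_P: 2.0}
  - name: bound
    protection:
      - {start: 15, end: 45, log10_P: 2.0}
      - {start: 25, end: 35, log10_P: 1.0}
back_exchange_fraction: 0.25
centroid_noise_sd: 0.02
```

```sh
hdxquant simulate --config demo.yml --seed 7 --out-dir demo
hdxquant compare demo/state_data.csv --state-a apo --state-b bound --out-dir demo
```

prints

```
wrote 396 centroid rows for 11 peptides (100% coverage)
estimated back-exchange factor: 25.0%
11 peptides compared, 3 significant at alpha=0.05
```

The estimator recovers the simulated 25% back-exchange factor from the
disordered termini, and `demo/residue_map.csv` classifies residues 21–40 as
increased — the true deprotected region 25–35 plus at most one peptide
overhang at each edge, which is the resolution limit of 10-residue peptides
with 5-residue overlap.

For occupancy quantification, simulate an evidence table with true
occupancies {K45: 0.6, K101: 0.2, K107: 0.2, K381: 0.6} and run:

```sh
hdxquant digly demo/evidence.csv --fasta demo/protein.fasta --out-dir demo
```

```
4 lysines, 4 with digly evidence
  K45: occupancy 0.577 (50 evidence rows)
  K101: occupancy 0.217 (84 evidence rows)
  K107: occupancy 0.174 (83 evidence rows)
  K381: occupancy 0.561 (50 evidence rows)
```

Each recovered area ratio lies within ±0.05 of its true occupancy at 50
evidence rows per site under ~30% area noise.

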