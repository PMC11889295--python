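# editqc

Post-editing quality control for genome-edited crops.

Before a CRISPR/Cas9-edited line can move toward field trials, a breeder has
to show three things: that the transformation construct (T-DNA and vector
backbone) is gone from the genome, that the guide did not cut anywhere it
should not have, and that the intended mutation — and nothing else — explains
the phenotype. `editqc` implements that workflow as a reusable library and
command-line tool, built around the case of a hull-less (*nud*) barley line
derived from the malting line DH120366:

* **k-mer transgene screen** (`editqc.kmer`) — alignment-free detection of
  construct sequence in whole-genome shotgun reads, with per-position
  statistics against a wild-type control, FDR control, and a
  present / absent / residual-fragments verdict.
* **Off-target scan** (`editqc.offtarget`) — exhaustive scan of a genome for
  protospacer matches within a mismatch budget under a PAM constraint
  (default SpCas9 NGG).
* **Target-site genotyping** (`editqc.genotype`) — global affine-gap
  alignment of amplicon sequences, VCF-style left-aligned indel calls, and
  zygosity classification (wild type / homozygous / heterozygous / biallelic
  / mosaic).
* **Trait statistics** (`editqc.traits`) — Dunnett's many-to-one comparisons
  computed directly from published-style group summaries (n, mean, SD),
  percent trait changes, and germination rates.
* **Synthetic data** (`editqc.simulate`) — generators for host genomes,
  constructs with host-homologous and low-complexity decoy segments, editing
  outcomes, and error-bearing reads, so the whole pipeline is testable
  without downloads.

## The statistics at the core

**Screen.** Every k-mer (k = 20) of every read is matched against the
construct on both strands; each match increments the k-mer's *start
position(s)* on the construct, so an f-bp leftover fragment lights up exactly
f − k + 1 consecutive positions. For sample counts c_s and control counts
c_c at a position, with total examined read k-mers T_s and T_c:

* positions the control covers are tested with the exact conditional
  binomial — given m = c_s + c_c, p = P(X ≥ c_s), X ~ Binom(m, T_s/(T_s+T_c));
* positions the control never touches (no control counts within ±k) are
  tested against the control's estimated background rate b with a Poisson
  tail, p = P(Pois(b·T_s/T_c) ≥ c_s).

p-values are Benjamini–Hochberg adjusted across all L − k + 1 positions, and
maximal runs with q below the FDR level (default 1%) are called. Runs driven
by sequence the host shares with the construct — host-derived promoter
segments, low-complexity C-rich tracts — are masked via a control-elevation
test and a sequence-entropy filter rather than reported as evidence.

**Dunnett.** For treatments i = 1..K sharing a control, t_i = (m_i − m_0) /
(s·√(1/n_i + 1/n_0)) with the pooled variance s², and the two-sided adjusted
p-value is P(max_j |T_j| ≥ |t_i|) under the K-variate t with df = Σ(n_i − 1)
and correlations ρ_ij = λ_i λ_j, λ_i = √(n_i/(n_i+n_0)), evaluated by
deterministic Gauss–Legendre quadrature over the shared control variate and
the pooled scale (accurate below 1e−6).

## Worked example

The package bundles the trait summaries of the naked-barley experiment
(wild-type DH120366 against the *nud* 8-3 and 8-10 mutant lines):

```bash
editqc traits \
  --summaries src/editqc/data/nud_trait_summaries.tsv \
  --control DH120366 --out traits_out.tsv
```

prints

```
                  trait    label  n  mean   sd         t  df  p_adjusted significance
         culm_length_cm  nud_8-3 20 85.03 4.16  0.739782  82    0.677174         n.s.
         culm_length_cm nud_8-10 40 84.18 5.15  0.107691  82    0.991385         n.s.
thousand_grain_weight_g  nud_8-3  4 34.20 3.02 -0.736556  14    0.685736         n.s.
thousand_grain_weight_g nud_8-10  8 33.05 2.47 -1.599576  14    0.222067         n.s.
hectoliter_weight_kg_hl  nud_8-3  4 80.01 1.71 11.210474  10    0.000001          ***
hectoliter_weight_kg_hl nud_8-10  4 76.85 1.28  8.911635  10    0.000009          ***
```

Growth traits are indistinguishable from the wild type, while hectoliter
(test) weight rises sharply in both hull-less mutants — a 23.85% and 18.96%
increase over the control mean (`editqc.traits.percent_change`), as expected
when the hull no longer occupies grain volume.

A full synthetic screen runs end to end from one scenario file:

```bash
editqc simulate --scenario src/editqc/data/default_scenario.yaml --out sim/
# write a sample sheet pointing at sim/control_*.fastq.gz (negative_control)
# and sim/sample_*.fastq.gz (query), then:
editqc screen --construct sim/construct.fasta --features sim/features.tsv \
  --sample-sheet sheet.tsv --out screen/
```

For the default scenario (full T-DNA insertion, 30× coverage) the query's
`*.call.json` reports `"status": "present"` with T-DNA coverage near 1.0,
while `region_averages.tsv` shows the characteristic pattern: high mean
counts per T-DNA position in the edited sample, near-zero on the backbone,
and background-level counts in the wild-type control.

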