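# Methods

This note documents the models, parameter choices and numerical decisions
behind `editqc`, and what the synthetic-data tests do and do not establish
about real data.

## k-mer transgene screen

### Counting model

The screen is alignment-free. Every length-k window of the transformation
construct (k = 20 by default) is indexed by its 1-based start position;
duplicated k-mers map to all of their positions, and both orientations are
held in a packed lookup table so a read k-mer matches if either it or its
reverse complement occurs in the construct (a palindromic k-mer is stored
once per position and therefore counted once). Each matching read k-mer
occurrence increments the construct start position(s) of the matched k-mer.

Counting *start positions* rather than covered bases is deliberate: it makes
the per-position average directly comparable to read depth, and it makes an
f-bp residual fragment light up exactly f − k + 1 consecutive positions, so
run geometry reads off fragment length as `matched_length = run_length + k − 1`.
A 20-bp leftover fragment is one significant position (matched length 20); a
21-bp fragment is two (matched length 21). Multi-mapping k-mers (repeats
within the construct) increment all their positions, which inflates counts
inside repeats; this is documented behaviour, not corrected. Read k-mers
containing non-ACGT bases are skipped and tallied, as are reads shorter
than k. Mates of a pair are treated as independent reads — the method uses
k-mer content only.

At sequencing depth d with read length R, the expected count at a
single-copy position is d·(R−k+1)/R·(1−e)^k for per-base error rate e
(≈ 0.873·d at R = 150, k = 20, e = 0.005); the unit tests verify simulated
tracks against this expectation.

### Per-position test

Counts at one position in a query sample (c_s, total examined read k-mers
T_s) are compared against a transgene-free negative control (c_c, T_c) with
a one-sided, exact, depth-normalized test:

* **Control-covered positions** — the conditional binomial: given
  m = c_s + c_c, p = P(X ≥ c_s) with X ~ Binom(m, T_s/(T_s+T_c)). This is
  the standard exact two-Poisson rate comparison; it is calibrated at every
  m and needs no background parameter.
* **Control-uncovered positions** — the conditional test cannot reject below
  (1/2)^{c_s} when c_c = 0, which puts single-copy short fragments at
  moderate depth (counts ~8–16) out of reach once the Benjamini–Hochberg
  threshold over ~19,000 positions (~1e−6) is applied. Positions where the
  control has *no counts anywhere within ±k* are therefore tested against
  the control's background rate b: p = P(Pois(b·T_s/T_c) ≥ c_s). Requiring
  the whole ±k neighbourhood to be empty matters: adjacent start positions
  share reads, so a zero count inside a control-covered block is a sampling
  fluctuation and must not be handed to the high-power branch (branching on
  the position's own count alone produces false positives inside
  host-homologous blocks at a rate of roughly one per three genome-scale
  screens).

The background b is the iteratively trimmed mean of the control track:
positions above the 99.9% Poisson quantile at the current estimate are
dropped and the mean re-taken until stable. A fixed-percentile trim is not
robust here because host-homologous construct segments can occupy well over
1% of positions. b is floored at 0.05 counts/position — far above the rate
at which sequencing-error k-mers spuriously match the construct at the
scales involved (~1e−5 per position), and far below real shotgun
backgrounds (~0.5–1 counts/position), where the data-driven estimate
dominates anyway.

The non-randomized p-values are conservative (as any discrete exact test's
are). The randomized (PIT) form `P(X > c) + U·P(X = c)` of the conditional
test is exactly Uniform(0,1) under the null, which is what the calibration
tests check; the hybrid's branch selection makes its PIT sub-uniform (never
anti-conservative), which is asserted separately.

### FDR, runs, masking, classification

p-values are Benjamini–Hochberg adjusted across all L − k + 1 positions and
maximal runs of q < α (default α = 0.01, the screen's 1% FDR level) are
called. Two mask sources move runs from evidence to `masked_runs`:

* **Control elevation** — the construct legitimately shares sequence with
  the host (host-derived promoter segments; common low-complexity motifs),
  so host reads light those positions up in every sample including the
  negative control. A position is flagged when its control count exceeds
  the 99.9% Poisson quantile at the background rate b (threshold floored at
  2 counts), and flags are dilated by ±k so coverage fluctuations inside an
  elevated block do not punch holes in the mask.
* **Low complexity** — construct windows with base-composition Shannon
  entropy below 1.0 bits (a random window sits near 2 bits; C-rich tracts
  of the kind that produce classic k-mer false positives sit near 0.8).

A run is masked when more than half of its positions carry a flag. The
final call is: `absent` with no unmasked runs; `present` when the matched
segments of unmasked runs (run start to run end + k − 1) cover more than
50% of T-DNA bases; `residual_fragments` when every unmasked run has
matched length ≤ 2k + 5 (compatible with a leftover fragment, not an
integrated cassette); `inconclusive` otherwise. Coverage is measured in
matched bases rather than significant start positions because at moderate
depth only part of the starts clear the FDR cut even over a fully present
T-DNA, while their k-mer windows jointly cover essentially all of it.

`marker_presence` is the in-silico analogue of marker-gene PCR (HPT, Cas9):
a feature is present when its mean count exceeds 5× the sample's
non-T-DNA background and an absolute floor of 1 count/position.

## Off-target scan

The scan is exhaustive rather than heuristic: every window on either strand
whose 3-nt PAM slot matches the IUPAC PAM pattern (N matches anything) and
whose 20-nt protospacer-equivalent lies within the Hamming budget of the
guide is reported, so no qualifying site can be missed. Mismatches are
counted over the protospacer only; PAM-less matches are not reported. A
genomic ambiguity code matches a concrete guide base when the base is in
the code's set, and a PAM pattern character when their sets intersect.
Coordinates are 1-based positions of the protospacer-equivalent 20-mer on
the plus strand; site sequences are reported in guide orientation.
Correctness is established by set-equality with a naive per-window oracle
and by strand-duality and mismatch-monotonicity properties.

## Target-site genotyping

Cas9's blunt cut is taken 3 bp 5′ of the PAM (between protospacer bases 17
and 18); reported cut offsets are informational, not enforced. Amplicons
are aligned globally under affine gaps (match +2, mismatch −4, gap open −6,
gap extend −1 — chosen so a 13-bp deletion stays one gap instead of
fragmenting), alignment scores are verified against an independent
quadratic-space Gotoh implementation, and indels are normalized to their
leftmost representation (VCF convention) so the same physical event always
yields the same call. Adjacent edits within 10 matched bases merge into one
cluster; one pure cluster yields a deletion/insertion/substitution call,
anything mixed — or more than one cluster — is `complex` with all edits
listed. Substitution-only alleles are reported as such, never folded into
wild type.

Mixed Sanger chromatograms are not deconvolved. The classifier takes
resolved per-allele sequences and works on the identity set (type, length,
sequence, anchor): one distinct non-wild-type allele is homozygous (without
wild type) or heterozygous (with it); two distinct non-wild-type alleles are
biallelic; more than two distinct alleles in one plant is a mosaic — the
signature of a chimeric regenerant, since a diploid lineage carries at most
two.

## Dunnett's test from summaries

The test is computed from (n, mean, SD) summaries because published trait
tables rarely ship raw data; a raw-data path computes summaries first and
delegates. Pooling is classical equal-variance across all groups,
df = Σ(n_i − 1). The two-sided adjusted p-value P(max_j |T_j| ≥ |t|) is an
exact K-variate t probability with product correlations λ_i λ_j,
λ_i = √(n_i/(n_i+n_0)); conditioning on the shared control variate and the
pooled scale makes the treatments independent, leaving a smooth double
integral evaluated with 160-node Gauss–Legendre rules on ranges whose
excluded tail mass is below 1e−12 — self-reported error well under 1e−6,
and adjusted p-values are reported to 6 decimals. Correctness is checked
three ways: K = 1 reduces to the two-sided pooled t (to 1e−6), agreement
with a 10⁶-draw Monte-Carlo oracle within 3 standard errors on randomized
configurations, and agreement with an independent implementation on raw
samples. Significance labels: *** / ** / * at 0.001 / 0.01 / 0.05.
Heteroscedastic variants are out of scope.

## Synthetic data

The generator emulates the structure the screen's inferences depend on:

* **Host genome** — 1 Mb of i.i.d. sequence at GC 0.44 (typical cereal
  exome-scale GC), standing in for a multi-gigabase genome. The screen's
  statistics are depth-normalized, so conclusions about calibration and
  power transfer; what does *not* transfer is the absolute number of
  repeat-driven multi-mapping positions a real 4-Gb repeat-rich genome
  would produce.
* **Construct** — 19,074 bp, T-DNA spanning 1–12,584, with HPT and Cas9
  marker features at fixed T-DNA fractions; a 2,000-bp segment copied from
  the host inside the T-DNA (emulating a host-derived promoter, the source
  of legitimate control counts); and the 21-bp C-rich tract
  `CCTCCCCCCCCCCCCCTCTCT` at 2,069–2,089, which is also planted at 25
  random host loci so that every sample — including the negative control —
  shows strong counts there, reproducing the classic false-positive
  behaviour of k-mer screens at low-complexity sequence (control counts at
  the decoy come out in the several-hundreds at ~30× depth, the right
  order for such a motif).
* **Events** — `none`; `full_insertion` (the whole T-DNA at one random
  locus); `fragment` (one copy of each requested length, default 20 and
  21 bp, drawn from T-DNA sequence away from the homology and decoy
  segments and each other). Fragment junctions are forced to break
  homology with the construct so a planted f-bp fragment matches over
  exactly f bases — otherwise a matching flank base would silently turn a
  20-bp plant into a 21-bp match.
* **Reads** — uniformly placed 150-bp reads, both strands equiprobable,
  substitution errors at 0.5% per base by default (no indel errors: at
  k = 20 they only shorten matches marginally and add nothing to screen
  realism). Read count is round(depth·L/R). Reads are generated single-end
  and written as alternating synthetic mates, since the screen ignores
  pairing. Default depth is 30×, the scale of the motivating experiment;
  the recovery tests run at 10× to demonstrate headroom.
* **Traits and amplicons** — normal per-individual draws from (label, n,
  mean, SD) specs, and amplicons built by applying explicit edit specs to
  a reference region.

Everything is bit-reproducible under a fixed seed; the command-line
`simulate` writes gzip output with a fixed header timestamp so whole output
directories are byte-identical across runs.

What passing the synthetic suite shows: calibration of the per-position
test under its null, correct run geometry and masking, full recovery of
planted present/absent/fragment outcomes at 10× with 0.5% errors, and exact
agreement of the scan and the statistics with independent oracles. What it
does not show: behaviour under real library artifacts (PCR duplicates,
coverage bias, adapter read-through), repeat-family multi-mapping at
genome scale, or chromatogram-level genotyping noise.

## Degenerate inputs and numeric edges

Empty FASTA files return empty lists with a warning; truncated FASTQ
records and sequence/quality length mismatches raise format errors carrying
the record index. Zero total read k-mers, empty T-DNA or backbone regions,
all-zero-variance Dunnett inputs, and non-positive control means are
rejected with explicit errors rather than propagating NaNs. BH inputs are
validated to [0, 1]. q-values of 0 are displayed as −log₁₀(FDR) capped at
300. Ambiguous construct windows (non-ACGT) are excluded from the index
with a warning.

## Known limitations

* The screen detects construct sequence; it does not locate insertion loci
  in the host (no split-read analysis) and does not estimate copy number.
* Fragments shorter than k are undetectable by design; fragments between k
  and ~k+3 are detectable only when depth puts their count above the
  BH threshold (single copies need roughly ≥ 8× effective coverage).
* The off-target scanner does not model bulges (guide–site indels) and does
  not score cutting activity.
* Dunnett assumes equal variances; with strongly unequal group SDs the
  pooled test can be anti-conservative for the small-variance groups.
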