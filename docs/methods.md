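# Methods

## The screening model

The screen asks, for every common SNP in a regulatory interval and every
motif in a library, two questions: *does this motif occur near the SNP at
all*, and *does swapping the SNP's alleles change how strongly the factor
would bind*. The two questions are answered with two deliberately different
statistics.

### Motif matching with exact score p-values

A position frequency matrix (PFM) of counts `c[i,b]` becomes a log2-odds
position weight matrix

    logodds[i,b] = log2( ((c[i,b] + p·bg_b) / (Σ_b c[i,b] + p)) / bg_b )

with the total pseudocount `p` (default 0.8) split across bases in
proportion to the background `bg`. The background is the scanned window's
own mononucleotide composition with a 0.01 floor per base (renormalized), so
an A/C-rich window is not trivially "enriched" for A/C-rich motifs.

A window score's p-value is **exact**, not asymptotic: the full distribution
of the motif-width word score under i.i.d. background is computed by dynamic
programming after rounding each matrix entry to an integer grid of step
1e-3 log2-odds units (the granularity is configurable; the DP is linear in
width × grid span). Words whose score is −∞ (possible at zero pseudocount)
are carried as a separate mass that never reaches a finite threshold. The
p-value of a query score is the survival function at the nearest grid point,
which makes the DP bit-identical to exhaustive enumeration of all 4^w words
discretized the same way — a property the test suite checks up to width 8.

Match p-values are Benjamini–Hochberg adjusted. The family is **per SNP
across the motif library** by default (configurable to global): the unit of
discovery is "which factors does this SNP's neighbourhood engage", and a
per-SNP family keeps the panel size from diluting motif discovery. A match
requires adjusted p ≤ 1e-3.

### Biophysical affinity

The same PFM also yields a mismatch-energy matrix

    ε[i,b] = (1/λ) · ln( (max_b' c[i,b'] + p) / (c[i,b] + p) )

so the per-position consensus base costs exactly zero and rarer bases cost
more, on a scale set by λ. A word of motif width with total energy
`E = Σ ε` binds with occupancy

    occ = R0·e^(−E) / (1 + R0·e^(−E))

and a sequence's **affinity** is the expected number of bound positions: the
sum of occupancies over every offset, on both strands by default. Defaults
are λ = 0.7 and `ln R0 = 0.584·width − 5.66`, the published parameterization
of this model family; both are plain fields on `TrapParams`. For the
consensus word at R0 = 1 the occupancy is exactly 0.5 (E = 0), which the
tests pin down analytically.

Affinity significance is empirical: `n` i.i.d. background sequences of the
window's length and composition are scored and
`p = (1 + #{A_bg ≥ A}) / (n + 1)` (add-one rule, so p is never 0 and is
exactly 1/(n+1) when the observation beats every sample). The standalone
default is n = 20,000, which resolves the 1e-4 decision threshold with
headroom; the screening pipeline uses n = 10,000 per SNP × motif (floor
1/10001, still below 1e-4) — the pipeline's null is shared between the two
alleles of the same SNP, which is both cheaper and the right pairing for a
ref-vs-alt comparison. Seeds for each SNP × motif null are spawned
deterministically from the screen seed via `SeedSequence`, so a fixed
config reproduces every numeric column bit for bit.

### The allele-dependent-change rule

"Significant allele-dependent change" is operationalized (configurably) as:

    min(p_ref, p_alt) < 1e-4   AND
    ( |log2(A_alt/A_ref)| ≥ 1  OR  exactly one of p_ref, p_alt < 1e-4 )

The first clause demands that at least one allele actually binds; the second
captures both a ≥2-fold shift and the qualitative create/destroy case where
one allele is significant and the other is not. `log2` ratios use an
epsilon of 1e-9 in numerator and denominator to stay finite at zero
affinity. The standalone `differential_affinity` operation additionally
reports a paired-background null p-value for the ratio (background sequences
receive the ref and the alt bases at the differing offsets and the |log2
ratio| distribution is tabulated); the pipeline's flag does not depend on
it, so `run_screen` skips that extra null for speed.

### Streaks as composite alleles

SNPs whose consecutive positions are within `streak_max_gap` (default 10 bp)
form a streak. Inside the screen, the alternate window of a streak member
carries the alternate bases of *every* member in the window — a tightly
linked block segregates as one two-allele haplotype, and scoring one SNP's
alt against the others' refs would construct a haplotype that rarely exists.
Outside declared streaks, screening is one-variant-at-a-time with reference
bases elsewhere.

Motifs are ranked by **recurrence** (number of SNPs at which they are
flagged), ties broken by mean |log2 ratio| and then id. Recurrence is this
package's definition of "recurrent motif enrichment"; it is deliberately a
count, not a combined p-value, because the per-SNP records are not
independent within a streak.

## Association statistics

Allele counts fold from genotype counts (`ref = 2·hom_ref + het`, etc.).
The allelic odds ratio uses the cross-product with the **Woolf** log-normal
95% CI, `exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))` — on the study's
printed counts (254/264 vs 55/217) this reproduces the printed 3.80
(2.70–5.35) at two decimals, which is how the interval method was
identified. A zero cell triggers the Haldane–Anscombe 0.5 correction with an
explicit flag rather than failure. The test is Pearson chi-square without
continuity correction (1 df) by default; Fisher's exact is a flag. LD is
composite r²: the squared Pearson correlation of genotype dosages, the
standard surrogate when phase is unknown; EM-based haplotype r² is out of
scope.

In-silico genotyping models an enzyme as `(site, cut_offset)` — PvuII is
`("CAGCTG", 3)` — and cuts every non-overlapping occurrence (overlaps raise,
since cut order would be ambiguous). Streak calling requires each
bidirectional read to align the streak span exactly once (reverse read
reverse-complemented first, IUPAC-aware), calls hom/het per member offset
(heterozygotes show the two-allele code, e.g. M for C/A), and returns
`no_call` on any within-read or between-read disagreement — mirroring how
bidirectional Sanger confirmation is actually scored.

## The synthetic-data generators

`make_reference` plants the wild-type streak string in an i.i.d. uniform
background (default 5,196 bp, streak ~600 bp from the 3' end, emulating the
study geometry). `make_panel` places 27 biallelic SNPs at MAF 0.273: the
five streak members are C→A at the planted string's variable-C offsets, and
background SNPs keep a 50 bp minimum spacing so the planted streak is the
panel's only clustered run — with unconstrained placement, spurious ≤10 bp
background pairs would appear in most 5 kb panels and blur the streak
structure the generator exists to emulate. `simulate_case_control` draws
Hardy–Weinberg genotypes per group with the case allele frequency solving
`odds(q_case) = OR·odds(q_ctrl)`; `simulate_ld_genotypes` copies haplotypes
between two markers with probability `c`, giving dosage correlation `c` and
r² = c² (c = 0.995 reproduces the study's r² = 0.99 at n = 514).

What the generators do **not** emulate: LD between background SNPs,
coalescent/demographic structure, sequencing error, base-composition bias
(background is uniform unless configured), or indels. Passing tests
therefore demonstrate that the statistics and the pipeline logic are
correct under the stated model, not that the screen is robust to the
correlation structure of real panels.

## Numerical choices and problem sizes

- Score-distribution granularity 1e-3 log2-odds units; p-value lookups snap
  to the nearest grid point, matching the enumeration oracle exactly.
- Affinity nulls: 10,000 samples per SNP × motif inside the screen, 20,000
  standalone; add-one empirical p-values.
- The end-to-end ranking study runs 20 seeded datasets in the test suite
  (12 in the reproduction script), each a 5,196 bp reference, 27 SNPs, and
  a 3-motif library (planted consensus + 2 random decoys); these sizes keep
  a full run in a few minutes on one core while leaving the 1e-4 threshold
  resolvable.
- The OR-recovery study uses 1,000 replicates of 5,000 cases / 5,000
  controls at true OR 3.8 and control alt frequency 0.2022; CI coverage is
  checked against the nominal 95%.
- Windows containing N are excluded from scoring with a warning; lowercase
  FASTA is uppercased on read.

## Known limitations

- Affinity p-values are Monte-Carlo, not distribution-fitted; very small
  p-values are floored at 1/(n+1).
- The screen scores windows of fixed flank (30 bp per side); a motif
  overlapping the window edge contributes only its in-window part.
- Indels are skipped on VCF read; only biallelic SNPs are screened.
- The per-SNP BH family treats SNPs as separate discovery units; records of
  streak members are correlated by construction, and recurrence counts
  should be read accordingly.
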