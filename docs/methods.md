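# Methods

## Study design being emulated

The package analyzes (and simulates) a mouse SCLC cohort with three
genotypes: RP controls, RPM with homozygous conditional *Msh2* loss (fl/fl)
and RPM with heterozygous loss (fl/wt), default cohort shape 5/9/2 samples.
Loss of *Msh2* disables mismatch repair, which raises the somatic mutation
rate (default 18-fold for fl/fl over RP), skews the mutation spectrum toward
the MMR-deficiency signatures SBS15 and SBS21, and — through the higher
mutation load — increases the number of candidate MHC-I binding mutant
peptides. Cre-mediated recombination deletes the floxed *Msh2* exon, which
is visible in exome coverage as a copy-number drop on that exon.

## Variant filtering and TMB

A call is removed when its exact (chrom, pos, ref, alt) allele occurs in
two or more samples ("recurrent": germline leakage or systematic artifact —
all occurrences removed), when the allele is blacklisted (a dbSNP stand-in),
or when its depth is below `min_depth` (30 by default). Reasons are
assigned in the fixed order recurrent → blacklist → depth so audit files are
reproducible. Recurrence matching is allele-resolved (not position-only)
because modern somatic callers emit allele-resolved records; the blacklist
match is likewise allele-aware, and both choices are configurable in the
sense that the blacklist/locus sets are caller-supplied.

TMB_s = kept_s / (callable_s / 10⁶), where callable_s counts bases covered
at ≥ `min_depth` in sample s. One shared threshold governs both the variant
filter and the denominator. TMB is undefined (an error) for a sample with
zero callable bases.

## Floxed-exon copy number

With c_e,s the read count of exon e in sample s, the within-gene ratio is
r_s = c_floxed,s / Σ_{e≠floxed} c_e,s, and ĈN_s = 2 r_s / median_{controls}(r).
The sum (rather than mean) over other exons and the median (rather than
mean) over controls are deliberate: the constant absorbed by the control
normalization makes sum and mean equivalent, and the median is robust to an
aberrant control. By construction the median control ĈN is exactly 2. Calls
use midpoint thresholds between the attainable levels: < 0.5 homozygous
loss, 0.5–1.5 heterozygous loss, ≥ 1.5 retained.

The per-base predicted profile divides each control's floxed-exon base
coverage by that control's median non-floxed-exon base coverage, takes the
median of these ratios per base, and multiplies by the target sample's own
median non-floxed coverage — the coverage the exon would show without
recombination.

## Mutational signatures

Catalogs index SNVs by pyrimidine-strand substitution and flanking bases in
the 96-channel substitution-major order (A[C>A]A … T[T>G]T);
purine-reference variants are reverse-complemented before assignment.
Activities solve min‖c − Pa‖₂ s.t. a ≥ 0 (scipy NNLS) per sample, in
mutation-count units. Plain NNLS is used instead of sparsity-driven
assignment heuristics because it is fully specified and deterministic; in
low-count samples the two approaches can differ, and samples with fewer than
10 SNVs are flagged low-confidence. The MMR fraction is
(a_SBS15 + a_SBS21)/Σa, computed over all fitted exposures (restricting the
denominator to signatures active across all samples is left to the caller,
since it changes the estimand); it is undefined for zero-activity samples,
which are excluded from group tests with a warning. Group comparison is
Kruskal–Wallis with midranks and tie correction.

The bundled reference matrix contains synthetic SBS15-like (C>T-dominated)
and SBS21-like (T>C-dominated) columns with six fixed peak contexts carrying
99% of the mass plus a flat background column. Real COSMIC MMR signatures
are similarly concentrated; diffuse columns would make finite-sample spectra
converge too slowly for catalog-level checks at 10³–10⁴ SNVs. Any 96×K TSV
can be supplied instead.

## Neoantigen enumeration

The mutant CDS applies the allele edit at its CDS coordinate
(anchor-base convention for indels). Frameshift sequences append the 3′ UTR
and are read through to the first stop of the shifted frame. Trimming keeps
the mutated codon plus ⌈13/3⌉ = 5 codons per side (missense/in-frame),
clipped at the CDS ends — a mid-CDS SNV yields a 33-nt window and an
11-residue peptide with the mutant residue centered. Frameshifts are trimmed
only on the wild-type 5′ side (same codon-aligned flank) and keep the entire
novel-frame peptide through to its stop, since the immunogenic novelty of a
frameshift lies entirely 3′ of the lesion. Candidates are all k-mer windows
(k = 9 by default, 8–14 supported) overlapping the mutated residues, minus
any window identical to a wild-type k-mer — self-peptides are not
neoantigens. A mutation is neoantigenic when at least one candidate ranks
below 2; strong binders rank < 0.5, weak binders 0.5 ≤ rank < 2 (the
boundary value 0.5 is assigned weak, 2.0 non, closing the half-open
intervals deterministically).

Scoring is pluggable. The bundled surrogate is a fixed position-weight
scorer with H2-Kb-like anchor preferences (aromatic at position 2,
aliphatic C-terminus) mapped monotonically to a percent-rank scale; it is
deterministic so enumeration and counting logic can be tested with planted
motifs, and it is not an affinity model. An adapter for an external
NetMHCpan executable is provided but never required.

## Survival

Endpoints: onset = onset − induction (never-onset animals censored at end
of follow-up); post-onset/post-enrollment = end − onset with events defined
as disease death or termination-criteria euthanasia. Animals ending for
unrelated causes are excluded by default — the emulated study's stated
policy — with a `censor` alternative, because exclusion biases the
Kaplan–Meier estimate when censoring is informative. The KM median is the
smallest observed time with S(t) ≤ 0.5 and is flagged undefined when the
curve never reaches 0.5. Log-rank is Mantel–Cox with hypergeometric
variance and ties grouped; Mann–Whitney uses exact enumeration for small
tie-free samples and a continuity-corrected normal approximation otherwise.
Curves and tests are computed via lifelines/scipy and are verified in the
test suite against hand product-limit computations and a brute-force
observed-minus-expected tabulation.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the emulated
study conditions.

- **Transcriptome**: 60 transcripts (CDS 300–1500 nt, ≥ 90-nt exons, one
  floxed gene with a middle floxed exon) on one chromosome, all + strand.
  The scaled-down exome (~50 kb vs ~30 Mb) keeps simulations fast; TMB
  values are therefore large in absolute terms, and only ratios across
  groups are meaningful.
- **Coverage**: per-base Poisson with mean `mean_depth × bias × CN/2` on the
  floxed exon (CN per genotype: 2/0/1) and CN = 2 elsewhere. The
  multiplicative exon bias is log-normal (σ = 0.2) drawn once per exon and
  shared across samples, as capture bias largely is in real exomes — which
  is exactly why the study's ratio-of-ratios normalization works. Poisson is
  the minimal count model; overdispersion is not simulated.
- **Mutations**: per-sample counts Poisson around the group rate (defaults
  50 / 900 / 50 for RP / fl/fl / fl/wt; the absolute scale is a free
  parameter, the 18-fold contrast is the design constant). Channels are
  drawn from the group mixture (fl/fl: 0.45 SBS15 + 0.35 SBS21 + 0.2 flat;
  RP and fl/wt: 0.1/0.1/0.8) and placed uniformly on exonic sites with the
  matching trinucleotide context. Placement avoids collisions cohort-wide:
  on a real exome two tumors essentially never hit the same base, so
  recurrent calls are produced exclusively by the artifact injector.
  Indels are 10% of events, half frameshift (1 bp) and half in-frame (3 bp).
  Consequences are annotated from the transcript models.
- **Artifacts**: shared calls copied into ≥ 2 samples, blacklisted calls,
  and low-depth calls (depth < 30), each at 2% of the true variant count by
  default, with ground-truth labels returned for scoring.
- **Cohorts**: event times are exponential with the target median
  (t = Exp(m/ln 2); a Weibull shape is exposed for robustness checks).
  Defaults: onset medians 258.5 (RP) / 285 (RPM) days; post-onset 55 / 46.5
  days; treatment-arm medians per genotype (RP: vehicle 53, chemo 73.5,
  anti-PD-1 53, combination 75; RPM: 41 / 83 / 51.5 / 85 — the combination
  medians are not design constants and were set once to values consistent
  with "effective in both genotypes, larger effect with MMR deficiency").
  5% of animals end for unrelated causes at a uniform time before their
  disease endpoint. 30% of events are termination-criteria euthanasia
  (both causes count as events).
- **Determinism**: one top-level seed is fanned out to stage-scoped
  generators via `numpy` SeedSequence spawning, so reruns are byte-identical
  and stages individually reproducible.

What the generator does **not** emulate: read-level noise (alignment,
mapping quality, strand bias), subclonal allele fractions and tumor purity,
germline polymorphism, overdispersed coverage, genome-wide CNV beyond the
floxed exon, and realistic exome size. Passing tests therefore demonstrate
correctness of the defined computations under the stated statistical model,
not robustness to upstream calling artifacts.

## Numerical and scale choices

Unit tests run on a smaller configuration (12 transcripts, 3/3/1 samples,
rates 30/540/30 — the same 18-fold contrast); acceptance-style checks use
the full default cohort, 100-sample copy-number sweeps at depth 100,
20-replicate NNLS recovery at 1000 SNVs per level, 10⁴-draw Kaplan–Meier
medians, and 200-replicate null calibration of the log-rank test — sizes at
which the Monte-Carlo tolerances in the tests (TV ≤ 0.05 at 10⁴ SNVs,
MMR fraction ± 0.07, CN recovery 100/100, type-I error in [0.02, 0.09])
follow from the binomial/multinomial noise of the generating model.
Degenerate inputs (all-zero catalogs, all-censored cohorts, zero callable
bases, zero control coverage) are flagged or raised rather than silently
propagated; exact identities (control median ĈN = 2, zero NNLS residual on
cone members) hold to floating-point precision.

## Known limitations

- NNLS refitting can differ from sparsity-driven assignment tools in
  low-count samples; the MMR fraction is stable but individual exposures
  may redistribute among correlated signatures.
- The surrogate predictor ranks are not affinities; binder counts are only
  comparable across groups within a run, not against published binder
  counts.
- The scaled-down exome inflates absolute TMB (mutations/Mb over ~0.05 Mb
  callable); group contrasts are the meaningful output.
- Exclusion of unrelated deaths (the default, matching the emulated study)
  biases KM estimates if such deaths are informative; use
  `unrelated="censor"` to assess sensitivity.
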