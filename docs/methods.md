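# Methods

This note records the models, conventions and design choices behind
`coihap`, in the spirit of a statistical-methods appendix: what is
computed, under which assumptions, and where the genuinely open choices
were made.

## Data model and conventions

All analyses operate on a fixed-length, pre-aligned nucleotide matrix
(`seqio.Alignment`). Mixed-length inputs are never merged: a survey that
produced, say, a 504-nt set and a shorter diagnostic set is analysed as
two separate runs, because every downstream quantity (S, k, Hamming
steps) is defined over one common column set. Coordinates are 0-based
half-open internally and 1-based inclusive in anything user-facing.
Sequences are taken as given on one strand; the only strand check is the
species-assignment screen, where a best identity below 70% raises a
"possible reverse strand" warning (same-gene opposite-strand identities
fall far below any within-complex value).

## Haplotypes and diversity statistics

A haplotype is an exact full-length string match; sequences containing any
non-ACGT character are excluded from collapsing (and logged), since one
ambiguous base would otherwise mint a spurious haplotype. Haplotype ids
inherit the first member's sample id, in input order, for determinism.

Diversity statistics default to **complete deletion**: every column with
any non-ACGT character is dropped before S, η_s, U, k are computed, so all
statistics share one site set — the assumption built into the neutrality
test variances. Pairwise deletion is available for k/π reporting but is
deliberately not used by the neutrality stage.

**Singleton rule (no outgroup).** At each segregating column the majority
base stands proxy for the ancestral state (ties broken alphabetically);
every non-majority base observed in exactly one sequence is one singleton
mutation, attributed to its carrier. At a biallelic column with counts
(1, n−1) this is exactly "the minority base is the singleton", the
convention the outgroup-free D*/F* statistics assume. A consequence worth
stating: a tri-allelic column whose three bases each occur once
contributes one segregating site but two singleton mutations, so η_s can
exceed S on multi-allelic data. Σᵢ Uᵢ = η_s always.

Haplotype diversity uses the unbiased form Hd = n/(n−1) · (1 − Σ p_h²).

## Neutrality tests

Tajima's D uses the 1989 coefficient chain (a₁, a₂, b₁, b₂, c₁, c₂, e₁,
e₂), all exposed in the result's `intermediates` for auditability. Fu &
Li's D* and F* use the outgroup-free formulas with the corrected variance
coefficients (the set used by the standard desktop software; the original
publication's versions contain known typos):

- c_n = 2(n·a_n − 2(n−1)) / ((n−1)(n−2))
- d_n = c_n + (n−2)/(n−1)² + (2/(n−1))(3/2 − (2a_{n+1}−3)/(n−2) − 1/n)
- v_D* = [(n/(n−1))²b_n + a_n²d_n − 2n·a_n(a_n+1)/(n−1)²] / (a_n²+b_n)
- u_D* = (n/(n−1))(a_n − n/(n−1)) − v_D*
- v_F* = [d_n + 2(n²+n+3)/(9n(n−1)) − (2/(n−1))(4b_n − 6 + 8/n)] / (a_n²+b_n)
- u_F* = [n/(n−1) + (n+1)/(3(n−1)) − 4/(n(n−1))
  + 2(n+1)/(n−1)²·(a_{n+1} − 2n/(n+1))] / a_n − v_F*

with D* = ((n/(n−1))S − a_n η_s)/√(u_D*S + v_D*S²) and
F* = (k − ((n−1)/n)η_s)/√(u_F*S + v_F*S²). No independent reference
implementation of D*/F* ships in this environment, so the transcription is
locked two ways: the frozen F1 fixture value (numerators hand-checked) and
a Monte-Carlo check that the standardized statistics have mean ≈ 0 and
standard deviation ≈ 1 under the neutral fixed-S null.

R2 = √(n⁻¹Σ(Uᵢ − k/2)²)/S follows the plug-in definition directly.

**P-values.** All four statistics share one null machinery: neutral
constant-size Kingman genealogies with the observed n, exactly S mutations
placed uniformly at random on total branch length (infinite sites), the
statistic recomputed per replicate, and the empirical tail probability
with the (count+1)/(reps+1) correction (never exactly zero). The lower
tail is the default alternative for every statistic, matching the
expansion hypothesis; two-sided is available. Default 10,000 replicates; a
seed is mandatory in pipeline runs. A beta-distribution approximation for
D was deliberately not used — one simulated null for all four statistics
is uniform and testable, and the simulation is cheap.

## Coalescent simulator

Waiting times between coalescences: with k lineages and growth rate g = 0,
Exp(k(k−1)/2). Under exponential growth (N(t) = N₀e^{−gt} looking back)
the cumulative coalescence rate has a closed-form inverse, so the waiting
time from time t₀ is w = ln(e^{gt₀} + gE/(k(k−1)/2))/g − t₀ with
E ~ Exp(1) — exact, no numerical integration. Fixed-S mutation dropping is
multinomial on branch lengths; fixed-θ draws Poisson(θ/2 · total length)
first. Statistics for null distributions are computed directly from the
derived-count representation; a test asserts they agree exactly with the
sequence-realization route. The simulator is checked against closed-form
moments (E[TMRCA] = 2(1−1/n), Watterson's E[S] = θ·a₁) and, as an
independent oracle, against msprime's TMRCA distribution
(Kolmogorov–Smirnov).

No recombination, migration or selection: mitochondrial DNA is effectively
non-recombining and the null of interest is the standard neutral
coalescent.

## Synthetic survey generator

`simulate_survey` emulates the structure of a zone-stratified whitefly
survey: three agro-ecological zones (default mean adult abundances
SU = 30.56, GF = 28.21 — surveyed means — and SG = 18, a documented
default for a zone reported only as "above 17 per plant"), 18 sites per
zone, a host drawn per site (cassava-dominated), per-host species
mixtures (cassava default 0.7/0.2/0.1 across an invasive SSA1-SG1-like
group, a resident group, and a non-cassava MED-like group), and 16
sequenced individuals per site. Species anchors differ by ~6% so that the
synthetic reference panel separates them cleanly at the conventional 3.5%
putative-species boundary.

The invasive pool is a **star**: one dominant haplotype (drawn with
probability 0.65) plus 40 distinct single-step satellites drawn uniformly
— the expansion signature. Two features of real data it does *not*
emulate: satellites recur (sampled with replacement from a finite pool),
which damps purely singleton-based statistics — on default settings D and
R2 flag the expansion strongly while D* may not — and there is no
within-site spatial or temporal autocorrelation. Passing tests on this
generator therefore demonstrate that the machinery detects star-like
expansion structure, not that any particular field dataset would yield
significant D*.

Resident and outgroup pools are realized from neutral constant-size
coalescent samples. One global seed drives everything through fixed
per-stage stream offsets; the same seed reproduces FASTA/TSV outputs
byte-for-byte.

## Species assignment

Percent identity is matches over comparable columns (columns with any
non-ACGT character skipped), reported to 2 decimals. Defaults: species
boundary 96.5% (the conventional 3.5% mtCOI divergence criterion for the
*B. tabaci* complex — a documented default, not a measured constant) and
reverse-strand screen at 70%. References longer than the analysis window
are sliced by sliding the alignment's first 25 consensus columns along the
reference and accepting ≤ 5 mismatches; anything worse instructs the user
to pre-trim rather than silently embedding an aligner. Ties take the
first panel entry, making results invariant to panel duplication.

## Haplotype network

Kruskal's algorithm over pairwise Hamming distances with the goeBURST
tie-break chain for equal-weight edges, compared endpoint-wise: more
single-step neighbours first, then more double-step neighbours, then
higher haplotype count, then lexicographically smaller id. The network is
built on haplotypes only (abundances as node attributes). Group-to-group
"mutational steps" are reported two ways — minimum pairwise Hamming
distance between member haplotypes (primary) and shortest MST path length
— because a published network diagram does not disambiguate which was
read off it. MST weight is verified against brute-force enumeration of
spanning trees on small fixtures.

## Trees

K2P distances use d = −½ln(1−2P−Q) − ¼ln(1−2Q) with pairwise deletion;
saturated pairs (log argument ≤ 0) are set to a configurable ceiling (10)
with a warning. Note the correction is larger for transitions than for
transversions at equal p-distance, as the formula dictates.
Neighbour-joining is Saitou–Nei with the Studier–Keppler Q criterion; a
negative branch estimate is clamped to zero with the deficit moved to the
sister branch, preserving the pair's path length. The NJ tree is a
fast grouping view, not a substitute for model-based phylogenetics;
likelihood/Bayesian tree inference is out of scope by design.

## McDonald–Kreitman

Codon-aware, default genetic code: invertebrate mitochondrial (table 5) —
AGA/AGG code serine and TGA tryptophan, so using the standard code on
insect COI would misclassify sites. The reading frame is user-supplied or
auto-detected as the stop-free frame (logged). Within a codon, each
distinct non-majority ingroup codon is compared to the ingroup majority
codon (star decomposition); ingroup-fixed positions differing from the
outgroup consensus form the divergence codon. Multi-position differences
are averaged over all minimal mutational pathways with equal weights,
excluding pathways through stop codons when any stop-free pathway exists;
steps into or out of a stop codon count as nonsynonymous. Fractional
counts are rounded half-to-even (logged) before the Fisher exact test,
which sums hypergeometric probabilities ≤ the observed table's (two-sided)
and returns p = 1 with a warning on a zero margin. The pairing of ingroup
and outgroup is a required user input; NI = (Pn/Ps)/(Dn/Ds) is reported
when defined.

## Survey GLM

The one-way Poisson model has closed-form MLEs (group means), so the fit
is exact; IRLS exists in-package purely as a cross-check (agreement to
1e−10 is asserted in tests, and statsmodels agreement as well). The group
effect is tested by likelihood ratio against the pooled-rate null
(χ², df = groups−1); when the full model's deviance/df exceeds 1.5 the
test switches to the quasi-likelihood F form (Δdeviance/Δdf)/dispersion vs
F(Δdf, df_resid). Both the 1.5 threshold and the α level are configurable
— the choice of threshold is a convention, not an estimate. Pairwise
comparisons are Wald z tests on log-rate differences with Holm adjustment
rather than a multivariate-normal single-step ("Tukey-type") adjustment:
deterministic, integration-free, and slightly conservative; this is a
deliberate, documented deviation from tool-specific Tukey procedures. The
compact letter display uses the insert-and-absorb algorithm on the
significance matrix. The unit of analysis (plants vs site totals) is
whatever the input rows are; every output declares its denominator.

## Problem sizes and numerical choices

Default simulation sizes — 2,000 replicates for calibration experiments,
100 replicates for power, 20,000 for moment identities, 10,000 for
pipeline p-values — were chosen so Monte-Carlo error is small relative to
the acceptance bands (binomial SE ≈ 0.005 on a 5% rejection rate at
2,000 reps) while keeping any single experiment in the minutes range on
one core. Ties in haplotype naming, panel order, majority-base election
and MST edge ordering are all broken deterministically so that every
output is byte-reproducible given a seed.

## Known limitations

- D*/F* coefficient transcription is locked by fixture + Monte-Carlo
  moments, not by cross-validation against a second implementation.
- The MK star decomposition for >2 ingroup codons at one position is a
  simplification of full parsimony pathway counting over the codon graph.
- The species-assignment screen is percent identity only; it will not
  separate groups whose mtCOI divergence is below the configured
  threshold, and it is not a species-delimitation method.
- Haplotype-count reports depend on upstream trimming and the ambiguity
  exclusion rule; two analyses of "the same" dataset can legitimately
  differ by a haplotype or two if their QC differed (published surveys
  show exactly this kind of internal discrepancy).
- The survey generator's abundance is Poisson per site; real counts are
  typically overdispersed between sites — the GLM's F fallback exists for
  that case, but the default generator does not exercise it.
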