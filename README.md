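# coihap

A toolkit for mtCOI haplotype surveys of cryptic insect species complexes —
the kind of study where hundreds of field-collected individuals (for
example *Bemisia tabaci* whiteflies from cassava fields) are barcoded with
a fixed-length mitochondrial COI fragment, and the questions are: which
putative species are present, how are their haplotypes related, and does
any population carry the genetic signature of a recent invasion or
demographic expansion?

`coihap` implements the full analysis chain as a library plus a thin CLI:

- **seqio** — aligned-FASTA ingestion with a strict single-length
  contract, sample-metadata attachment, trimming, round-trip writing.
- **haplotypes** — collapse to unique haplotypes; the diversity sufficient
  statistics (segregating sites *S*, singletons η<sub>s</sub> with
  per-sequence attribution *U<sub>i</sub>*, mean pairwise differences *k*,
  π, haplotype diversity *Hd*).
- **species** — putative-species assignment by exhaustive percent-identity
  search against a labelled reference panel (a local, deterministic
  replacement for remote BLASTn), with divergence and reverse-strand
  flags, and per-host/site/zone composition tables.
- **network** — goeBURST minimum-spanning haplotype network over Hamming
  (mutational-step) distances, group-to-group step counts, K2P distances
  and a neighbour-joining grouping tree (Newick/GraphML/DOT export).
- **neutrality** — Tajima's D, Fu & Li's D\* and F\* (outgroup-free, with
  the corrected variance coefficients), and Ramos-Onsins & Rozas R2, all
  with p-values from one fixed-S coalescent null engine.
- **mk** — McDonald–Kreitman test under the invertebrate mitochondrial
  code, with minimal-pathway averaging for multi-step codons and a
  hypergeometric Fisher exact test.
- **coalsim** — the coalescent simulator behind the nulls (constant size
  and exponential growth, fixed-S or fixed-θ mutations) and a
  survey-scale synthetic-data generator: zones × sites × hosts with
  Poisson abundance, species mixtures, and an "invasive" star-shaped
  haplotype pool.
- **survey** — one-way Poisson abundance GLM with likelihood-ratio test,
  overdispersion-aware F fallback and a compact-letter display of
  pairwise comparisons.
- **pipeline / cli** — end-to-end orchestration with a manifest, and the
  `coihap` command with subcommands `collapse`, `assign`, `network`,
  `tree`, `neutrality`, `mktest`, `glm`, `simulate`, `pipeline`,
  `fixtures`.

## The statistics at the core

With *n* sequences, *S* segregating sites, η<sub>s</sub> singleton
mutations and *k* the mean pairwise difference count:

- Tajima's **D** = (k − S/a₁) / √(e₁S + e₂S(S−1)), a₁ = Σ<sub>i<n</sub> 1/i.
- Fu & Li's **D\*** contrasts S with a₁η<sub>s</sub>; **F\*** contrasts
  k with ((n−1)/n)·η<sub>s</sub> — both standardized with the corrected
  no-outgroup variance coefficients.
- **R2** = √(n⁻¹ Σᵢ (Uᵢ − k/2)²) / S, small under star-like genealogies.

Negative D/D\*/F\* and small R2 indicate an excess of rare variants, as
expected after a demographic expansion (or selective sweep). Significance
comes from simulating neutral constant-size coalescent genealogies with
the observed *n*, dropping exactly *S* mutations uniformly on total branch
length, and taking the empirical lower-tail probability with the
(count+1)/(reps+1) correction.

## Worked example

Generate a synthetic survey (54 sites in three agro-ecological zones, one
invasive star-shaped haplotype pool) and analyse it:

```bash
coihap simulate --seed 1 --outdir survey
coihap glm survey/survey_metadata.tsv
```

```
SU: rate 32.33 [a]
GF: rate 28.78 [a]
SG: rate 19.33 [b]
```

The two high-abundance zones are statistically indistinguishable (same
letter) and both exceed the third — the classic field pattern of a
whitefly upsurge concentrated in particular agro-climatic zones.

```python
from coihap import read_fasta, collapse_haplotypes, diversity_summary, neutrality_suite
from coihap.species import ReferencePanel, assign_species
from coihap.seqio import Alignment

aln = read_fasta("survey/survey.fasta", metadata="survey/survey_metadata.tsv")
panel = ReferencePanel.from_fasta("survey/survey_panel.fasta")
calls = assign_species(aln, panel)
sg1 = Alignment([r for r, c in zip(aln, calls) if c.best_label == "SSA1-SG1"])
table = collapse_haplotypes(sg1)
ds = diversity_summary(sg1)
for r in neutrality_suite(ds, reps=2000, seed=1):
    print(f"{r.statistic:>5} = {r.value:8.5f}   p = {r.p_value:.4f}")
```

```
    D = -2.39687   p = 0.0005
Dstar =  1.44221   p = 0.9730
Fstar = -0.35166   p = 0.4098
   R2 =  0.00804   p = 0.0005
```

The invasive group (529 sequences, 40 haplotypes, one dominant haplotype
at n = 363) shows strongly negative Tajima's D and a tiny, highly
significant R2: one dominant haplotype ringed by low-frequency single-step
variants — the signature of a recent population expansion. (D\*, which
looks only at singletons, is blunted here because satellite haplotypes
recur in a finite pool; see `docs/methods.md`.)

The full pipeline (collapse → assign → network → neutrality → MK → GLM →
manifest) runs from one config file:

```bash
coihap pipeline run.cfg
```

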