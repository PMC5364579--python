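# Methods

## Trait-rule engine

A trait rule is a tree whose leaves test membership of a gene symbol, an EC
number, or a case-insensitive product substring, and whose internal nodes
are `ALL`, `ANY`, `AT_LEAST(k)` or a reference to another trait. All
combinators are monotone, so adding genes to an annotation can only switch
traits on, never off — the property the dropout simulations rely on.
Evidence sets report the genome's gene symbols matched by satisfied GENE
leaves anywhere in the tree (including inside failed combinators, which is
useful when diagnosing a near-miss); EC and product matches support the
verdict but are not counted as gene evidence, keeping the invariant
evidence ⊆ genome gene set. Trait references are resolved against the
rulebook and cycles are rejected when the rulebook is constructed, not at
evaluation time.

Gene symbols are normalized by lower-casing only the first character
(`CheY → cheY`, `NifH → nifH`), the casing convention of prokaryotic
annotation pipelines; matching thereafter is exact. Methyl-accepting
chemotaxis proteins have no single canonical symbol, so chemotaxis detects
them from the product text instead.

### Default rulebook choices

Where a gene-set criterion is fully specified (chemotaxis, motility, EPS
production/secretion, rnf, nif thresholds, single-gene traits) the default
rulebook encodes it verbatim. Three calls required a decision:

- **CO₂ fixation (CBB)**: form I RuBisCO needs cbbL (+cbbS) and form II
  needs only cbbM, so the presence call is `cbbL ∨ cbbM ∨ EC 4.1.1.39`;
  no stricter threshold is biologically defensible for a presence call,
  and the rule is one config line to tighten.
- **N₂ fixation**: the EC number and the ≥2-of-nifKDH criterion are
  treated as alternative evidence routes (OR), mirroring the CBB design;
  requiring both would make the call hostage to whichever annotation field
  the upstream tool happened to fill.
- **H₂ oxidation**: matched by EC 1.12.1.3 plus a shipped, editable list of
  uptake/Ech hydrogenase symbols, since annotations frequently carry the
  symbol but not the EC.

Fermentation pathway gene lists (eight pyruvate→acetate routes taken as
ALL-rules, three pyruvate→ethanol routes taken as 2-of-3 rules) are not
canonical; they ship as `data/fermentation_pathways.yaml` with the
MetaCyc/KEGG identifier each list was drawn from, and are meant to be
edited. Denitrification is exposed as four separate step traits
(nar/nap, nir, nor, nos) rather than one composite.

Group assignment uses precedence A > B > C with B = both EPS traits and
C = chemotaxis ∧ motility; the precedence makes the labels mutually
exclusive and total, and a genome satisfying everything is A by
construction. B tolerates arbitrary partial motility gene content — only
the complete motility trait matters.

## Quality gate

`accept_bin` is the two-threshold rule (≥31 of 36 single-copy genes, ≤2
duplicated). Duplicated genes still count as present, since the two
thresholds are independent statements about completeness and contamination
respectively. `completeness_percent` = 100·n_present/total with total
defaulting to the 36-gene panel; the gate therefore implies ≥ 86.1%
estimated completeness.

## Gene-frequency comparison

Coverage columns are normalized to sum to one per sample; frequencies are
carried as fractions internally and written as percentages in outputs.
Trait frequencies sum the member genes' frequencies, matching rows by
normalized symbol with an EC-tag fallback (`gene|EC:n.n.n.n` row ids).

The one-way fixed-effects ANOVA is computed from explicit between/within
sums of squares so the result object can expose df, group means and the
degenerate-case contract: zero within-group variance yields F = 0, p = 1
for equal means and F = ∞, p = 0 for unequal means, and a design with one
value per group (df_within = 0) is an error. The test suite cross-checks
against `scipy.stats.f_oneway` to 1e-10 relative. The default design is
two groups — biofilm (garnet + glass, n = 2) versus planktonic (two size
fractions × duplicates, n = 4), giving df = (1, 4) — with any alternative
grouping expressible through the design file. Raw per-trait p-values are
reported, as in the original per-trait analyses; a Benjamini–Hochberg
column is available behind `bh_correction=True` / `--bh` and off by
default.

## Diversity

Shannon (natural log by default, base selectable) accepts counts or
relative abundances and is computed via `scipy.stats.entropy`; inverse
Simpson is 1/Σ pᵢ². Chao1 uses the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)), defined even when F₂ = 0, with the classic
form a switch. ACE uses the standard ≤10-count rare/abundant split
(scikit-bio's implementation); when every rare taxon is a singleton the
ACE coverage estimate is zero and the bias-corrected Chao1 value is
returned with a logged note. Rarefaction draws exactly n reads without
replacement via `numpy`'s multivariate hypergeometric sampler with an
explicit per-call seed; the per-sample summary rarefies before computing
indices when a depth is given (the 10,000-read default of the bundled
generators mirrors common 16S practice) and uses raw counts otherwise.

Abundance filtering keeps taxa reaching the threshold (default 1%) in at
least one sample and pools the rest into a remainder row, preserving
column sums; habitat overlap intersects the ≥threshold taxa of two
samples, with label-based exclusion of buckets like "Unknown phylum" or
the pooled remainder left to the caller.

## Cell abundance

ATP→cells is a bare division by an ATP-per-cell factor. That factor is
protocol-dependent and has no universal value, so it is a required user
input; the CLI's 1 amol/cell default is an explicit placeholder, never a
biological constant asserted by the package. Replicate measurements
(typically triplicate) are summarized as mean ± SD (ddof = 1). The
biofilm:planktonic fold divides cells·cm⁻² by cells·mL⁻¹ on purpose —
the standard caveated comparison of attached to suspended abundance — and
every output carries a units note saying so.

## Synthetic data

`generate_genome` builds a minimal satisfying gene/EC/product set for the
planted group and metabolic traits, sampling uniformly among alternatives
at `ANY`/`AT_LEAST` nodes (so a planted motility genome carries exactly 20
of the 24 structural genes plus motAB), then deletes each required item
independently with probability `dropout` and adds decoys from a fixed
lexicon (`syn0000`…) verified disjoint from every rulebook symbol. Dropout
is thus the synthetic analogue of bin incompleteness (dropout ≈ 1 −
completeness), and classification accuracy decreases monotonically in it.

`generate_coverage` gives every gene one log-normal baseline shared across
samples, multiplies a trait's genes by the planted fold in the boosted
group, and applies unit-mean multiplicative log-normal noise with the
requested coefficient of variation (σ² = ln(1 + CV²)). The default
conditions used throughout validation are the study layout — 2 biofilm vs
4 planktonic samples — with CV = 0.1 and a 5-fold planted effect for power
runs. `generate_otu_table` draws one log-normal community profile and
multinomial samples of 10,000 reads per sample by default.

What the generators do **not** emulate: real annotation error (wrong
symbols rather than missing ones), compositional correlation between
traits, phylogenetic structure among taxa, or overdispersion beyond the
log-normal/multinomial models. Passing the recovery tests therefore shows
the pipeline's logic and calibration are correct under these models, not
that any particular field dataset satisfies them.

## Validation studies and problem sizes

`biofilmtraits.validation` runs the Monte-Carlo studies used by the tests
and the acceptance script: classification accuracy over 4 × 200 genomes
per dropout level; ANOVA type-I error over 1000 null coverage simulations
(rejection rate at α = 0.05 lands within 0.05 ± 0.02) and power over 200
simulations at fold 5 (≥ 0.9; observed ≈ 1.0). These sizes give
Monte-Carlo standard errors well below the decision margins while keeping
a full run in seconds.

## Known limitations

- Presence/absence is taken from upstream annotation; there is no
  homology search, so rule calls inherit the annotation tool's vocabulary.
- The sulfate-reduction call rests on a single gene (dsv), as the
  dissimilatory dsrAB genes may be absent from the annotations entirely.
- The ANOVA assumes approximately normal within-group frequencies; with
  n = 2 vs 4 it has little robustness to heavy-tailed noise, which is why
  the type-I calibration is checked explicitly under the generator's
  log-normal noise model.
- Percent-mode OTU tables are validated only to column sums of 100 ± 0.5,
  accommodating printed-table rounding.
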