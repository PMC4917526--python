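# Methods

This note documents the models, defaults and numerical choices behind
`duobin`, and what the synthetic validation does and does not demonstrate.

## Differential-coverage binning

**Model.** A scaffold's observation is its mean per-base depth in each of two
samples. Genomes are assumed to be clonal populations with uniform coverage
along the genome, so scaffolds of one genome concentrate around a single
point in the coverage plane; relative abundance differences between the two
conditions spread genomes apart. Coverage is compared after normalization by
aligned-read counts (`factor_s = min(aligned)/aligned_s`), with the
lower-depth sample as the unchanged reference.

**Seeding.** DBSCAN on `(log10(c1 + ε), log10(c2 + ε))` with ε-pseudocount
0.1 (admits zero-coverage scaffolds), DBSCAN radius `eps = 0.1` (log10 units)
and `min_samples = 5`. The radius was chosen from the noise analysis: for
Poisson depth, the standard deviation of a scaffold's log10 mean coverage is
≈ 0.434/√(c·L) — under 0.01 for c ≥ 10× and L ≥ 2 kb — so genuine clusters
are an order of magnitude tighter than 0.1 while genomes whose coverage
differs by ≥ 30 % in either sample sit farther apart than that. Scaffolds
below 500 bp (the assembly's minimum scaffold convention) are excluded from
seeding and left to link recovery. Binning was originally an interactive,
visual step in this style of analysis; a deterministic clusterer replaces it
here because a testable artifact needs reproducible labels.

**Composition refinement.** Genomes with indistinguishable coverage (the two
*Clostridium*-like genomes in the default community are an extreme case:
identical coverage in *both* samples) are separated on composition.
Tetranucleotide frequencies use 136 canonical (reverse-complement-collapsed)
classes — assembled scaffolds have arbitrary strand, so strand-invariant
counts are the standard remedy. Windows containing non-ACGT symbols are
skipped; a scaffold with no valid window is excluded; below 50 valid windows
the vector is statistically weak (the constant is exposed as
`LOW_CONFIDENCE_WINDOWS`). PCA is column-centered without variance scaling
(all 136 entries share the frequency scale); component signs are fixed by
making each component's largest-magnitude loading positive, so scores are
reproducible bit-for-bit across row orderings.

Within each coverage bin, recursive 2-means on the first 3 principal scores
proposes splits. A split is accepted only if (i) both children keep ≥ 5
scaffolds and (ii) the separation score — centroid distance divided by the
pooled within-child RMS distance — exceeds 3.0. For a unimodal Gaussian
cluster a forced 2-means split scores ≈ 2.7 in the effectively
one-dimensional case, so 3.0 sits just above the no-structure baseline while
well-separated GC families score ≥ 4; the guard of 5 scaffolds per child
prevents noise-driven fragmentation. Splitting never merges or crosses
seeded clusters. Three components are retained by default (configurable);
the leading component tracks GC content and the next two capture
within-GC compositional structure.

**Link recovery.** A noise scaffold joins the bin to which its summed
paired-end link weight is maximal, unique, and ≥ 3 (read pairs); ties leave
it unassigned. Rounds iterate to a fixpoint with batch updates, so a
recovered scaffold can anchor its neighbors and the outcome is independent
of link order. The minimum weight of 3 is a conservative default against
chimeric or spurious pairs; no published value exists for this step.

**Bin filtering.** A bin is rejected only when it is *both* less than 20 %
complete *and* smaller than the minimum size (default 1 Mb; scale it with
genome size when simulating scaled-down communities). The conjunction
matters: a 13 %-complete bin of 4.1 Mb is a legitimate low-coverage genome
and is kept, mirroring how such tables retain large incomplete bins while
discarding small fragments.

**Label canonicalization.** Final labels are renumbered by each bin's
lexicographically smallest scaffold id, making the full labelling invariant
to input row order.

## Marker census, completeness, duplication

The reference set is 105 essential single-copy genes (abstract ids
`ESG_001..ESG_105`; any id list can be plugged in, and a HMMER3 tblout
adapter maps ORF hits to scaffolds). Completeness is
`round_half_up(100·unique/105)` as an integer percent — half-up rounding
reproduces every observed (found → %) pair in the reference bin profile.
"Duplication level" has no single published definition, so both candidates
are reported: the count of markers seen ≥ 2 times, and the ratio
total-hits/unique-markers (1.0 when clean, 0 by convention for an empty
bin).

## Taxonomy

Mean nucleotide identity over a bin's essential genes (genes without hits
are excluded from the mean and counted separately — scoring them zero would
penalize database incompleteness, not the bin). Thresholds are inclusive:
≥ 95 species, ≥ 85 genus, ≥ 75 phylum. Below genus, protein and placement
evidence decide: the call is the deepest rank at which the two lineages
agree walking from kingdom down (a disagreement at some rank stops the walk,
which is exactly the deepest-common-ancestor rule); placement is used only
at high/medium confidence. A phylum-level nucleotide call acts as a floor
when the fallback is shallower. The conflict-resolution rule is this
package's own declared policy — published analyses describe only "a
consensus" — so it is documented here rather than inferred.

## Profiles

Clade tables (lineage string, sample, abundance) may hold read counts or
pre-normalized percentages; both are summed within clades at the requested
rank and renormalized to 100 per sample, which makes the rollup idempotent.
Ratios between conditions use a 10⁻⁴ % pseudocount for zeros (configurable).

## Synthetic community generator

**What it emulates.** The two-condition berry-surface metagenome structure:
~13 dominant genomes, GC 29–64 %, 57–270 scaffolds per genome (lognormal
lengths, σ = 0.25, truncated at 500 bp), per-sample mean coverages with
cross-condition skews up to ~4,000-fold, planted subsets of the 105-marker
set (including optional duplications), per-gene identity evidence around
each genome's nominal identity (σ = 0.3 points), and paired-end links
between consecutive scaffolds (weights 1 + Poisson(9)).

**Genome model.** Order-k Markov chains (default order 1; the packaged
community uses order 2). Transition rows are Dirichlet draws (concentration
20 × base composition) rescaled so each row's G+C emission probability
equals the GC target exactly — realized GC then deviates only by
binomial-scale noise (≪ the ±2-point contract), while the within-AT and
within-GC preferences differ genome to genome and give each genome a
distinct TNF signature. Real genomes carry higher-order structure (codon
bias, repeats, mobile elements) that this model does not; TNF separation
between same-GC synthetic genomes is therefore conservative in some
respects (no shared mobile elements blurring signatures) and optimistic in
others (no within-genome heterogeneity).

**Depth model.** Independent per-base Poisson with the genome's per-sample
coverage as rate (`noise_model="none"` gives exact constant depth for
debugging). Real depth is overdispersed and positionally correlated
(GC bias, mappability); the Poisson choice makes coverage estimates tighter
than reality, which the seeding radius analysis above accounts for by
leaving an order-of-magnitude margin. Aligned-read counts are derived from
total simulated bases at 100 bp per read.

**Fold ratios.** The packaged bin profile lists each bin's coverage in its
dominant sample; the minor-sample coverage is that value divided by the
profiled fold ratio (~4,000× for the *Paenibacillus*- and
Lactobacillales-like genomes, ~3,700× Actinomycetales, ~2,400×
*Clostridium*, 740× *Pantoea*). Ratios unreported for the *Pseudomonas*-
and *Erwinia*-like genomes are fixed at 100× — large enough to be
condition-specific, small enough not to overstate separation. These are
one-time modelling choices, not tuning knobs.

**Problem size.** The default community scales genome lengths to 1/20 of
the profiled bins (~3.2 Mb of sequence, ~2,150 scaffolds), keeping scaffold
counts, GC, coverages and marker censuses at their profiled values. This is
the package's chosen validation size: the statistical structure that makes
differential-coverage binning work (cluster tightness vs. cluster spacing,
TNF noise vs. TNF separation) depends on scaffold lengths and coverages,
both of which are preserved, not on total genome span.

**Determinism.** One global seed fans out through `numpy` `SeedSequence`
spawning into independent per-genome, per-sample and link streams; identical
specs produce byte-identical FASTA, depth, truth and hit tables.

## What passing tests show — and don't

Recovering ≥ 11/13 planted genomes at purity ≥ 0.9 (in practice 13/13 at
purity 1.0 under the default seed) demonstrates that the pipeline's stages
compose correctly and that its defaults are calibrated to the noise model
above. It does not demonstrate performance on real assemblies, where
strain mixtures, chimeric scaffolds, uneven coverage and shared repeats
violate the generator's assumptions; the generator deliberately omits
read-level simulation, sequencing error and assembly artifacts.

## Degenerate inputs and tie-breaks

- All-zero coverage: seeding returns all-noise with a warning.
- A scaffold with no valid 4-mer window is excluded before PCA.
- Equal link weights to two bins: the scaffold stays unassigned.
- `duplication_ratio` of an empty bin: reported as 0.
- Empty community specs fail validation before any stage runs.
- Aligned-read counts must be positive; zero is a configuration error.
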