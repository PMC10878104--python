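# Methods

## Scope and design

ampliscope benchmarks amplicon-sequencing pipeline choices — 16S region ×
classification method × reference database — against a known ground truth,
and implements the per-species multi-database combination rule that
exploits the complementarity of reference databases.  It consumes FASTA
reference databases with rank-delimited taxonomy, FASTA/FASTQ reads or ASV
representative sequences, and tabular inputs (BLAST outfmt-6 hits, profile
and PCR-result TSVs).  Denoising (DADA2/SMRTLink), alignment/phylogeny
(MAFFT/FastTree) and sequence retrieval are out of scope: the toolkit
starts from sequences the user already has, or from its own synthetic
worlds.

## Taxonomy handling

Three lineage-string dialects are normalized onto one seven-rank
(domain→species) container: QIIME/Greengenes2 prefixes
(`d__...; s__Genus_species`), plain SILVA semicolon paths, and a
`Root;`-prefixed semicolon path for RDP-style training sets (the real RDP
header layout varies by release; this normalized form is this package's
convention and round-trips losslessly).  Missing tail ranks are allowed,
missing interior ranks are not.  Species labels are normalized to a bare
binomial — underscores to spaces, whitespace collapsed, strain/subspecies
suffixes stripped — and all accuracy scoring compares these binomials
case-insensitively, because the three database families format species
differently and the combiner needs one key space.

Record filters follow standard practice: deduplication removes records
shorter than 200 bp and exact duplicate accessions or sequences (first
occurrence kept; no reverse-complement collapsing — exact string equality is
cheap and deterministic); the CCS length window keeps 1,000–1,800 bp; the
annotation filter discards hits with e-value > 1e-10 **or** identity < 99 %
(the OR-discard reading; `discard_logic="and"` is available) and rejects
vague species names via a documented, configurable token blacklist
("sp.", "uncultured", "bacterium", bracketed/candidate markers, ...).

## In-silico PCR

Primer sites are found by IUPAC-aware scanning of both strands: a template
base matches a primer symbol iff it lies in the symbol's expansion
(template `N` matches nothing unless the primer symbol is `N`).  Defaults:
at most **1 mismatch per primer** with a **4-base 3′ clamp** that must match
exactly, since 3′ mismatches abort extension.  The mismatch allowance for
"appropriate mismatches" in published in-silico amplifications is rarely
stated; these defaults are a PCR-realism choice, and both are flags.  Each
forward site is paired with the **nearest** downstream reverse site
(shortest product — polymerase realism; `all_products` overrides), product
length is bounded (defaults 50–5,000 bp), and amplicons are primer-inclusive
(`strip_primers` removes the sites).  Coordinates are 0-based half-open on
the plus strand everywhere.  Forward-primer mixtures (27F-A:27F-B = 4:1 for
V1–V2/V1–V3) take the union of sites; the weights only drive the read
simulator's primer sampling, never site detection.

The engine is validated against an independent oracle that expands each
degenerate primer into its full set of concrete strings and finds sites by
overlapped regex search; at zero mismatches both must agree exactly.

## Classifiers

**Naive Bayes (k-mer multinomial).**  One class per distinct full training
lineage; features are overlapping plus-strand k-mer counts (windows with
non-ACGT bases dropped), Laplace-smoothed.  Defaults k = 8, α = 0.001,
confidence threshold 0.7, 100 bootstrap iterations of k-mer subsamples at
1/8 of the query's k-mer count — mirroring the RDP/QIIME conventions this
classifier family standardizes on; all configurable.  Queries are
orientation-normalized first (query vs reverse complement by shared
vocabulary with the model).  Per-rank confidence is the fraction of
bootstrap winners agreeing with the point prediction through that rank; the
lineage is truncated below the first rank failing the threshold.
`n_bootstrap=0` skips the bootstrap (used for bulk read profiling, where
the species-level point call is what matters).  Ties are broken
lexicographically on the lineage string, so results are independent of
training-record order and of the seed.

**Top-hit consensus.**  A self-contained aligner (no external BLAST/VSEARCH
binary, so the artifact is hermetic): candidates ranked by shared distinct
k-mers, globally aligned (match +1, mismatch −1, gap open −5, extend −2 via
Biopython's PairwiseAligner), hits kept at identity ≥ 0.97 up to 10
accepts, lineage assigned rank-wise where ≥ 51 % of kept hits agree.
Because the alignment is global, queries should be classified against a
region-matched (amplified) reference, which is what the pipeline stage
does.  With one accept it reduces to nearest-neighbor by identity.

Neither classifier aims to reproduce QIIME2's exact internals; scikit-learn
is used in the test suite only as an independent cross-check.

## The combination rule

From the per-(species, region, method, database) accuracy grid, each
species is mapped to its argmax-accuracy database (ties to a configurable
priority list, default RDP → SILVA → Greengenes2; all-zero species are
mapped to the priority head and flagged).  At inference time, a database's
species call enters the candidate set only when that database is the
authority for the species it called; among several candidates the highest
stored (species, database) accuracy wins, and if no database is the
authority for its own call the result falls back to the best overall single
pipeline for the region, flagged `fallback`.  The inference-time conflict
rule is this package's documented interpretation — accuracy grids alone do
not dictate a merge algorithm.  By construction, on the evaluation set used
to build the lookup, combined per-species accuracy is ≥ the best single
database's for every species; a held-out split (build the lookup on one
query set, score on another) is supported to separate genuine
complementarity from overfitting.  Pipeline summaries report the unweighted
mean ± sample sd of per-species accuracy across species (and across the
key-*Lactobacillus* subset), labeled as such.

## Community evaluation

Profiles hold relative abundances summing to 1, with sub-species mass under
an explicit `unclassified` key.  Dissimilarities (profiles aligned on the
union of species): Bray–Curtis Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ); Euclidean; Jaccard in the
abundance-weighted form 2B/(1+B) derived from Bray–Curtis B (a binary
variant is a flag); Kulczynski in the quantitative form
1 − ½(Σmin/Σx + Σmin/Σy).  The weighted Jaccard and quantitative Kulczynski
match the behavior of the standard ecology packages that popularized these
names without printing formulas.  PCoA is classical scaling: double-center
−½D², eigendecompose, keep positive-eigenvalue axes; negative eigenvalues
are reported, not corrected (Cailliez correction by flag); axis signs are
fixed by making each axis's largest-magnitude loading positive.

Diagnostic concordance: presence is called at relative abundance ≥ 0.1 %
(boundary inclusive), cross-tabulated against PCR results, and summarized
by sensitivity, specificity, precision, recall, F1, accuracy and Cohen's
κ = (accuracy − Pe)/(1 − Pe) with
Pe = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)]/N².  Zero denominators yield NaN
with a warning rather than an exception; an all-zero matrix raises.

## Synthetic worlds

Species sequences are block-structured, not phylogenetically simulated:
fixed conserved blocks carry every primer-binding site at realistic
spacings (V1–V3 ≈ 485 bp, V4 ≈ 297 bp, full length ≈ 1.46 kb), and nine
variable blocks diverge per species from a shared random backbone
(default 0.25 substitutions/base).  This is sufficient to create the one
phenomenon the benchmark needs — region-dependent resolvability — while
staying fully auditable; a coalescent-style simulator is deliberately out
of scope.  Where primers physically overlap on the real gene (515F within
533F, the 338F/338R palindrome, 1100R/1115F, the two 1492R variants) the
conserved blocks overlap identically, so every primer has exactly one site.

Sister pairs share the V3–V6 variable blocks (configurable), making them
indistinguishable to V3–V4, V4 and V4–V6 but separable by V1–V3 and
V7–V9 — the *Lactobacillus* phenomenon.  The three derived databases carry
disjoint engineered defects (lineage swaps, omissions, genus truncation),
guaranteeing no single database is best for all species.  Record- and
query-level mutations are confined to variable blocks so that amplification
failure is always an engineered condition (the per-species dropout flag),
never sampling noise.  Dropout edits only bases unique to the target
region's primer footprint — whole-site scrambles where the site is
unshared, single 3′-clamp point mutations where it is shared (tolerable by
the co-located primer at the default mismatch allowance); knocking out the
universal 27F/1492R pair is impossible without collateral loss and raises.
All randomness flows from one seed through named per-subtask generators, so
worlds, databases and read sets can be regenerated independently and
byte-identically.

Mock reads are drawn multinomially from the specified composition; each
read is the species' region amplicon with iid substitutions at the stated
error rate, truncated to the read length (223 bp emulates keeping only
forward reads of a short-insert run).  The simulator does **not** model
real 16S base composition, chimeras, quality-dependent errors or platform
error profiles — so passing tests demonstrate the correctness of the
machinery and the direction of the regional/combination effects, not
accuracy figures transferable to real data.

## Problem sizes and numerical choices

Default experiment sizes — 12 species, 2 sister pairs, 3 records per
species, 5 queries per species at 1 % divergence, 20-seed uplift and
10-seed truncation batches, 1,000-read mocks — are chosen so a full
evaluation runs in seconds on one core while keeping multinomial standard
errors small enough for 3-SE recovery checks.  Tolerances: NB posterior vs
brute force 1e-9; PCoA distance recovery 1e-8; symmetric-matrix check
1e-12; profile normalization 1e-9.  Ties everywhere break
lexicographically; degenerate inputs (empty databases, all-zero profiles,
all-zero confusion matrices, queries shorter than k) raise or return
explicit unclassified results as documented in each function.

## Known limitations

* Accuracy numbers from synthetic worlds are constructions, not estimates
  of any real database's performance; real Greengenes2/SILVA/RDP snapshots
  differ in coverage and curation in ways the three stylized defects only
  caricature.
* The combination rule is evaluated by default on the same queries that
  built the lookup (matching common practice); use the held-out split for
  an unbiased estimate of the uplift.
* The top-hit classifier's global alignment requires region-matched
  references; classifying short reads against full-length references will
  under-call identity by design.
* Primer dropout semantics are guaranteed at the default matching
  parameters (max_mismatch 1, clamp 4); at other settings shared-site
  point edits may not isolate a single region.
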