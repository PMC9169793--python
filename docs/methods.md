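# Methods

`bgcscout` implements a genomics-driven procedure for finding
pathogen-induced biosynthetic gene clusters (BGCs) in a plant genome,
starting from four precomputed inputs: a gene annotation, an expression
compendium with its study design, a WGCNA-style coexpression module
assignment, and a GENIE3-style transcription-factor (TF) regulatory
network.  Module detection and network inference are deliberately *not*
part of the package — they are inputs, produced upstream by standard tools.

## Induction ranking

Each module m is summarized by an eigengene: the per-sample arithmetic mean
of its member genes' expression (the averaging convention of the source
network, not a first principal component).  Expression is transformed as
log2(x+1) by default before averaging; the transform is a configuration
switch (`raw` is available) because compendium processing conventions vary.

"Normalized" eigengene expression is the within-study z-score (mean 0,
SD 1, ddof = 1).  This removes study-specific location and scale, making
treatment effects comparable across experiments of different depth; adding
a constant to all of a study's values provably leaves every downstream
delta unchanged.  Studies with fewer than two samples or zero variance are
zeroed with a warning rather than propagating NaNs.

The induction score of a module is the unweighted mean over studies of
(mean normalized eigengene over treatment samples − mean over control
samples).  Modules are ranked by this mean delta, largest first; ties break
lexicographically on module id so the ranking is a deterministic total
order.  The top k = 5 modules (configurable) are carried into mining.

## Adjacency mining and cluster calling

Genes are ordered per chromosome by the numeric index parsed from their
accession (configurable regex with named `chromosome` and `index` groups,
defaulting to the IWGSC wheat pattern, e.g. `TraesCS2B02G445900`); genomes
without numeric accessions fall back to file-order ranks.  "Physically
adjacent" means consecutive in this rank order, not a fixed accession step,
because annotation insertions break fixed spacing.  Unassigned-scaffold
genes (chromosome token "U") participate, ranked by index; a configuration
flag can exclude them.

Mining takes the union of the selected modules' genes and reports every
maximal run of at least `min_size` = 3 genes whose consecutive rank gaps
are at most `max_gap` (default 1 = strictly adjacent; raising it tolerates
interleaved non-module genes, which real clusters contain).  The procedure
is equivalent to brute-force enumeration of maximal qualifying runs and is
invariant to input gene order; returned runs never overlap.

Runs are classified from annotation family labels through a user-editable
keyword vocabulary: a run is *kinase* when at least half its members are
kinases; *metabolic* when it contains two or more distinct
specialized-metabolism families, or a scaffold-forming family (TPS/KSL,
CPS, OSC, CHS) together with at least one tailoring family (CYP*, UGT,
OMT, HSD, SDR, ACT, CHI); otherwise *other*.  A single-family tandem array
(e.g. three UGTs) is therefore not metabolic.  Metabolic runs containing a
scaffold gene become candidate BGCs; the product class follows the scaffold
(TPS/KSL/CPS → diterpene, OSC → triterpene, CHS → flavonoid; mixed classes
→ unknown).  The coexpression bait is the scaffold gene with the highest
mean (transformed) expression, ties broken by gene id.

## Coexpression

For each candidate, the Pearson correlation r of every member against the
bait is computed across all samples on the configured transform.  Members
are flagged coexpressed when r is *strictly* greater than the threshold
(default 0.8).  Zero-variance profiles get an undefined marker (NaN), never
a zero, and are never flagged.  Coherence summaries (count, fraction,
min/median/max r) exclude the bait.

## TF overlay and enrichment

The network is consumed as given: duplicate edges keep the maximum weight
and self-loops are dropped.  Per-TF incidence counts candidate clusters
with at least one targeted member — clusters, not edges.  TFs are merged
into groups of homoeologs (same triad, when triad assignments are
supplied) and/or tandem duplicates (same chromosome and family within 5
ranks, configurable); groups are connected components of that relation.
Shared regulators are TFs with incidence ≥ `min_bgcs` (default: the number
of called candidates).

GO enrichment of the shared TFs' target set uses the upper-tail
hypergeometric probability P(X ≥ k) with N the background size (unannotated
genes count toward N), K the background term count, n the selection size —
identical to a one-sided Fisher exact test — followed by Benjamini-Hochberg
correction over the tested terms.  Annotation is taken as a flat gene→term
table; no propagation up the ontology graph is performed, so parent terms
are enriched only insofar as they are annotated directly.

## Homology and microsynteny

Pairwise protein alignment is exact global Needleman-Wunsch-Gotoh (via
Biopython's `PairwiseAligner`) with BLOSUM62, gap open 10 and extend 0.5 —
standard protein defaults, exact rather than heuristic at candidate-cluster
scale.  The unknown residue X scores 0 against everything.  Among
co-optimal alignments the aligner's canonical first traceback is reported,
which is deterministic.  Percent identity is computed over the alignment
length excluding terminal gaps by default (configurable to full length),
since published identity figures rarely state a convention; percent
similarity is the BlastP "positives" convention — aligned columns with a
positive substitution score.

Orthology is reciprocal best hit (RBH) by alignment score; a tied best hit
yields no pair (logged).  An optional minimum-identity filter keeps a
genuinely absent ortholog from matching a random best hit.  Homoeolog
triads across subgenome protein sets require a mutually consistent RBH
triangle; two-member components are dyads that name the missing subgenome
(this is how subgenome-specific cluster absence is detected), and anything
else is reported as inconsistent.

Microsynteny is rank-based (gene order, not base pairs): blocks are chains
of ortholog anchors strictly increasing in genome-A rank and strictly
monotone in genome-B rank (increasing = collinear, decreasing = inverted),
with per-step rank gaps ≤ 10 on both genomes.  The longest chain is
extracted first (O(n²) DP; ties prefer collinear orientation and the
earliest start), its anchors are removed, and extraction repeats while
chains of ≥ 3 anchors remain.

## Mass annotation

Monoisotopic masses are sums of principal-isotope masses (NIST table via
pyteomics).  Charged adducts add or subtract the *proton* mass
(1.00727646688 Da), not the hydrogen-atom mass, so electrons are handled
implicitly; `[M+H−H2O]+` additionally subtracts a neutral water.  The ppm
error is 1e6·(observed − theoretical)/theoretical.  Under this arithmetic
an observed ion at 329.1010 against the [M+H]+ of C18H16O6 (329.1020)
deviates by −2.9 ppm; published assignments of such ions sometimes print
ppm values computed from unrounded instrument masses, so modest
disagreement with values recomputed from rounded printed masses is
expected and not resolvable from the printed digits alone.

## Synthetic data model

The generator exists so every stage can be validated against a planted
truth without external downloads.  It emulates:

- **Genome**: wheat-style chromosomes (`1A`, `1B`, `1D`, ...) with
  accession indices in steps of 100.  Planted runs — six BGCs (default mix:
  three diterpene, two triterpene, one flavonoid, each 5–7 genes with one
  or two scaffold genes and ≥ 2 tailoring genes), kinase arrays, and
  single-family decoy tandems — occupy consecutive ranks, never overlap,
  and are separated by ≥ 3 background genes so plants cannot merge during
  mining.  Background family labels follow fixed frequencies roughly
  matching family sizes in a large cereal genome (scaffold enzymes ~0.4%,
  kinases ~5%, tailoring ~6%, TFs ~3%), with mild tandem correlation for
  the large families.
- **Expression**: Gaussian on the log2 scale —
  `mu_g + sqrt(rho)·f_module + sqrt(1−rho)·noise_sd·eps` plus an
  `effect_size` shift (default 3, in log2 units ≈ eigengene z-units at
  noise_sd 1) in treatment samples of the induced module — exponentiated
  to a TPM-like scale as `2^x − 1` clipped at 0.  The log-normal form is a
  stand-in: the real compendium's distributional detail is not modeled.
  All planted runs are assigned to a single induced module (default
  "ME25" of 40 modules); background genes are assigned uniformly.  Default
  design: 7 studies × (6 treatment + 6 control) samples.
- **Network**: a configurable number of shared TFs (default 21) with at
  least one edge into every planted cluster, partial TFs wired into proper
  subsets of clusters, and background edges onto non-cluster genes.
- **GO**: random background terms plus a defense-response term planted on
  shared-TF targets with high probability.
- **Proteins**: homoeolog families diverged from a uniform-random ancestor
  by independent per-site substitution (uniform over the 19 alternatives),
  so expected pairwise identity is (1 − m)².

What the model does **not** capture: read-level sequencing noise, batch
and tissue effects, correlated module membership along chromosomes beyond
the planted runs, realistic protein composition or indel evolution, and
the many-to-many homology of real gene families.  Passing the planted-truth
tests therefore demonstrates that the pipeline's logic recovers the
structure it is designed to find under its stated statistical assumptions —
not that those assumptions hold for any particular real compendium.

## Scoring planted recovery

A candidate matches a planted cluster when its member set *contains* the
planted members: mining may legitimately extend a run by a boundary gene
that happens to fall in a selected module, and such a call still identifies
the cluster.  Precision counts matching candidates; recall counts distinct
planted clusters recovered.  At the default validation scale (5 × 2,000
genes, 40 modules, effect 3) the full pipeline achieves perfect precision
and recall in ≥ 95 of 100 seeds; the rare misses are single chance
background runs that contain a scaffold and a tailoring gene — the same
false-positive mode a real analysis would face and then triage manually.

## Numerical and reporting choices

- Coordinates are 1-based inclusive (GFF3 convention); strand is stored
  but unused by mining.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); no global RNG state.  Fixed inputs, config
  and seed give byte-identical outputs.
- Report tables are TSV with fixed column order and floats at 6
  significant digits; the run summary is JSON with sorted keys.
- Degenerate inputs (zero-variance studies or genes, empty candidate sets,
  empty networks) produce warnings and empty results, not errors; a truly
  invalid input (negative expression, duplicate ids, missing metadata)
  raises with the offending record named.
- Validation problem sizes (10,000 genes, 84 samples, 50–100 repeated
  seeds, 200–500 oracle instances) were chosen to exercise the method's
  behavior convincingly at desk scale.

## Known limitations

- The enrichment stage tests the pooled shared-TF target set; per-TF
  enrichment tables are available through the library but not summarized
  in the pipeline report.
- Synteny block extraction is greedy longest-first; anchors shared between
  two equally long chains are assigned to the first extracted.
- RBH at hexaploid whole-genome scale is out of scope by design — callers
  supply candidate-region protein sets.
- The family vocabulary is keyword-based; annotations whose enzyme labels
  deviate from it need a custom mapping.
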