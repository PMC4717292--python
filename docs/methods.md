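# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of `mycolink`.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Bootstrap expression quantification

An "all alignments" aligner reports, per read, a set of candidate gene
models.  Treating the candidate set — not a placement — as the unit of
information, the quantifier resamples the `n` aligned reads with
replacement and, within each iteration, assigns every copy of a
multi-mapped read to exactly one candidate uniformly at random.  Per-gene
RPKM is `10⁹·count/(n·length)` with `n` the aligned reads in the sample
(library size is not recoverable from an alignment table).  The mean and
sample SD over iterations carry both counting and mapping uncertainty;
significance of expression is the probability mass at or below zero of a
normal with those moments, called at uncorrected `p < 1e-4`.

Conventions: SD = 0 with mean > 0 gives `p = 0`; SD = 0 with mean = 0
gives `p = 1` (the degenerate limit of the normal tail).  The exact
per-iteration multi-map rule of the original bootstrap tool is not
restated in its applications, so the random-single-assignment mode is the
normative one here — it propagates mapping ambiguity into the SD, which
is the point of the bootstrap — and a deterministic fractional `1/k`
split is available behind a flag.  Internally, reads are collapsed into
equivalence classes by candidate set; resampling is then a single
multinomial draw per iteration followed by binomial splits, which is
distributionally identical to read-level resampling and lets 10,000
iterations run as a few vectorised operations.

Quantile normalization maps every sample onto the cross-sample mean of
order statistics; ties receive the average target value over the tied
ranks, so constant columns are well-defined.  Matrix TSVs are re-read
with round-trip float parsing; the default pandas parser can be one ulp
off, which would break lossless export/import cycles.

## Filtering, fold-change profiles, clustering

Genes enter clustering when significantly expressed in **every** sample
and variable: coefficient of variation SD/mean > 0.33 computed on the
untransformed per-sample expression (CV is scale-dependent, so it is not
taken on the log scale).  Replicates are averaged per condition on the
linear scale; a gene's profile is `log₂(condition mean) − mean over
conditions of log₂(condition mean)`.  The baseline is the mean of the
log₂ values (a geometric-mean baseline): profiles then average exactly to
zero across conditions, which the correlation stage relies on.

K-means uses Euclidean distance on the profiles, k = 9 with 50 restarts,
keeping the best within-cluster sum of squares; deterministic for a fixed
seed.  k = 9 mirrors the nine co-regulation groups the study design
produces; no automatic k selection is attempted.  Cluster annotation and
motif enrichment share one kernel: the upper-tail cumulative binomial
`P(X ≥ x)`, `X ~ Binomial(n, f)`.  The printed form of that statistic in
the literature carries typographical artifacts; enrichment semantics
force the upper tail, which is what is implemented.  Two backgrounds are
used deliberately: term enrichment is computed against all annotated
genes (annotations "in the genome"), motif carrier frequency `f_M`
against the differentially regulated (filtered) gene set, per the
statistic's definition.

## Motif scanning

Motifs are IUPAC strings scanned for presence/absence only — match
multiplicity is ignored by design.  An `N` in the *sequence* is an
unknown base and satisfies only the motif symbol `N`.  Scanning is
forward-strand by default with a `both_strands` option (the reverse
complement of the pattern is scanned too); published strand conventions
for plant motif libraries are inconsistent, so the conservative literal
default was chosen.  Enrichment passes need `p < 0.01` **and** ≥ 10
carrier genes in the cluster; the carrier floor guards against motifs
that merely co-occur with a shared function.  A second evidence channel
reports, for each transcription factor inside a predicted sensor complex
whose TF class has a known binding motif, the carrier count of that motif
in each cluster linked to the complex; TF classes without a specific
motif (e.g. ERF, IAA-AUX) contribute nothing.

## Sensor-complex prediction

The co-expression network is rank-based: each allowed gene proposes its
top-5 correlated partners over the external compendium, a proposal
becomes an edge when the two-sided t-test on r (n−2 df) gives
`p < 0.01`, and the edge set is the union of proposals (a `mutual` flag
restricts to reciprocal ones).  Boundary ties rank lexicographically by
gene id for determinism; zero-variance genes are excluded with a warning.

LOI Z-scores: observed counts per unordered localization-pair over the
reference interactome (multi-label and pre-split compound labels
contribute every combination), against a configuration-model null — the
2E endpoint slots are randomly re-paired, preserving every protein's
degree in every iteration; self and multi edges are allowed in the null
as in standard configuration-model resampling.  `Z = (obs − mean)/SD`
with the population SD over 10,000 iterations; pairs whose null count
never varies get Z = 0.  Note a structural property the synthetic
generator has to respect: because degrees are preserved, each label's row
of the pair-count matrix has fixed sum, so a label pair scores Z > 0 only
when pairing is assortative *beyond* degree.  Protein localization is the
argmax of the per-protein score table; ties assign all tied labels, and
compound labels such as `nuclear:cytoplasm` split into both components.

Edges survive filtering when (i) both proteins are significant in every
in-house sample, (ii) both carry an allow-listed sensing/signalling
annotation (the allow-list is a required input; the generator ships an
example vocabulary), and (iii) the edge LOI — the maximum Z over the two
proteins' localization label pairs — exceeds 1.  Maximum, because an
interaction is possible if *any* compatible localization pairing supports
it.  Connected components of size ≥ 2 are reported as candidate
complexes (pair-only components are legitimate; most published
subnetworks are pairs) with roles assigned by annotation precedence
receptor > transcription factor > defense > cascade.

## Metabolic turnover (PRMT)

UEF abundance is the summed quantile-normalized RPKM of the gene models
carrying an EC annotation; a gene with several EC labels contributes its
full value to each.  The reaction table is restricted to allowed
pathways; `weight(e, m)` is (appearances of m as reactant − as product)
over e's kept reactions, divided by e's number of kept reactions so that
an enzyme's influence does not scale with its reaction multiplicity (the
unnormalized sum is available behind a flag).  Per condition,
`Δe = log₂ abundance − cross-condition mean of log₂ abundance`; the log
floor is half the smallest positive abundance, so unexpressed-in-one-
condition enzymes stay finite.  The score is the per-metabolite mean of
`w·Δe` over expressed enzymes touching it — the per-metabolite mean keeps
scores comparable across metabolites of different connectivity while
preserving the sign semantics (positive = net consumption).  A reference-
condition baseline (e.g. free-living) is available instead of the
cross-condition mean.  Reversible reactions are scored as written.
PRMT is not flux balance: rates follow enzyme abundance, the metabolome
is treated as well-mixed, and no mass balance is enforced.

## Integration

Correlations are Pearson r between each metabolite's score profile and
each cluster's mean log₂ fold-change profile over the shared 8-condition
axis (host replicates averaged; ≥ 3 shared conditions required;
zero-variance profiles are recorded missing).  Strong links are the
pairs at or beyond the empirical 0.001 and 0.999 quantiles of the pooled
coefficient distribution — pooled, not per-cluster, as the literal
reading of "all possible correlation coefficients"; with fewer than
1/percentile pairs only the global extremes are kept, with a warning,
and a fully degenerate pool selects nothing.  Negative-r links are
flagged synthesis-coupled: increased predicted synthesis tracking
increased host expression.

Assembly rules: (1) complex → cluster on non-empty gene overlap, with the
shared genes as evidence; (2) metabolite → cluster for strong links,
routed through the cluster's linked complex — a strongly correlated
cluster with no complex keeps its edge flagged *dangling* with a warning
rather than being dropped, since the case is biologically open; (3) motif
edges from both evidence channels, labelled `complex_tf` vs `enriched`;
(4) cluster → phenotype for every enriched annotation term (p < 0.05).
Every edge carries exactly one rule and its evidence; assembly is a pure,
order-independent function of its inputs.  The model serializes to
GraphML (list attributes joined for interchange) and flat JSON.

## The synthetic world

The generator emulates the study design: conditions FL, 6 h, 12 h, 24 h,
48 h, 72 h, 96 h, Myc with replicate counts (2,1,1,1,1,1,1,2) — ten
transcriptomes per organism.  Defaults, chosen once as desk-scale study
conditions:

* **Host**: 600 genes; 9 planted clusters × 30 genes with distinct
  time-course shapes of amplitude 2.0 log₂ units; per-sample lognormal
  noise sd 0.25 log₂; one third of genes silent, so ~67 % are called
  significantly expressed, matching real root transcriptomes.  The nine
  default shapes are deliberately non-mirrored (max off-target |r| ≈ 0.77
  after centering): exact up/down mirror profiles would make
  metabolite–cluster couplings unresolvable in principle.
* **Motifs**: a PLACE-style library; cluster i's motif is inserted (a
  concrete IUPAC realization, at a random non-overlapping offset, forward
  strand) upstream of 80 % of its members and 5 % of others.  Short
  library motifs like CAAT occur upstream of nearly every gene by chance
  and serve as built-in negative controls.
* **Complexes**: four planted complexes (2 receptors, 2–4 cascades, 0–2
  TFs, 0–1 defense proteins) inside clusters 2, 5, 7, 9; sizes ≤ 6 so
  each member's top-5 compendium neighborhood covers all of its partners.
  Members co-express through a shared latent factor in the 60-sample
  compendium (loading 1.5, noise sd 0.5); receptors localize to the
  plasma membrane, cascades to the cytoplasm (one per complex gets the
  compound `nuclear:cytoplasm` label to exercise splitting), TFs to the
  nucleus.  The reference interactome (200 proteins, 600 edges) is
  block-assortative: signalling-route label pairs and organelle label
  pairs interact within their blocks, the blocks barely mix, and
  membrane–nucleus contact is disfavoured — organelle proteins carry real
  degree so that, under the degree-preserving null, the signalling pairs
  genuinely score Z > 1.
* **Symbiont**: 1000 genes.  Each of six planted metabolite links gets 3
  dedicated ECs × 2 genes whose expression tracks the linked cluster's
  profile; the link sign is carried by reaction direction (consuming vs
  producing the metabolite, with shared currency metabolites on the other
  side).  Background genes carry idiosyncratic per-condition variation
  (sd 0.5 log₂) in addition to replicate noise — without it, quantile
  normalization leaves a shared rank-shift as the only condition signal
  in every unplanted enzyme, and 1000 genes (not fewer) keep the
  normalization's order statistics smooth enough not to distort planted
  profiles.  Three links are consumption-signed, three synthesis-signed;
  two land in clusters without complexes to exercise the dangling-edge
  rule.  The background reaction table has 150 ECs, 320 reactions and a
  250-metabolite pool, 80 % of reactions in allowed pathways.
* **Alignments**: reads multinomial in expression × length, 20,000 per
  sample, 10 % listing a second random candidate gene.

What the generator does **not** emulate — hence what passing tests do not
show about real data: sequencing error and coverage bias; intron/isoform
structure; host background genes have flat condition profiles, so the
CV filter separates planted from background more cleanly than in a real
root transcriptome; the mycorrhizal samples are pure, not plant–fungus
mixtures; cluster profiles are exactly shared by members rather than
correlated families; reference-interactome noise is purely structural;
and KEGG-scale reaction networks are far larger and more reticulate than
the synthetic table.  Recovery results on this generator demonstrate
correctness of the inference chain, not its power on field data.

## Numerical conventions and degenerate inputs

Deterministic seeding throughout (`numpy.random.default_rng`; the world
generator spawns independent child streams per component, so regenerating
one component never shifts another).  Empty alignment tables quantify to
zero/non-significant; empty filter results, empty networks and empty
models are legal outputs; k > number of profiles, unmapped samples,
unannotated reference proteins and empty localization score maps are
rejected with diagnostics.  Bootstrap variance uses the ddof = 1 sample
SD with a guard at one iteration; exact-constant resamples yield SD
exactly 0.  Boundary ties in neighborhood ranking break lexicographically;
tie values in quantile normalization interpolate the mean-order-statistic
curve.

## Problem sizes

Test and acceptance runs use the default desk-scale world (600 + 1000
genes, 10 + 10 samples, 60-sample compendium, 10,000 LOI resamples,
10,000 bootstrap iterations on toy alignment tables, twenty seeds for the
end-to-end recovery); the full suite and the acceptance script each
complete in about a minute on one CPU.
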