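# Methods

## The problem and the model

A numt is a fragment of mitochondrial DNA inserted into the nuclear
genome. At the moment of insertion it is a snapshot of the
mitochondrial haplotype of its lineage; afterwards it evolves under the
nuclear regime — typically an order of magnitude slower, without the
mitochondrial AT compositional bias, without codon-level purifying
selection, and exposed to indels and segmental duplication. A clone
survey with conserved mitochondrial primers samples a mixture of the
contemporary ortholog and these nuclear copies. The package's job is to
separate the two, characterize the numts, and place them in time.

The time axis is resolved phylogenetically, not by a molecular clock:
co-analyzing numts with the orthologs of many taxa, a numt that
clusters with its own contemporary ortholog was inserted recently
(neonumt), one that branches off before other species' orthologs was
inserted before those speciations (paleonumt), and a clade consisting
only of numts from two or more species marks an insertion in their
common ancestor (synaponumt), whose age is bounded above by the oldest
fossil of the MRCA's group.

## Clone characterization

* **Screen.** A clone is a cloning error if its best gap-excluded
  identity to every reference sequence, over at least 50 comparable
  columns of an optimal global alignment, is below `min_identity`
  (default 0.60). This is a reproducible stand-in for the original
  survey practice of discarding clones with no BLAST similarity to
  insect mitochondrial genes. Note the default is comfortably above the
  ~0.25 identity of unrelated sequence but *can* exclude numts near
  saturation (p-distance ≳ 0.4, as the most ancient documented
  synaponumts are); lower it when such numts are the object of study.
* **Alignment.** Needleman–Wunsch global alignment (match +1, mismatch
  −1, gap open −4, gap extend −1) with free end gaps on the clone,
  since clones are sub-fragments of the gene (60–1,882 bp in the
  motivating survey). Biopython's deterministic first-optimal alignment
  is used; the classification is judged over the aligned overlap only.
* **Identical vs numt.** Identical means zero point mutations and zero
  indel events over the overlap. Anything else (that passed the screen)
  is a numt. Unique numts are byte-identical equivalence classes; the
  representative is the lexicographically smallest clone id.
* **Mutation counts.** Point mutations are differing unambiguous bases
  in ungapped columns. Each maximal gap run is one indel event; an
  event whose running net indel length is not ≡ 0 (mod 3) marks a
  frameshift. Stop codons (TAA/TAG under NCBI table 5; the table id is
  configurable) are counted reading the clone contiguously in the frame
  the ortholog induces at the start of the overlap, so codons
  downstream of a frameshifting indel are read in the shifted frame —
  the frame is always the ortholog's, never re-estimated from the
  clone, because a pseudogene has no frame of its own.
* **Distances and composition.** Uncorrected p-distance with pairwise
  deletion (gap/N columns dropped per pair). AT fraction over
  unambiguous bases. Bowker's matched-pairs symmetry test on the 4×4
  divergence matrix; degrees of freedom count only base pairs with
  n_ij + n_ji > 0 (the convention of the matched-pairs symmetry-test
  literature); df = 0 returns S = 0, p = 1. Pairwise deletion is the
  default for the test's site set; complete deletion can be had by
  degapping first.

## Tree inference

Distances are p or JC69 (−¾ ln(1 − 4p/3)), pairwise-deleted; JC69 is
capped at 5.0 substitutions/site from p ≥ 0.75, where the correction
diverges — relevant because paleonumts reach p ≈ 0.5. Neighbor joining
follows Saitou–Nei with the Q criterion, label-order tie-breaking, and
negative branch lengths clamped to zero with the deficit moved to the
sister branch (path lengths through the join are preserved). Bootstrap
resamples alignment columns with replacement; support is the percentage
of replicate trees containing each internal bipartition of the point
tree. The point topology is seed-independent. NJ replaces likelihood
inference as the built-in engine deliberately: it is deterministic,
dependency-free and adequate at survey scale, and the classifier
consumes any rooted Newick tree, so ML trees can be dropped in at that
interface. Leading/trailing gaps of short clones are treated as missing
data throughout.

## Numt classification

Operating on a rooted tree whose tips are labeled
`id|taxon|locus|role`:

1. Internal edges shorter than ε (default 1e-6) or with bootstrap
   support below `support_min` (default 50) are collapsed into
   polytomies, with the collapsed length added to child edges. Both a
   zero-length and a low-support reading of "polytomy" are therefore
   available, and ε = ∞ is a valid limiting case (every within-species
   numt becomes a neonumt at internal path 0).
2. A focal numt tip q is a **neonumt** iff (a) no other taxon's
   ortholog (nor the outgroup) branches off the path between q and the
   focal ortholog — i.e. they share a possibly polytomous clade not
   interrupted by foreign orthologs — and (b) the internal path
   (patristic distance minus both terminal branches) is ≤ δ (default
   0.02 substitutions/site). Otherwise it is a **paleonumt**.

   The internal path, not the patristic distance, carries the verdict
   on purpose: a recent insertion into a fast-evolving nuclear region
   has a long *terminal* branch but still attaches next to the
   ortholog, and must stay a neonumt. The survey this package models
   classified numts by visual inspection of 77 trees; δ and ε are the
   package's explicit, config-exposed operationalization, validated
   against simulator ground truth (not against the published eyeballed
   counts): on planted insertions at 0.1 vs 50 MY, truth concordance is
   ≥ 0.98 over 100 replicates at the defaults.
3. **Synaponumts** are maximal clades whose tips are all numts,
   spanning ≥ `min_species` species, with support ≥ `support_min` when
   supports are present; only candidates without a candidate ancestor
   are reported, so the output is non-nested. Multi-species numt clades
   with long terminal branches and weak support can be long-branch
   artifacts, which is why the support filter defaults on.
4. **Dating** selects the most specific fossil calibration row
   (smallest species superset; ties to the smaller maximum age) whose
   species set covers the clade, and reports its [min, max] MY interval
   as the maximum insertion age. An uncovered clade is reported
   uncalibrated rather than raising.

## The simulator

The generator emulates the study conditions of a PCR-cloning numt
survey; its defaults are those conditions, fixed once.

* Species tree: pure-birth (Yule) conditioned on the taxon count,
  rescaled to the requested root age; ultrametric, ages in MY.
* Sequences: HKY85 with exact per-branch transition matrices (expm of
  the scaled rate matrix, not event-by-event simulation). Mitochondrial
  regime: rate 0.01 subs/site/MY per lineage (the classic arthropod
  mtDNA figure), stationary frequencies A/C/G/T = 0.35/0.15/0.15/0.35
  (AT = 0.70), κ = 4. The ortholog lineage is substitution-only, with
  an optional (default-on) codon-aware rejection mask that reverts
  in-frame stops — a cheap stand-in for purifying selection keeping the
  gene intact. Nuclear regime after insertion: rate multiplier 0.1,
  uniform stationary frequencies, indels as a Poisson process
  (2e-5 events/site/MY, geometric lengths with mean 3), duplications at
  0.005 events/numt-lineage/MY.
* Insertion: Poisson at 0.02 events/lineage/MY; each insertion copies
  the mitochondrial state *at that moment* (the mito sequence is
  evolved piecewise through the insertion times of a branch, so numt
  and descendant ortholog share the pre-insertion history exactly). At
  each speciation a numt survives into each daughter with
  `retention_prob` (default 0.9); copies surviving in ≥2 species are
  truth-labeled synaponumt members. Planted insertions at chosen ages
  on a chosen lineage are supported for controlled experiments.
* Cloning: ~50 clones per taxon, ortholog with probability 0.6 else a
  numt proportional to copy number, and independent per-clone PCR
  errors, Binomial(L, 0.00015) — 0.0987 expected errors on a 658-bp
  COI barcode fragment. All randomness flows from a single seeded
  generator; a fixed seed gives byte-identical FASTA/TSV output.
* Truth classes use the terminal-branch convention: an insertion on the
  focal taxon's terminal branch is a true neonumt, anything older a
  true paleonumt. The two notions ("on the terminal branch" vs
  "clusters with the contemporary ortholog") diverge when terminal
  branches are tens of MY long; the validation experiments therefore
  take the focal taxon with the shortest terminal branch, so an old
  (50 MY) planted insertion is genuinely ancestral.

What the simulator does **not** model: insertion-site mechanism
(non-homologous end-joining, retrotransposon mediation), heteroplasmy,
chimeric clones, primer-site mismatch amplification bias, and rate
variation among sites. Passing tests on simulated data show the
pipeline recovers the generating process of this model; they do not
certify behavior under those unmodeled features of real data.

## Aggregation conventions

Cross-family summaries are unweighted means of per-family ratios
(mean-of-ratios, not ratio-of-sums): this is the convention that
reproduces the published per-gene summary percentages from the
published per-family rows (ratio-of-sums gives e.g. 57.96% rather than
60.55% for the COI identical fraction), and it weights families equally
regardless of cloning depth. Families with a zero denominator are
excluded from that mean only. Percentages are reported to two decimals
with half-up rounding. Note the bundled ND5 identical-fraction mean
recomputes to 59.73% from the per-family rows, 0.06 points away from
the published 59.67% — the discrepancy is in the source's own rounding
and is below every tolerance used here. Missing (family, locus) cells
are absent rows, excluded from means (hence 28/25/24 families per
locus).

## Validation experiment sizes

The calibration experiments run at sizes chosen as the package's
standard check: 1,000 sequence pairs for the Bowker type-I rate
(observed ≈ 0.04–0.05 at α = 0.05; slightly conservative, as expected
for sparse divergence matrices), 100 replicates each for classifier
concordance (6-taxon trees, 658 bp, planted insertions at 0.1/50 MY)
and synaponumt recovery (planted ancestral insertion, retention 1,
100-replicate bootstrap, detection requires a supported ≥2-species
numt-only clade).

## Known limitations

* The similarity screen can discard near-saturated paleonumts (see
  above); the threshold is exposed.
* Bootstrap requires a common alignment; clone sets with indels are
  handled by per-pair alignment distances, which yield trees without
  supports (the classifier then collapses on branch length alone).
* NJ is a distance method; for publication-grade trees substitute an
  ML tree at the Newick interface.
* Fossil dating bounds only the *maximum* insertion age; nothing in
  the method dates the insertion from sequence divergence.
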