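# Methods

## Family identification

Membership requires a homeodomain plus a dimerization/lipid-binding partner
domain: (HD ∧ HALZ) ∨ (HD ∧ START). Subfamily calls check the
motif-bearing rules first (III: HD+START+MEKHLA; II: HD+HALZ+CPSCE) and
fall back to the plain combinations (IV: HD+START; I: HD+HALZ), because the
rule sets are otherwise strictly nested. START takes precedence over HALZ
when both are present, matching the biology (subfamily III/IV proteins can
carry a zipper variant alongside START). The classifier is total: every
domain set maps to exactly one of I–IV or a rejection with a stated reason,
and rejected candidates are retained in the output log rather than silently
dropped. Real surveys contain members whose annotated domains disagree
with their phylogenetic placement; the classifier deliberately follows the
domain rules only, so such discordance surfaces in the logs instead of
being patched case by case.

Locus assignment filters alignments at aligned length ≥ 180 bp (the
query-cover floor implied by the ~60-aa homeodomain), identity ≥ 99 % and
E ≤ 1e-6, keeps each transcript's single best alignment (lowest E-value,
ties by higher identity then leftmost start — a deterministic ordering so
locus ids are reproducible), and merges best alignments on the same
chromosome that overlap by at least 1 bp, transitively. Coordinates are
1-based inclusive (BLAST convention); strand is ignored for locus identity.
A genotype-specific locus is one whose members all come from the focal
genotype.

GO summarization partitions annotated members into the seven cells of the
{BP, MF, CC} Venn diagram — each member falls in exactly one cell, so cells
are disjoint and sum to the annotated count — plus per-subfamily category
tallies.

## Ka/Ks and dating

NG86 counting. Synonymous sites per codon are the expected fraction of the
nine single-nucleotide mutation fates that preserve the amino acid;
mutations creating a stop codon count as nonsynonymous, which keeps
N + S = 3 × codons exactly (per-codon normalization to three sites, the
MEGA/Biopython convention). Site counts are averaged between the two
sequences, making the estimate symmetric under swapping. Codons differing
at k positions are resolved by equal-weight averaging over the k!
substitution orderings, excluding orderings that pass through a stop codon
(with a fallback to all orderings if every one is blocked, so differences
are never dropped). Raw proportions pN = Nd/N and pS = Sd/S receive the
Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p), undefined (flagged
saturated) at p ≥ 3/4. ω = Ka/Ks is flagged undefined when Ks = 0.

The method choice itself is a design decision: the upstream computation is
a counting-method Ka/Ks, and NG86 with Jukes–Cantor is the classical
default whose downstream arithmetic (ω and clock dates) reproduces the
published duplication report from its printed Ka/Ks values. γ-corrected or
maximum-likelihood variants are out of scope.

Dating uses the synonymous molecular clock T = Ks/(2λ), λ = 6.5×10⁻⁹
substitutions per synonymous site per year (the standard dicot rate), with
T reported in million years. Printed dates from 3-decimal Ks values carry
an implied ±0.039 MYA rounding tolerance at this λ.

Unaligned CDS input goes through a global codon-granularity
Needleman–Wunsch (+1 per matching nucleotide within a codon pair, −2 per
codon indel); gap columns and stop-codon columns are removed before
counting. Duplicate-pair selection ranks all sequence pairs by percent
identity over the ungapped alignment columns, deterministically.

## Expression breadth and the background contrast

A gene is called expressed when TPM strictly exceeds a threshold
(default 0; the threshold is configurable since real surveys rarely state
one). Breadth histograms conserve the gene count by construction.

The background contrast draws `n_boot = 20` random same-size gene sets
without replacement from the background pool (target genes excluded) and
compares the target's "expressed in ≥ 1 sample" count x with the bootstrap
counts via a prediction-interval t statistic

t = (x − mean) / (sd · √(1/(1−f) + 1/n_boot)),  df = n_boot − 1,

where f is the fraction of the pool used by each draw. The 1/(1−f) term
undoes the finite-pool variance deflation of without-replacement draws:
without it the test is anti-conservative whenever the draw is a
non-negligible share of the pool. A two-sample test on bootstrap replicate
statistics was considered and rejected: the target yields a single observed
count, and re-subsampling one fixed gene set underestimates the between-set
variance, which inflates the type-I error by an order of magnitude. The
calibration of the implemented test is verified by simulation (1000 null
replicates land within the exact binomial 99 % interval around the nominal
1 %). No multiple-testing correction is applied by default across the
threshold sweep; Benjamini–Hochberg can be layered on by the caller.

Age trends operationalize "regular variation with growth" as strict
monotonicity across the age-ordered samples plus a max/min fold span
≥ 2 (configurable). Sample grouping is agglomerative average-linkage
clustering on 1 − Spearman ρ between sample columns, cut to k groups, with
group labels renumbered by first appearance so the output is deterministic;
zero-variance samples get unit distance to everything, with a warning.

## Co-expression networks

Spearman ρ uses tie-corrected average ranks; two-sided p comes from the
t transform on n − 2 df (exact-permutation agreement at n = 8 is within
0.01). At least 4 samples are required; zero-variance genes are dropped
with a warning (genes expressed nowhere are constant, so the "expressed
somewhere" filter is subsumed). Edges are retained on p alone, both signs
of ρ, because only significance cutoffs — not |ρ| floors — are part of the
procedure being reproduced; this choice is recorded in output metadata.
Clusters are connected components (the minimal reading of network
"clusters"; Markov clustering would be a possible refinement but is not
implemented). Hubs are nodes with degree strictly greater than the
connectivity cutoff.

The tendency test sweeps thresholds in decade steps from 5.0E-02 to
1.0E-08 (the stated endpoints; the grid in between is a design choice),
recording target node/edge counts against 20 random same-size draws, with
the same corrected prediction t-test per threshold. Counts are
non-increasing as the threshold tightens, and tighter edge sets nest inside
looser ones — both properties are verified on random fixtures.

## qPCR stress response

Livak ΔΔCt: ΔCt = Ct_target − Ct_reference per replicate; ΔΔCt subtracts
the calibrator group's mean ΔCt (pH 6.0, the optimal growth condition);
fold = 2^−ΔΔCt. Group summaries use the geometric mean of replicate folds
(equivalently 2^−mean(ΔΔCt)), which makes the calibrator's mean fold
exactly 1 — an arithmetic mean cannot, by Jensen's inequality. Group-vs-
control tests are two-tailed Welch t-tests on the log-scale ΔΔCt values
(folds are log-normal under Gaussian Ct noise), with the star convention
\* p ≤ 5e-2 and \*\* p ≤ 1e-2. With three replicates, Welch runs on
roughly 2–4 degrees of freedom, so only large effects reach \*\*.

Hub coupling correlates per-replicate fold profiles across all
group × replicate values (n = 15, chosen for power); correlating the five
group means instead is available as an option since either convention is
defensible. The reference gene enters only through Ct_reference and is
never modeled explicitly; amplification-efficiency correction is out of
scope (no efficiency data).

Fresh-weight analysis reuses the same Welch machinery on per-flask gram
values.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic given (seed, parameters); every dataset is
emitted alongside its truth record.

* Domain tables plant the study-sized subfamily composition
  {I: 73, II: 13, III: 11, IV: 20} plus rejected candidates cycling
  through rule-violating domain sets.
* Candidate sets reproduce the three-method cardinalities 114/83/112 with
  a 117-id union and exactly one id exclusive to the second method.
* Alignment tables plant 64 loci (5 focal-genotype-specific) with decoys
  that each fail exactly one locus filter.
* CDS pairs place at most one substitution per codon, so the bookkept
  difference counts are exactly what pathway counting recovers; site
  counts recorded in truth come from the final pair. Targets are bounded
  below 0.7 and infeasible combinations raise.
* Expression matrices use a latent-factor Gaussian model exponentiated to
  positive TPM-like values; Spearman statistics are invariant to the
  monotone transform, which is why it suffices. A module gene is
  l·factor + √(1−l²)·σ·ε, so the expected pairwise rank correlation is
  ≈ l at σ = 1 and exactly 1 at σ = 0. Breadth classes are structural
  zeros, so the default TPM > 0 call is exact on fixtures. The ages-design
  default classes are {0: 22, 1: 18, 2: 11, 3: 19, 4: 47} (the two-age
  class inferred so classes with k ≥ 1 total 95 of 117); the background
  pool defaults to 1000 genes with 40 % expressed, mirroring the reported
  random-transcript contrast.
* qPCR tables follow Ct_target = Ct_reference + ΔCt_base − log2(fold) +
  noise with three replicates per pH group.

None of this simulates read-level RNA-seq, real transcriptome abundance
distributions, genome sequence context, or primer chemistry. Passing tests
demonstrate that the estimators recover planted structure under the
latent-factor / structural-zero / Gaussian-Ct models — not that real
ginseng data would yield the study's dataset-dependent counts, which
require the original transcriptome and genomes.

## Problem sizes and numerical choices

The validation experiments run at sizes chosen to exercise the statistics
meaningfully while staying cheap: exhaustive NG86 oracle over all
sense-codon pairs with ≤ 2 differences (~2100 pairs); the full 8! Spearman
permutation null; 200 random nesting fixtures; 1000 null replicates per
calibration check (pool sizes of 1000 and 300 genes); 100 seeds for hub,
Ks, fold and sign-pattern recovery; 50 seeds for sample-clustering
recovery. Floating comparisons in tests use 1e-9 absolute tolerance (1e-12
where exactness is structural). Ambiguity characters are rejected at
alignment construction; gapped or stop-containing codon columns are
dropped with a logged count at alignment time.

## Known limitations

* NG86 with equal pathway weights and Jukes–Cantor correction
  underestimates divergence at high saturation; saturated proportions are
  flagged rather than extrapolated.
* Connected components are a coarse notion of network clusters.
* The prediction t-test assumes approximate normality of bootstrap counts;
  with very small targets or extreme thresholds the counts are discrete
  and the test becomes conservative (sd = 0 cases degenerate to an
  equality check).
* The codon-aware aligner uses simple match/gap scores; for distantly
  related CDS pairs a protein-guided alignment would be preferable.
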