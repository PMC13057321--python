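# Methods

## Data model and conventions

A **clonotype** is one assembled TCRβ rearrangement, keyed by
`(V gene, CDR3 nucleotide sequence, J gene)` with gene-level names (allele
suffixes `*NN` stripped on read; family level additionally strips the
`-N` gene number). Duplicate keys in an input table are merged by summing
UMI counts, so parsing is order-independent. CDR3 nucleotide coordinates
run from the conserved V Cys codon through the conserved J Phe codon,
inclusive, matching the anchors of the segment library.

Functionality is decided from the CDR3 alone: *out-of-frame* when the
nucleotide length is not a multiple of three, else *stop-codon* when the
translation contains `*`, else *functional*. Out-of-frame sequences keep a
codon-by-codon translation with a trailing `_` for the partial codon, so
non-functional repertoires remain analyzable.

Insertion lengths come from explicit `vd_insert`/`dj_insert` columns or
from MiXCR-style junction reference points (`VEnd/DBegin/DEnd/JBegin`;
negative gaps clamped to 0; for D-less rows the single V–J run is recorded
on the VD side). When neither source is present the lengths stay *absent*
and insert-based features raise an error rather than fabricating zeros.

## The recombination model

Scenario probability factorizes as

    P(scenario) = P(V) P(D) P(J)
                  · P(del_V) P(del_D5) P(del_D3 | del_D5) P(del_J)
                  · P(ins_VD) P(ins_DJ)

- **Deletions.** Each end is truncated-geometric: `P(d) ∝ q^d` on
  `{0..cap}`, renormalized. Caps are `min(max_deletion, available)`; the V
  cap preserves the Cys codon, the J cap is the anchor offset (nothing from
  the Phe codon onward is removable), and the two D ends are drawn
  sequentially so their caps never overrun the segment. Defaults: `q = 0.4`,
  `max_deletion = 6`.
- **Insertions.** Run length is zero-inflated shifted-geometric:
  `P(0) = π₀`, `P(k≥1) = (1−π₀) p (1−p)^{k−1}` with `p = 0.3`; inserted
  bases are i.i.d. (uniform by default). π₀ is the single interpretable
  TdT-activity dial; the presets (preterm 0.45, term 0.15, adult 0.05) are
  this package's own calibration of "low / intermediate / high" TdT
  activity, chosen to produce a zero-insert clonotype fraction of roughly
  0.2 in fetal-like samples and near zero in adult-like samples, with a
  ~3 nt CDR3 length gap — the qualitative regime reported for human
  ontogeny. They are presets, not fitted values.
- **D-less rearrangement** is available through `d_skip_prob` (one V–J
  insertion run); it defaults to 0 and, when enabled, the Pgen sum includes
  the D-less scenarios.
- **Clone sizes and UMIs.** Rearrangements receive log-normal weights
  (σ = 1.0) and UMI counts are one multinomial draw, reproducing heavy-
  tailed clone-size dispersion under UMI counting. One seeded generator per
  simulate call; no global RNG state.
- **Selection.** The simulator applies no selection, so raw output is
  about two-thirds non-productive — useful for null checks (functional and
  non-functional V usage differ only by noise). `apply_selection`
  hypergeometrically thins non-functional UMIs to a target share (default
  0.08, in the range seen in naïve-subset mRNA repertoires) while leaving
  functional clonotypes untouched.

### Exact generation probability

`pgen_nt` sums `P(scenario)` over *every* decomposition of a query
sequence: V-prefix masses and J-suffix masses are accumulated per split
point, trimmed-D variants are grouped by their residual string, and the two
insertion runs account for the remaining middle segment. Scenarios are
mutually exclusive by construction (each fully specifies the junction
strings), so the sum is exact: on toy libraries it matches brute-force
enumeration to machine precision, and with insertions disabled the
probabilities of all generable sequences sum to 1. The model is
deliberately simpler than an IGoR/OLGA-parameterized human TRB model —
absolute Pgen magnitudes are not comparable to published values; only
ordering statements (e.g. matched public clonotypes have higher Pgen than
the repertoire average) are meaningful, and only those are asserted.

## Feature definitions

- **Non-functional fractions**: by unique clonotype and by UMI, over the
  full table.
- **Summary features** (functional clonotypes by default): mean CDR3 nt
  length, mean total insert size, zero-insert frequency. Weighting is
  unique-clonotype by default with UMI weighting available; published
  repertoire summaries rarely state their weighting, so both are exposed
  and the choice is part of the call signature.
- **Convergence**: distinct-nt / distinct-aa ratio among the top 3,000
  functional clonotypes by UMI count, ties broken lexicographically by
  nucleotide sequence for cross-platform determinism.
- **Downsampling** is multivariate-hypergeometric (without replacement);
  samples below the requested depth raise an error for the caller to skip.
- **Diversity**: observed diversity = clonotype count; normalized
  Shannon–Wiener = `−Σ f ln f / ln S`, defined as 0 at `S = 1`.

## Physicochemical profiling

The central CDR3 window of width *w* (default 5) starts at
`⌊(len−w)/2⌋`; clonotypes shorter than the window are excluded, never
padded. Kidera factors are averaged within the window, then across
clonotypes (UMI weighting by default). The binding-strength score counts
residues from {L, F, I, M, V, W, C, Y}; `count` is the default (an "average
number of strongly binding residues"), `fraction` is available because
germline CDR lengths differ between V genes. For CDR1/CDR2 the full
germline region is used (they are short); an optional symmetric trim is
exposed. Length-matched downsampling takes the per-length minimum clonotype
count across samples and draws exactly that many per length, so all outputs
share one CDR3aa length histogram.

## Overlap geometry and multivariate analysis

F2 is computed on the functional sub-repertoire with frequencies
renormalized within it (the analysis concerns expressed, selectable
receptors); keys are `(V gene, CDR3aa)`, so nucleotide variants of one
amino-acid clonotype pool their frequency. Non-overlapping pairs are
floored at F2 = 1e−12 (distance 12) to keep matrices complete for MDS
rather than dropping pairs. Classical MDS double-centers squared distances;
negative trailing eigenvalues are truncated at zero with a flag; axis signs
are fixed (largest-|coordinate| positive) for reproducibility. Feature PCA
z-scores each column (ddof = 1) and uses SVD with the same sign convention;
hierarchical clustering uses Euclidean distance with average linkage by
default (recorded in the output; the linkage is a convention, not a claim).

## Annotation matching

A clonotype matches an annotation when gene-level V names are equal, CDR3aa
lengths are equal, and Hamming distance ≤ 1 (default). "Mismatch" is read
as substitution-only — the conventional meaning in repertoire matching;
indels are excluded, which the length gate enforces. A clonotype counts
once per label regardless of how many annotation records it hits, so the
result is invariant to annotation duplication; labels are analyzed
independently. Cumulative frequency is within the functional
sub-repertoire; repertoires should be downsampled to a common UMI depth
upstream when comparing across samples.

## Group statistics

Kruskal–Wallis uses the tie-corrected H with a chi-square reference
(delegated to scipy; the all-identical-values case returns H = 0, p = 1).
The Dunn post-hoc z statistic uses joint mid-ranks with the tie term
`Σ(t³−t)/(12(N−1))` and two-sided normal p-values. FDR control is
Benjamini–Hochberg, applied across the feature family at the KW level and
separately within each feature's Dunn pair set; both adjusted families are
reported because the correct family depends on the question being asked.
BY is not implemented; BH is the default reported adjustment.

## What the synthetic cohorts do and do not show

The simulator reproduces the mechanisms that drive the developmental
signature — insertion scarcity shortens CDR3s, concentrates probability
mass on few sequences, and creates convergent and public clonotypes — so
direction tests (preterm-like vs adult-like ordering of zero-insert
frequency, CDR3 length, convergence, intra-cohort F2 distance, matched-set
Pgen) are genuine end-to-end checks of the analysis code. The synthetic
library is not IMGT germline, segment usage is uniform unless overridden,
thymic selection is reduced to a single thinning step, and there is no
HLA structure, subset identity, or antigen history; passing tests therefore
validate the pipeline's arithmetic and the qualitative mechanism, not
quantitative agreement with any human dataset.

## Problem sizes and numerical choices

Verification runs use deliberately modest sizes chosen as a package
default: cohorts of 10 samples at 3,000 rearrangements / 4,500 UMIs for
direction checks (4,500 matching the usual diversity-downsampling depth),
400/1,200 for the 200-replicate power sweep, 10⁵ rearrangements for
sampling consistency, 10⁴ per π₀ for the closed-form recovery, and 2,000
replicates for type-I calibration. Tolerances: exact identities at 1e−12
(pgen vs enumeration, statistic vs reference formula), probability
conservation at 1e−9, Euclidean MDS recovery at 1e−6, stochastic checks at
3 standard errors or 99% binomial intervals. Seeds are explicit everywhere;
a `SeedSequence` spawns per-suite children below 2³¹.

## Known limitations

- Pgen magnitudes are model-internal; no import of IGoR/OLGA parameters.
- The deletion law is independent truncated-geometric per end; real
  junctions show correlated trimming and P-nucleotides, which are not
  modeled.
- Amino-acid-level Pgen is available only by enumeration at toy scale.
- Annotation matching asserts sequence similarity to database entries,
  not functional antigen specificity.
- The packaged germline library is synthetic; analyses of real data should
  supply an IMGT-derived library in the documented TSV format.
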