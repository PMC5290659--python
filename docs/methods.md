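# Methods

`ugtevol` analyses families of duplicated protein-coding genes — the
motivating case is the plant family-1 UDP-glycosyltransferases (UGTs),
which carry the 44-residue PSPG signature box — by chaining duplicate
detection, Ka/Ks estimation, molecular-clock dating, motif windowing and
distance phylogenetics, and validates the whole chain on simulated
families with known history.

## Duplicate detection

All gene pairs are scored by global protein alignment (affine-gap
Needleman–Wunsch, BLOSUM62, gap open −11 / extend −1 — the classic
protein-search defaults; the aligner's parameters are configurable and
matrices can be loaded from NCBI-format files). A pair is called a
duplicate when each member is the other's top-scoring partner
(reciprocal best hits); equal top scores keep all tied pairs, and output
order is canonical in the gene ids, so results are independent of input
order.

Chance similarity is excluded by a score threshold calibrated at run
time: alignment scores of residue-shuffled sequence pairs (homology
destroyed, length and composition preserved) are collected and the
threshold set to their mean + 6 SD. Under a Gaussian tail that puts the
chance-pass probability around 1e-9, well below one in a million —
the same intent as a stringent BLAST E-value cutoff, without
re-implementing Karlin–Altschul statistics. Pairs are classified
intra-/inter-chromosomal from a (possibly partial) chromosome map;
genes without assignments yield `unplaced` pairs.

## Ka/Ks (NG86)

The estimator is the Nei–Gojobori (1986) "unweighted pathway" counting
method:

* **Sites.** For each sense codon, each of the nine single-nucleotide
  neighbours contributes 1/3 of a site, classified synonymous or
  nonsynonymous by the standard genetic code. Mutations creating stop
  codons are excluded from the count entirely, so S + N for a
  stop-adjacent codon falls slightly below 3 (the MEGA convention). Site
  totals are averaged over the two sequences.
* **Differences.** For a codon pair differing at k positions, the k!
  single-step pathways are weighted equally; pathways through stop
  codons are excluded and the remainder re-weighted. If no stop-free
  pathway exists (possible only for some 2–3-difference pairs), the
  column is skipped for that pair — from both the difference counts and
  the site counts, which keeps pS = Sd/S well-defined.
* **Correction.** Proportions pS = Sd/S and pN = Nd/N are corrected for
  multiple hits with the Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3);
  p ≥ 0.75 is saturation and marks the pair `undefined`.

Codon pairs reach the estimator via pairwise protein alignment projected
back to codons, with gap columns dropped per pair (pairwise deletion) —
the counting is strictly pairwise, so pairwise alignments are exactly
what it consumes.

Filtration before dating follows the usual practice for duplicate-age
spectra: Ks < 0.001 (indistinguishable from zero; allelic or assembly
noise) and Ks > 2 (saturated) are removed. Selection classes are
Ka/Ks < 1 purifying, > 1 positive, with an optional symmetric neutral
band around 1 (default 0: only exactly 1 is neutral; see *Parameter
recovery* for why tests use a finite band).

## Molecular clock

Retained Ks converts to divergence time by t = Ks/(2r)/10⁶ million
years, with r = 6.5×10⁻⁹ substitutions per synonymous site per year by
default (a standard plant nuclear synonymous rate; overridable per run
and recorded in the run metadata). The inverse k = 2rt·10⁶ calibrates
the simulator; the round trip is exact to floating-point precision.

## PSPG motif windowing

A position-specific log-odds profile (log₂ odds against a uniform 1/20
background, Laplace pseudocount 1) is built from user-supplied
44-residue seed motifs. Scanning slides the profile along the protein
and reports the best-scoring window above a threshold defaulting to 60%
of the profile's maximal self-score, with 1-based inclusive coordinates
(a window starting at 331 ends at 374) and up to 50 residues of flanking
context per side — the flank length is configurable, and the flanks feed
the reduced phylogeny. The profile is ungapped and fixed-length, which
matches how the PSPG box is used in practice.

## Phylogeny

Distances are p-distances (1 − identity over shared non-gap columns).
Neighbor joining follows Saitou–Nei with the Q-criterion, deterministic
tie-breaking (smallest index pair), standard branch-length formulas, and
negative length estimates clamped to zero with a counter — exactly
additive matrices are recovered perfectly. Bootstrap support resamples
alignment columns with replacement (seeded NumPy generator), rebuilds
the NJ tree per replicate, and reports the percentage of replicates
containing each internal split of the original tree. Fitch small
parsimony scores a tree by rooting it on a leaf edge (making every
internal node binary) and running the classic set intersection/union
pass per column; tree *search* under parsimony is deliberately out of
scope. Trees serialize to newick with supports as internal-node labels.

## In-silico splicing

For a single-intron gene the fused CDS is exon I + exon II (intron
coordinates are inputs, 1-based inclusive; no ab-initio intron
prediction). Four primers are designed: external forward/reverse = the
first/last 20 nt of the fused CDS (reverse complement for the reverse
primer), and two 30-nt internal chimeras straddling the exon–exon
junction: exon II-F = last 15 nt of exon I + first 15 nt of exon II on
the sense strand, exon I-R its reverse complement. Each exon must
therefore be ≥ 15 nt. Melting-temperature optimization is out of scope.

## Relative expression

The Livak 2^−ΔΔCt method: technical replicates are averaged on the Ct
scale, ΔCt = Ct_gene − Ct_reference within each sample,
ΔΔCt = ΔCt_sample − ΔCt_calibrator, fold change = 2^−ΔΔCt. The
calibrator's fold change is 1 by construction. Amplification-efficiency
(Pfaffl) correction is not implemented.

## The simulator and what passing tests mean

`simulate_family` evolves one random ancestor (uniform sense codons, ATG
start, terminal stop) along a comb genealogy: duplication times sorted
descending, each spawning a lineage that evolves independently to the
present; the true divergence time of two genes is the spawn time of the
earlier-spawned one. Per branch of duration t, single-nucleotide changes
are proposed uniformly (Poisson-distributed count) and accepted at
relative rates 1 : ω : 0 for synonymous : nonsynonymous : stop-creating
changes (for ω > 1 the rates are rescaled into [0, 1] and the proposal
budget inflated so synonymous calibration is preserved). The budget is
set so the expected number of accepted synonymous substitutions per
synonymous site between two lineages separated t MY ago equals
k = 2rt·10⁶ — the quantity the NG86→clock chain estimates. Realized
synonymous substitution counts match this calibration to under 1%.

A 44-residue motif can be embedded at a stated protein position; it is
written into the ancestor and held invariant during evolution (a
conserved signature), so every copy carries it exactly. The conserved
window consequently dilutes realized whole-gene divergence by roughly
its share of the sequence — at the default 500 codons this contributes
a few percent of downward bias to family-wide Ks, well inside the
dating-error budget the pipeline tests use.

The generator deliberately omits: insertions/deletions (so alignments
are trivially correct and alignment error is not probed),
across-site rate heterogeneity, codon-usage bias, transition/
transversion bias, recombination, and rate variation among lineages.
Passing the recovery tests therefore shows the estimator chain is
correct *under its own model assumptions*; it does not certify accuracy
on real data, where all of the above violations occur.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| n_codons | 300 (500 for family runs) | typical UGT CDS is ~1400–1500 nt |
| ω | 0.3 | family-wide Ka/Ks distributions of plant gene families peak around 0.3 |
| r | 6.5×10⁻⁹ /site/yr | standard plant synonymous clock rate |
| times_mya | 5, 15, 40 | spans recent whole-genome-duplication-scale to ancient family splits |
| motif length / position | 44 at residue 331 | the PSPG box geometry |

## Parameter recovery and numerical notes

* Selection-class recovery tests use a neutral band of 0.35 around
  Ka/Ks = 1. The band equals ≈1.75 sampling SD of the ratio estimate at
  the test condition (Ks 0.2, 300 codons, ratio SD ≈ 0.2 measured over
  200 replicates); with a zero band the neutral class is unrecoverable
  by any continuous estimator, and a much wider band would swallow the
  ω = 2 class.
* Ks histogram mode uses half-open bins [i·w, (i+1)·w) anchored at 0
  (default width 0.05), with a small tolerance on the bin index so
  boundary values land in their nominal bin despite float division;
  ties resolve to the lower bin.
* All stochastic components (simulator, bootstrap, threshold
  calibration) take explicit seeds; pipeline runs with the same
  configuration are byte-identical.
* The fractional-median length filter (default: drop proteins shorter
  than 0.5× the median) is iterated to a fixed point, because dropping
  short sequences can raise the median; iteration makes the kept set
  idempotent under re-filtering.
* Degenerate inputs: empty alignments, < 2 genes, < 3 taxa, stop-codon
  inputs to the codon counters, intron spans touching sequence
  boundaries, and missing reference/calibrator measurements all raise
  typed errors naming the offending stage in pipeline runs.

## Known limitations

* NG86's equal-weight pathway averaging slightly inflates Ks under
  strong positive selection: at ω = 2, Ks 0.2, 300 codons the upward
  bias is ≈5–7% (nonsynonymous multiple hits within multi-difference
  codons are partially assigned to synonymous steps). Under purifying
  selection — the regime of most duplicate-family data — the bias is
  negligible. Maximum-likelihood codon models would remove it but are
  out of scope.
* The clock conversion inherits every caveat of a strict clock; reported
  MYA values are only as good as the assumed r.
* Bootstrap support is computed on whatever columns are supplied; for
  fixed-length motif windows the effective number of informative columns
  is small and supports are correspondingly coarse.
* The duplication caller has no synteny or gene-structure awareness; an
  intron-count comparison can be applied downstream but no collinearity
  analysis is attempted.
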