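# Methods

This note documents the models and procedures `cepkit` implements, the
defaults it ships, and what its synthetic-data suites do and do not
demonstrate about real genomes.

## Motif model and weighting

The peptide domain is modelled as a width-15 position-specific
probability matrix (PSPM) over the 20 amino acids, estimated by weighted
column counting from a set of domain instances, with Dirichlet smoothing
`p_i(a) = (c_i(a) + κ·b(a)) / (W + κ)`. The default pseudocount is
`κ = 0.01 · n_sites` — the conventional light smoothing; the background
`b` is uniform (1/20) unless a motif file provides one.

Counting is weighted in two stages:

1. **Equalization.** Every genome assembly carries equal mass; within an
   assembly each ORF carries equal mass; within an ORF each domain
   carries equal mass. A genome with many paralogs, or a gene with
   tandem domains, therefore cannot dominate the model.
2. **Lineage decay.** Each domain's weight is multiplied by
   `decay^depth(organism)`, default `decay = 0.8` (a 20% reduction per
   internal node), where `depth` counts the internal nodes on the
   species-tree path from the root to the organism's leaf *including the
   root*. Counting the root makes the convention well defined on a
   two-leaf tree, where a single uniform factor applies to both leaves
   and cancels after the final renormalization — the convention is
   observationally neutral on balanced trees and only matters where tree
   depth is unbalanced, which is exactly the over-representation it is
   meant to discount. Final weights renormalize to sum to 1.

## Scoring and exact p-values

A window `w` scores `s(w) = Σ_i log2(p_i(w_i)/b(w_i))` bits. Its p-value
is the exact tail probability that a random background 15-mer scores at
least `s`, computed by dynamic programming: per-position scores are
discretized to a grid of width `g` (default: score range / 2¹⁴, i.e.
≥ 10⁴ bins) and convolved across positions. Per-position scores are
rounded **up**, so every window's discretized sum is ≥ its exact score
and reported p-values are conservative — they can only overstate, never
understate, the tail. Halving `g` must not (and, in the test suite, does
not) change any accept/reject decision at the scanning cutoff.
Thresholds at or below the minimum achievable score return exactly 1,
above the maximum exactly 0. The default scanning cutoff is
p ≤ 6 × 10⁻¹¹; at that stringency a 10-kAA background sequence yields an
expected ≈ 6 × 10⁻⁷ false windows, so any hit is effectively diagnostic.
Overlapping hits are resolved greedily by descending bit score (ties to
the leftmost offset) — one domain per window, matching the biology of a
non-overlapping excised peptide.

## Gene discovery

ORFs are maximal stop-free runs in all six frames, kept when ≥ 50 AA
(inclusive; runs abutting contig ends need no flanking stop; N-containing
codons translate to X and do not terminate a run, but any window
containing X scores −∞). After scanning, the start codon is chosen among
every in-frame ATG and every leucine codon (TTA/TTG/CTT/CTC/CTA/CTG —
non-ATG starts are documented in plants; the set is configurable)
upstream of the first domain: each candidate's downstream prefix is
scored by a signal-peptide scorer and the maximum-scoring candidate wins
if its score strictly exceeds 0.400, ties breaking 5′-most (longest
signal). The architecture is then parsed from the scorer's cleavage-site
call: NSS = cleavage length, variable region to the first domain,
C-terminal extension from the last domain to the stop (length 0 flagged
explicitly). Genes reachable from overlapping ORFs with the same CDS
span are deduplicated; output order is (contig, position, strand).

The signal scorer is a pluggable contract. The built-in heuristic scorer
combines the three classic signal-peptide features — positive charge in
residues 1–5, the maximal 8-residue mean Kyte–Doolittle hydropathy in
residues 6–20, and small residues (A/G/S/C/T) at the −3/−1 positions of
the best cleavage site searched over lengths 15–30 — through a fixed
logistic. It is a deterministic sequence-property scorer, not a trained
predictor; workflows with access to external predictions can supply them
via the table-backed scorer instead.

## Distances and family contrasts

Pairwise distances are maximum-likelihood branch lengths under the JTT
empirical substitution model: `t` maximizes `Σ_sites log[π_a P(b|a,t)]`
over gap-free columns, optimized by bounded scalar search on
`t ∈ [10⁻⁶, 10]` to 10⁻⁶ (upper-boundary maxima carry a saturation
flag). `P(t)` comes from the eigendecomposition of the reversible
generator built from the published JTT exchangeabilities and
frequencies, normalized to one expected substitution per site per unit
`t`. Alignments are Needleman–Wunsch with affine gaps (open 11, extend 1
in half-bit units) on the JTT log-odds matrix at `t = 1`; rate
heterogeneity across sites is not modelled.

Intra-organism pairwise distances (IOPDs) are distances between genes
(or 15-mer domains) of the *same* assembly, aggregated by plant family;
assemblies with fewer than two genes contribute nothing, and no
cross-assembly pairs enter. Because IOPD distributions are multimodal
and skewed, family comparisons rank-transform the pooled values
(midranks for ties) before Tukey's HSD on the studentized range; GC
contents are logit-transformed first, with the standard small-sample
smoothing `p ← (p(n−1)+0.5)/n` to keep boundary values finite. Type-I
error and power of both tests are verified by simulation in the test
suite.

## Orthology

Cross-organism similarities are Smith–Waterman bit scores with the same
JTT-derived matrix and gap costs. The reciprocal-best-hit graph connects
genes in different organisms that are each other's *unique* best hit
(ties yield no edge, keeping the procedure deterministic); the edge
weight is the smaller of the two directional scores. Pruning scans edges
in ascending (weight, gene-id pair) order and deletes the first edge
whose endpoints have different neighbor sets, restarting after each
deletion — the stricter reading of "repeat from the second step" — until
every edge is consistent; the surviving components are provably cliques.
Groups of ≥ 4 members are emitted (the threshold is configurable; both
"more than four" and "at least four" readings are supported). The
implementation is verified against an independent brute-force reference
on hundreds of random graphs and is invariant to input order.

## Sitewise dN/dS

Per-site selection is estimated by pathway counting. For every codon
site and sequence pair, expected synonymous and non-synonymous site
counts (per-position, stop mutations excluded and renormalized) and
pathway-averaged observed differences are accumulated. The
non-synonymous rate `dN` is computed per site, while the synonymous rate
`dS` is pooled over the whole alignment: synonymous changes are treated
as a site-independent neutral clock, mirroring how model-based per-site
dN/dS machinery shares the synonymous rate across sites. Per-site `dS`
was evaluated and rejected: it is dominated by the ancestral codon's
synonymous opportunity and makes per-site ratios uninterpretable. Both
rates receive a Jukes–Cantor multiple-hit correction.

Uncertainty comes from a bootstrap over *sequences* (pairs sharing a
sequence are strongly dependent, so resampling pairs understates
variance), summarized as a 95% BCa interval — bias correction from the
bootstrap CDF at the point estimate, acceleration from jackknife
skewness; plain percentile intervals measurably undercover for this
skewed ratio at ~20 sequences. Intervals are clamped to bracket the
point estimate. A site is flagged **constrained** when the interval's
upper bound is below 1. Sites with no observed changes report NA with an
uninformative (0, ∞) interval; an alignment with no synonymous changes
anywhere yields the +∞ sentinel at sites with non-synonymous changes.
This whole estimator is a deliberate, deterministic substitute for
Bayesian stochastic-mapping machinery: it is validated by simulation
recovery (flag sensitivity and false-flag rate under known per-site ω),
not by matching any particular posterior intervals.

Alignment columns entering dN/dS are first trimmed by a gap-score rule:
per-column gap scores (1 − gap fraction) are sorted and the threshold is
placed at the steepest drop between consecutive distinct values — a
documented approximation of gap-based ("gappyout"-style) trimming that
leaves gapless alignments untouched.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not real genome composition. Each family has founder NSS/variable/
domain/extension segments; each ortholog set descends from the founder
at the configured within-genome divergence (JTT, default 0.4
substitutions/site), and each species' copy descends from its set
ancestor at the ortholog divergence (default 0.05) — so intra-genome
distances track the divergence knob across the whole prepropeptide and
orthologs cluster tightly for RBH recovery. Genes are back-translated
(uniform synonymous codons, or GC3-biased with weight `exp(bias·GC3)`),
framed by stop codons, preceded by an in-frame pad of residues with no
Met/Leu codons so that even short genes sit inside a ≥ 50-AA stop-free
run (as in real genomic context) without adding start-codon candidates,
and embedded on either strand (probability 0.5) in i.i.d. background at
the configured GC (default 0.40). Canonical domains are
rejection-sampled to scan at p ≤ 6 × 10⁻¹¹ and NSS templates to score
> 0.8; the three decoy classes are rejection-sampled to violate exactly
one requirement each ("group II"-like domains to p > 10⁻⁸ under the
scanning PSPM, signal-less loci to fail start selection, domain-less
loci trivially). Defaults: 4 species, 5 ortholog sets, 2 decoys per
class per species, multi-domain probability 0.15, no-extension
probability 0.058 (matching the observed share of such genes in seed
plants).

The codon-alignment simulator for dN/dS proposes per-codon
Poisson-distributed mutations drawn uniformly from the codon's non-stop
single-nucleotide neighbors (stop mutations are treated as never
observed, consistent with the estimator's stop renormalization), accepts
synonymous changes always and non-synonymous ones with probability ω.
The default divergence of 0.7 proposals/codon/branch (≈ 0.9 nt
substitutions per codon between two tips) is the regime where per-site
counting has power without saturating the Jukes–Cantor correction.

**What passing suites do and do not show.** The suites demonstrate
correctness of the machinery — recovery when the scanning model is the
generating model, signal prefixes satisfy the scorer, and genes are
single-exon with clean stop-delimited context. They do not demonstrate
sensitivity on real genomes, where the motif model is estimated rather
than true, signal peptides vary beyond the heuristic's features, and
assemblies contain repeats, gaps and compositional heterogeneity.

## Numerical and design choices

* "Longer than 50 AA" is implemented as inclusive ≥ 50, and "above
  0.400" as strictly greater; both configurable.
* Lineage decay applies after the three-level equalization, followed by
  renormalization.
* The species-tree reader rejects a root with more than two children as
  an unrooted-convention error unless an intentional polytomy is
  requested (star trees in simulation).
* Supplementary-table parsing is header-map-driven (TSV/CSV exports);
  column layouts of real exports are supplied by the user.
* Coordinates everywhere are 0-based half-open on the forward strand;
  CDS spans and strings exclude the stop codon.
* Problem sizes in the default suites — 10 simulated datasets for
  recovery, 50 replicates × 500 sites for distance recovery, 1000/500
  null replicates for the rank/logit tests, 8–12 alignments × 50 sites
  for dN/dS calibration, 200 random graphs for the orthology oracle —
  were chosen to make the measured rates stable at the asserted
  thresholds.
* Pipeline outputs embed the tool version, a hash of the merged
  configuration and the seed in every table header; a rerun with an
  identical configuration is byte-identical.

## Known limitations

* The heuristic signal scorer is not a trained predictor; its 0.400
  cutoff is calibrated only in the sense that the simulator's templates
  and decoys separate cleanly.
* Pairwise ML distances ignore among-site rate variation and alignment
  uncertainty; saturated pairs are flagged, not resolved.
* The dN/dS estimator pools pairs on a star-like assumption and shares
  dS alignment-wide; lineage-specific synonymous-rate variation will
  leak into per-site ratios.
* The clustering-RBH method cannot separate in-paralogs that arose after
  the species splits; ties are dropped rather than resolved.
* The simulator has no indels within genes, no introns, no repeats and
  no isochore structure.
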