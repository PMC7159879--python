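# Methods

## The detection model

A conflict system is modeled as a gene-order grammar: an ordered list of
required component domains (e.g. VMAP → MoxR → vWA), an optional-component
set, and three conservation constraints. A candidate is any run of
consecutive genes around an anchor gene whose protein carries the
template's anchor domain (window: 5 genes per side, truncated at replicon
ends). A run matches when, read 5′→3′ on the coding strand — genomic order
for '+' runs, reversed for '−' runs — the required domains appear in
template order, each consecutive intergenic gap is at most `max_gap`
(default 70 nt, counted as nucleotides strictly between gene spans, floored
at 0 for overlaps), and all run members share one strand. A single protein
carrying two required domains in N→C order satisfies both roles, which is
how vWA–β-propeller fusions match. For mixed-strand runs (reachable only
when a template relaxes the strand constraint) the reading direction is
ill-defined, so both directions are tried.

Matched runs then face the cross-lineage filter: the orientation-normalized
tuple of member cluster identifiers plus strand pattern (the *signature*)
must occur in genomes from at least two phyla. Cluster identifiers come
from score-density single-linkage clustering of the run member proteins.
Overlapping matches of one template in a genome are deduplicated, keeping
the match with more optional components and breaking ties toward the
leftmost genomic position. Every emitted instance is re-verified against
all structural filters before being returned.

Effectors of an instance are the domains resolved C-terminal to the core
domain on the designated component (the vWA host in the ternary systems),
plus the domains of optional effector genes inside the run.

The eight shipped templates (`templates.json`) cover the ternary systems
(VMAP, iSTAND, FtsH, β-propeller), the GTPase-centric systems (GAP1-N1
with GASH, GAP1-N2 with FNIII, optionally a paralogous second DO-GTPase),
and the peptidase-regulated systems (NucA–trypsin, EACC1–caspase). Users
can supply their own template JSON without code changes.

## Clustering

Pairs are aligned with local Smith–Waterman under BLOSUM62 and affine gaps
in the NCBI 11/1 convention (a gap of length *g* costs 11 + *g*; Biopython's
`PairwiseAligner` is configured with open = −12, extend = −1 to express
this). Raw scores convert to bits with λ = 0.267 and K = 0.041, the
standard gapped-BLOSUM62 constants for these penalties. An edge requires
`coverage_a ≥ L`, `coverage_b ≥ L` (coverage = aligned residues over
sequence length) and bit-score density ≥ `S` bits per aligned column;
clusters are connected components; the representative is the longest
member (smallest id on ties). An exact prefilter skips pairs whose length
ratio is below L, since the longer sequence could never reach coverage L.

Two threshold sets are used, mirroring the two uses of clustering:
near-identity culling at L = 0.9, S = 1.89, and classification-level
grouping at L = 0.25, S = 0.8 (the looser set lets homologous components
keep one cluster through effector turnover, which changes protein length).
`S` is interpreted uniformly as bits per aligned column; a percent-identity
mode is available by flag for workflows that expect identity semantics at
low S.

A deliberate consequence of the cross-phylum filter: in very small genome
collections a genuinely planted system family may occur in only one phylum
and is then (correctly) suppressed. Detection statistics are therefore
quoted at the default study scale.

## Statistics

**Trait enrichment.** For each system, presence is per organism (≥ 1
instance). With q = trait-positive organisms carrying the system, m/n =
trait-positive/negative organisms and k = carriers, the reported p is the
upper tail P(X ≥ q) of the hypergeometric distribution, summed in log
space from `gammaln` terms (`logsumexp`), so extreme tails (log₁₀ p ≈
−150 and beyond) remain meaningful; `log10_p` is always reported alongside
`p`. Organisms flagged NA are excluded from both the universe and the
presence counts — including them among the negatives would bias the test.
A Benjamini–Hochberg column can be derived downstream; raw p-values are
reported. The module also provides margin inversion: given printed rows
(q, k, p) over a universe of known size, it scans all feasible integer
trait margins m and returns the least-squares fit on log p — used when a
study prints per-system results but not its trait margin.

**Positional clustering.** Normalized positions are anchor-gene stop
coordinates (strand-aware) over replicon length, binned into 20 equal
intervals over [0, 1]; χ² = Σ (Oᵇ − E)²/E with E = N/20, df = 19. An
optional folded mode maps x → min(x, 1−x) over [0, 0.5] to superimpose
symmetric replicon arms; the default is unfolded, treating the 20
intervals literally.

**Length peaks.** Histogram at 50-residue bins, 3-bin moving-average
smoothing, peaks as strict local maxima with height ≥ 5% of the sample.
These three constants are pragmatic choices for component-length scales of
hundreds to ~1500 residues.

**Entropy.** Column entropy uses base-2 logs over the 20 standard
residues, excluding gaps and X; columns more than 50% gapped are skipped
(common practice for domain alignments); profiles are unweighted, with
sequence weighting left to upstream alignment curation. Mean positional
entropy is the arithmetic mean of used columns.

**Rank-sum.** Two-sided Wilcoxon rank-sum: exact by full enumeration of
group assignments for combined sizes ≤ 12 (a permutation formulation,
hence valid under ties), otherwise the normal approximation with tie and
continuity corrections (scipy's asymptotic Mann–Whitney). The two routes
are cross-validated at the switch boundary; note the normal approximation
has an irreducible worst-case error of ≈ 0.015–0.04 against the exact p at
these sizes (established by exhaustive enumeration over all U values), so
agreement is asserted at 0.02 at combined n = 12, not tighter.

**Tree congruence.** Trees are consumed (newick), never inferred. Both
trees are pruned to shared leaves (≥ 4 required), treated as unrooted, and
compared by Robinson–Foulds symmetric difference, normalized by 2(n−3).

**Hit resolution.** A protein's architecture is the maximum-total-bit-score
subset of its domain hits in which every pair overlaps by ≤ 10 residues,
found exactly for ≤ 15 hits (ties broken toward higher-scoring, more
N-terminal hits) with a greedy fallback above that. Exact selection was
chosen over pure greedy because greedy is not optimal when one long hit
spans two shorter, jointly better hits.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes, at
a desk scale of 300 genomes × 200 genes by default (the full pipeline then
runs in about a minute on one CPU; tests use smaller collections chosen as
the package's own working sizes).

- **Gene geometry:** protein lengths from N(750, 200) nt / 3; intergenic
  gaps geometric with mean 30 nt; operon-like strand runs with 0.75
  persistence per gene.
- **Trait and planting:** multicellularity flags Bernoulli(0.277) — the
  fraction implied by inverting the published per-system association
  p-values over the 6956-organism universe; systems planted per genome
  with P(system | multicellular) = 0.3 and 0.02 otherwise; among planted
  genomes 36% receive a second, independently drawn paralogous system.
- **Planted blocks:** correct gene order on one random strand; internal
  gaps geometric (mean 20 nt) truncated at 70 so every planted instance
  satisfies the structural filters by construction (internal consistency
  is asserted at 100% in tests).
- **Proteins:** components are emitted from shared consensus sequences by
  independent per-site substitution — θ_fast = 0.25 for vWA/VMAP,
  θ_slow = 0.05 for MoxR and the housekeeping control family — so the
  ungapped stack of a family is its alignment. Effector complements are
  1 + Poisson(2) draws (mean 3) from a weighted 12-domain pool, fused
  C-terminally to the vWA host. Domain hits are emitted from the planted
  layouts with ±3-residue jitter, not from a simulated profile search.
- **EAD coupling:** with probability 0.9 per system-bearing genome, one
  EAD copy is fused to the VMAP component and a satellite gene carries the
  same EAD fused to an effector domain.
- **Positions:** anchor targets drawn uniformly or from the symmetric
  bimodal mixture N(0.33, 0.05)/N(0.67, 0.05) (default), emulating the
  two-arm bias of linear chromosomes; blocks are inserted at the gene
  index nearest the target, shifting to the nearest free slot when blocks
  would collide (so multi-system genomes can displace one block).
- **Decoys:** each decoy violates exactly one filter — an internal gap of
  120–300 nt, one flipped strand, or a single-phylum family (separate
  consensi, planted only in the first phylum) — so each filter's rejection
  is independently testable.
- **Determinism:** one numpy Generator seeded once, drawn in fixed stage
  order; a fixed seed yields byte-identical output files.

What the generator does **not** emulate: nucleotide-level evolution, codon
structure, indels within families, phylogenetically correlated gene
content, horizontal transfer, or realistic domain-hit noise
(false-positive/negative profile matches). Passing recovery tests
therefore demonstrate the correctness of the neighborhood logic and
statistics under the stated generative assumptions, not performance on
real annotation noise.

## Numerical choices and degenerate inputs

- Coordinates are 1-based inclusive throughout; '−'-strand genes keep
  start < end; the strand-aware stop is `end` on '+' and `start` on '−'.
- Alignment raw score ≤ 0 is treated as "no alignment" (zero columns and
  coverage).
- `p = exp(log p)` may underflow to subnormal/zero for astronomically
  small tails; `log10_p` carries the information in those regimes.
- Empty instance lists: effector distributions report NA means; the
  positional test refuses to run; enrichment reports NA for absent
  systems.
- All statistics are invariant to input ordering; clustering output is
  order-invariant by construction (connected components).

## Known limitations

- The scanner assumes domain hits are trustworthy inputs; no rescoring or
  e-value filtering is applied beyond hit resolution.
- The cross-phylum filter uses exact signature equality over run cluster
  ids; a shared-core relaxation is exposed via the classification
  clustering thresholds rather than a separate signature mode.
- Published per-system association p-values cannot be reproduced to
  printed precision from the printed counts alone: no single integer
  trait margin over the stated universe is consistent with all printed
  values simultaneously (the inversion utility quantifies this; the
  recomputed values land within about an order of magnitude on log p).
- BLASTCLUST's percent-identity semantics for low S is approximated by an
  explicit identity mode rather than an automatic S-dependent switch.
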