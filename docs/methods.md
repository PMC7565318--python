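# Methods

`lakescape` implements the analytical chain of a lake-scale landscape-genetics
study of a haploid organism (the motivating case is the lichen photobiont
*Diplosphaera chodatii* sampled around a boreal lake): aligned marker
sequences and a terrain model go in; haplotype networks, AMOVA/PhiPT tables,
Mantel isolation-by-distance tests over four hydrology-aware distance models,
and an AICc competition among landscape dispersal hypotheses come out. A
synthetic-lake generator stands in for field data so every stage is testable
offline.

## Sequences and genetic distances

Sequences are aligned, equal-length strings over `{A,C,G,T,-,N}`. Two gap
conventions are used on purpose, matching the tools of the tradition this
pipeline reimplements:

* **Haplotypes and mutational steps** treat the gap as a fifth character
  state: any single base change, insertion or deletion separates haplotypes,
  and the step distance between two sequences is the count of differing
  sites. `N` (or any unrecognised code) is missing data and the site is
  skipped for that pair.
* **Kimura 2-parameter distances** use complete deletion: every site holding
  a gap or `N` in *any* sequence is removed once, globally, before all
  pairwise comparisons. With transition proportion `P` and transversion
  proportion `Q` over the retained sites,
  `d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))`. Saturated pairs (non-positive
  logarithm argument) are flagged undefined rather than clamped — downstream
  consumers must decide, not inherit a silent cap.

Rarefaction (haplotype accumulation) uses the exact hypergeometric
expectation `E[H_m] = sum_h (1 - C(N-N_h, m)/C(N, m))`, computed with integer
binomials.

## Haplotype networks

Haplotype pairs within a connection limit `j_max` are grouped into networks;
inside each network the retained connections form a minimum spanning network
(Kruskal grouped by weight, keeping every tie at the minimal weight), and a
retained k-step connection is expanded through k-1 inferred intermediate
nodes so every drawn edge is a single mutational step. Full statistical-
parsimony loop resolution is deliberately not attempted: the published
network topologies this mirrors are tree-like, and the loop-breaking rules of
the classic TCS program are under-documented; the MSN keeps all co-minimal
alternatives instead.

The connection limit is either user-fixed (to match legacy TCS output when
known) or estimated: the probability that a pair differing at `j` sites is
parsimoniously connected is modelled as `r^j`, where `r` is the probability
that a differing site changed exactly once, computed under a Jukes–Cantor
correction of the observed mean pairwise divergence (per-site substitution
count Poisson(lambda), `lambda = -3/4 ln(1 - 4p/3)`,
`r = lambda e^-lambda / (3/4 (1 - e^{-4 lambda/3}))`). `j_max` is the largest
`j` with `r^j >=` the parsimony probability (default 0.95), at least 1 and at
most the alignment length. The estimator is monotone: longer alignments at
equal absolute divergence never yield a smaller limit.

The dominant haplotype of a network is the most frequent (ties to the lowest
haplotype index). Subnetworks are a documented heuristic: removing the
dominant node splits a network into branches, and branches with at least
`min_branch_size` observed haplotypes (default 3) are labelled N1-A, N1-B, …
by decreasing size.

## AMOVA and PhiPT

Single-level distance AMOVA with squared pairwise distances
`delta_ij = d_ij^2` (the convention of distance-based haplotype AMOVA):

    SS_total  = (1/N) sum_{i<j} delta_ij
    SS_within = sum_p (1/n_p) sum_{i<j in p} delta_ij
    SS_among  = SS_total - SS_within

with `df_among = K-1`, `df_within = N-K`, unequal-size coefficient
`n0 = (N - sum n_p^2/N)/(K-1)`, `Va = (MS_among - MS_within)/n0`,
`Vw = MS_within` and `PhiPT = Va/(Va+Vw)`. `Va` may be negative and is kept in
PhiPT (the reference tables print negative PhiPT next to a 0% variance
column); only the percentage display truncates at zero. The permutation test
reassigns individuals to populations with sizes preserved, one-tailed on
large PhiPT, `p = (#{PhiPT_perm >= PhiPT_obs} + 1)/(n_perm + 1)` (default 999
permutations), so `p` is never 0. The distance fed to AMOVA defaults to step
counts; K2P is selectable in the pipeline config.

## Mantel tests

The Mantel statistic is the Pearson correlation of the strict lower triangles
of the genetic (K2P) and geographic matrices; permutations jointly shuffle
rows and columns of one matrix; the alternative is one-tailed "greater"
because isolation-by-distance predicts a positive association (this also
reproduces the reference pattern of large p for negative r). An exact
enumeration (`mantel_exact_p`) over all `n!` relabelings serves as the oracle
for tiny inputs.

## Raster hydrology and the four distance models

The DEM (plain-text ESRI ASCII grid, planar metres, row 0 = north) is
processed with:

* **Priority-flood sink filling**, epsilon default 1e-5 m so flats become
  strictly drained and D8 directions are deterministic;
* **D8 flow directions** with ESRI codes (E=1 clockwise to NE=128), steepest
  drop/distance, ties to the lowest code, edge or nodata-adjacent cells with
  no lower neighbour becoming outlets (code 0);
* **Flow accumulation** as upstream contributing-cell counts (area = count x
  cellsize^2), computed in topological order with cycle detection;
* **Stream network extraction** at an accumulation threshold (pipeline
  default: 1% of draining cells — the reference study does not state its
  threshold), annotated with Strahler orders;
* **Shoreline extraction** tracing the cell-edge boundary of the single
  submerged 4-connected region as a counter-clockwise closed ring.

Sample sites snap to the nearest point of the shoreline or stream network
(ties to the lower segment index). The four distance matrices: Euclidean
(recorded coordinates), shoreline (shorter arc between snapped positions),
network Euclidean (straight line between network-snapped positions), network
path (undirected shortest path along segments, partial end segments
included; disconnected pairs get +inf flags, never silent substitutes).
Directed flow lengths are subsumed by the undirected path distance, which is
what the Mantel stage consumes.

## AICc competition

Each landscape hypothesis (a named partition of samples into K populations)
is scored from its AMOVA within-population sum of squares:

    AICc = n ln(SSw/n) + 2K + 2K(K+1)/(n - K - 1)

with `n` the number of sequences analysed for that marker (read from the
input, never hard-coded). `dAICc` and Akaike weights
`w_i = exp(-dAICc_i/2)/sum_j exp(-dAICc_j/2)` rank the hypotheses. K is the
number of populations the hypothesis defines, not the number of labels a
table caption lists. This AICc form reproduces the reference study's 12
printed AICc values from its printed mean squares to within the propagation
of their 3-decimal rounding (≈ n·0.0005/MS: ±0.03 at n=51, ±0.10 at n=79),
and its printed Akaike weights exactly to 2 decimals.

### A caveat on AICc-from-SSw under the null

Under an exchangeable (panmictic) null, `E[SS_within] = SS_total (N-K)/(N-1)`,
so `n ln(SSw)` *decreases* by roughly `K-1` as K grows while the penalty adds
`2K`: the net expected AICc difference favours the smallest-K hypothesis by
about 1.1 units per unit of K. Consequently the K=3 hypothesis wins the
competition in more than half of panmictic replicates for every
parameterisation of the synthetic generator we measured (54–98% depending on
the noise level) — model selection on unstructured data is biased toward the
coarsest partition, not uniform across hypotheses. The corresponding
acceptance test is kept faithful to the chance-level expectation and fails;
treat sub-chance uniformity as unattainable for this statistic rather than a
regression.

## Synthetic lake generator

`synth.make_lake_dem` builds a deterministic basin on a 260x140 grid of 20 m
cells (5.2 x 2.8 km domain): an elliptical lake of ~3.6 x 1.5 km below a
20 m reference water level, a semi-enclosed bay joined by a narrow channel,
two inflow creek valleys (east and north), and one outflow valley descending
from the west shore to the grid edge as the unique low exit — after sink
filling, >99% of lake cells drain through the outflow mouth. Valleys carry a
V cross-section so each hosts a single stream thread. 34 shoreline sites
(jittered regular spacing, >= 25 m apart, emulating the reference sampling
design) each contribute 3 replicate samples (102 sequences).

The four landscape hypotheses are assigned geometrically: bay, west outflow
cap, east inflow cap ("mistik"), north inflow arc ("twin"), remainder
middle; In–Out-Bay (K=3) merges non-bay sites into inflow/outflow halves;
Bay Topography (K=5) keeps all five regions; Hydrology (K=4) merges the bay
into the middle; Wind (K=4) replaces the middle with a central wind band and
reattaches out-of-band sites to the nearest inflow/outflow anchor.

Sequences follow a private-site mutation model: a random ancestral sequence
of length 607; each population centroid mutates Poisson(m_b) sites drawn
from a globally disjoint pool; each individual adds Poisson(m_w) private
sites. Because mutated sites never collide, expectations are closed-form:
E[steps] = 2 m_w within and 2 m_b + 2 m_w between populations, which the
tests verify to ±5%. Under `panmixia` m_b is forced to 0; under `ibd`
centroids are per site and carry a mutation count growing linearly with the
site's shoreline arc position (a linear, not circular, gradient — documented
simplification). Defaults m_b = 0.05, m_w = 0.8 were chosen once so that a
typical realization matches the magnitudes of the motivating study (mean
realized PhiPT ≈ 0.055 under the Hydrology scenario; ~57 haplotypes of 102
samples). What the generator does *not* emulate: homoplasy and recurrent
mutation, sequencing failure/error, within-thallus strain mixtures, and any
physical wind or current model — passing tests demonstrate the statistical
machinery, not realism of lake dispersal.

## Numerical choices and degenerate inputs

* Distances carry explicit units; mixing units is an error, undefined
  entries (K2P saturation, disconnected network pairs) are masked, and AMOVA
  and Mantel refuse masked inputs rather than guessing.
* PhiPT is NaN when `Va + Vw = 0`; Mantel r is NaN when a triangle has zero
  variance; permutation p-values use the +1 convention.
* All randomness flows through `numpy.random.default_rng(seed)`; fixed seeds
  give byte-identical generator output and identical pipeline tables.
* Problem sizes in the test-suite simulations (100 recovery replicates, 200
  panmixia replicates, 500 permutation-uniformity replicates, 50x50 random
  hydrology grids) were chosen as the smallest sizes at which the asserted
  statistics are stable.

## Known limitations

* The connection-limit estimator is a principled reconstruction, not a
  bit-for-bit clone of TCS 1.21; use `fixed_limit` to match legacy output.
* Subnetwork grouping is a heuristic on verbal criteria from the tradition
  it mirrors; `min_branch_size` is exposed.
* Single-level AMOVA only (one region); no hierarchical variance components,
  no diploid codominant F-statistics.
* Geodesy is out of scope: inputs are assumed planar metres.
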