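# Methods

## Scope and model of the data

`cytosynth` analyzes mass-cytometry (CyTOF) experiments in which live cells
are pulse-labeled so that three biosynthesis activities become measurable
channels alongside ordinary antibody markers: IdU (iodine channel) marks
nascent DNA, an anti-BrdU/BrU lanthanide antibody marks BRU incorporated
into nascent RNA, and an anti-puromycin antibody marks puromycin
incorporated by elongating ribosomes. The data model is an event table —
nonnegative ion counts per cell per channel — with channel metadata
(marker name, mass tag, and a kind: phenotype, biosynthesis, barcode,
bead, viability or signaling). Event order is meaningful; every filter
returns an index mask rather than a reordered copy.

All analysis statistics operate on the arcsinh-transformed scale
`y = asinh(x / c)` with cofactor `c = 5`, the variance-stabilizing
transform standard for ion counts. The pipeline keeps the master table on
the raw-count scale and each stage transforms its own working view:
clustering and pseudotime use transformed phenotype markers, the
Friedman–Rafsky test transformed biosynthesis channels, while IdU
positivity is defined on raw counts (see below). This avoids double
transformation while honoring the raw-count definition of the IdU rule.

## Synthetic data generator

The generator exists so that every downstream stage can be scored against
ground truth without external data. Counts follow a zero-inflated
log-normal–Poisson model: per event and channel, a latent intensity
`lambda = exp(Normal(log m, s))` around the population median `m` with
log-scale spread `s` (default 0.35), an observed count `Poisson(lambda)`,
and an extra point mass at zero by channel kind (3% for phenotype, 2% for
signaling, none for biosynthesis/barcode/bead/viability channels, whose
zeros already arise from the Poisson stage). This reproduces the zero mode
plus right-skewed positive mode of real ion-count channels. It does not
model acquisition-time Gaussian broadening of large peaks, channel
correlations beyond those induced by population structure, or cell-size
effects, so passing tests demonstrate algorithmic correctness on
realistic marginals, not performance on any particular instrument.

Structural features emulated, each carrying truth labels:

- **Cell-cycle phases** (G0/G1, S, G2, early M, late M) with the canonical
  marker code — CyclinB1 negative/mid/high for G0G1/S/G2, p-HH3 high in
  mitosis — and phase-specific biosynthesis: IdU elevated only in S
  (median 200 counts vs ~1 background, so the >10-count rule separates
  cleanly); BRU in mitosis at a configurable fraction (default 0.3) of the
  G2 median; puromycin reduced only in late mitosis (default 0.3); p-4EBP1
  maximal in early mitosis. Mitosis defaults to 2% of events, the rare
  transient state the method is meant to resolve.
- **Inhibitor dose–response** as a four-parameter Hill curve on the median,
  `m(d) = m0 * (floor + (1 - floor) / (1 + (d / ic50)^hill))`, with
  secondary targets carrying their own parameters (actinomycin D
  suppressing BRU; cycloheximide suppressing puromycin and, secondarily,
  BRU and IdU). The Hill form is the package's choice; only monotone
  dose-dependence of the median is asserted anywhere.
- **Palladium barcoding**, 3-high-of-6 channels giving 20 keys ("high"
  median 200 counts, "low" 0), with doublets formed by summing the channel
  values of two random events at a configurable rate.
- **Calibration beads** (high in all bead channels), cisplatin-positive
  dead cells, cleaved-caspase-positive apoptotic cells, +1-mass isotope
  spillover (`dst += Poisson(fraction * src)`), and an optional linear
  sensitivity drift over the acquisition used to exercise bead
  normalization. Instrument drift beyond one linear factor is out of scope.

Three scenario builders fix the study conditions. `cellcycle`: one
asynchronously dividing line, 100,000 events. `pbmc_timecourse`: six
barcoded stimulation time points (0, 0.25, 0.5, 1, 2, 5 h; 120,000 events
total by default) over seven immune populations, with immediate S6/4EBP1
phosphorylation, a BRU burst at 0.5–1 h returning to baseline by 5 h,
puromycin and CD69/cytokines rising only at 2–5 h, B cells highest in
baseline RNA synthesis and myeloid populations in baseline protein
synthesis. `marrow_hierarchy`: 13 populations (100,000 events; real marrow
studies of this kind run 3x larger) including erythroid precursors high in
all three channels, plasma cells with high puromycin/rRNA but background
BRU, and a B-cell continuum over a latent coordinate u ~ U(0,1): CD34
falls as CD19 rises, CD10 is lost late as CD20 appears, IgM switches on
with half-rise at u = 0.6, and a BRU burst peaks at u = 0.75 — after the
IgM onset, mirroring the transcriptional burst at the pro-/pre-B
coordination point. All generation is deterministic given a seed.

## Preprocessing

**Bead normalization.** Bead events are those with every bead channel
above a threshold (default 100 counts). The run is cut into windows
(default 5,000 events); each window's scale is the whole-run bead median
over the window bead median, averaged across bead channels, interpolated
over event index, and applied to all non-bead channels. This is a
deliberately simple per-window median scheme; it recovers global
sensitivity shifts and linear drift but not the finer smoothing of
dedicated normalizers.

**Debarcoding.** Per event the transformed barcode channels are sorted;
the top-k channels form the candidate key. Assignment requires an exact
key match and a separation (lowest "high" minus highest "low", transformed
scale) of at least 1.5; events failing the separation test are flagged as
doublets. No Mahalanobis refinement step is applied. The cutoff does all
the doublet work in a full k-of-m design — any top-k subset matches some
key — and is placed between the two separation regimes at the default
signal levels: singlet gaps sit near 4.4 transformed units (200-count
barcodes over zero), doublet gaps near 0.7 (a doubled barcode over a
single one) or less. There the scheme assigns >99% of singlets and rejects
~94% of doublets; the residual acceptances are mostly doublets whose two
cells share a barcode key, which are invisible to any combinatorial
debarcoder.

**Gating.** Ordered threshold rules (keep/drop/flag) on raw or transformed
values. Viability gates (cisplatin, cleaved caspase-3) default to Otsu
thresholds between the live and dead modes of the transformed channel,
since the criteria are qualitative ("cisplatin positive") rather than
numeric. Gating is idempotent and reports in/out counts per rule.

**IdU positivity** is `raw count > 10` — counts, never transformed values;
calling it on a transformed channel is an error. The threshold is a
config value: on real data it should be calibrated against an unlabeled
control, because baseline IdU incorporation varies by cell type.

## Clustering (SPADE-style)

Density-dependent downsampling retains an expected 15% of events: the
density score is 1/(distance to the k-th nearest neighbor) (k = 15; only
the ordering matters), and each event is kept with probability
min(1, TD/density) where TD is found by bisection so the expected kept
fraction hits the target. This inverts the density, so rare populations
survive. Kept events are agglomerated by average-linkage hierarchical
clustering on Euclidean distance in the transformed phenotype channels,
cut at the target node count (150 for blood, 175 for marrow); average
linkage is used in place of the original SPADE heuristic because it is
deterministic and standard, and downstream results depend only on the node
count. Node medians are computed over all channels, a minimum spanning
tree connects the nodes, and every event (including dropped ones) is
assigned to the nearest node median (ties to the lowest index).
Biosynthesis and signaling channels are excluded from clustering and used
only for per-node statistics. Nodes are annotated into populations by
ordered first-match rules on node medians (marker high/low with a
threshold, default 2.5 transformed units ~ 30 counts). Exact average
linkage is quadratic in memory; at the default 15% of 100,000 events
(~15,000 retained) it needs ~1 GB and about a minute.

## Population statistics

Per-population activity is the median on the transformed scale; condition
effects are reported as the difference of transformed medians versus the
matched population in the control condition (a log-fold-change analog —
where a "ratio" of transformed values appears in figure legends, the
difference of arcsinh medians is the implemented quantity, following the
methods wording). Populations sharing an annotation are pooled across
nodes before medians are taken. A population absent at a condition yields
a missing value, not zero.

IdU-positive fractions are reported per population; the positive/negative
split is emitted only when more than 4% of the parent is positive.

Uncertainty is the ordinary nonparametric bootstrap of the median:
R = 1000 resamples of size n with replacement, percentile CI at 95%
(the percentile flavor is recorded in output metadata; other bootstrap CI
families would be equally defensible). Deterministic given a seed.

Friedman–Rafsky p-values are displayed with the star convention
`*` for 1e-14 < p < 1e-7, `**` for 1e-21 < p < 1e-14, `***` for
1e-28 < p < 1e-21, `****` for p < 1e-28.

## Friedman–Rafsky population-equivalence test

For two cell populations compared on the transformed BRU/puromycin plane:
pool the events, build the Euclidean minimum spanning tree, and count
cross-population edges R. Under the permutation null (labels assigned
uniformly given the tree), E[R] = 2*n1*n2/n, and the conditional variance
given the tree's degree structure is

    Var[R] = (2 n1 n2)/(n(n-1)) * [ (2 n1 n2 - n)/n
             + ((C - n + 2)/((n-2)(n-3))) * (n(n-1) - 4 n1 n2 + 2) ],

with C the number of edge pairs sharing a node. The standardized statistic
W = (R - E[R])/sqrt(Var[R]) is referred to the one-sided lower normal tail
(fewer cross edges = segregation = dissimilarity). Both moments are
verified against exhaustive enumeration of all labelings of fixed trees up
to n = 12 in the test suite; the enumeration oracle is part of the public
API (`fr_exact_null`).

The test subsamples: each of N iterations (default 100) draws S/2 cells
per population (default S = 200) without replacement, and the summary
probability of equivalence is the median of the per-iteration p-values
(mean and minimum are also reported). When a population has fewer than S/2
events, S is lowered to twice the smaller size with a warning. The MST is
built by Prim's algorithm on the dense distance matrix — O(S^2), no edge
sort — with ties between equal-weight edges (duplicate points) broken
deterministically by event index, with a warning.

Two calibration notes. First, the median-of-N aggregation is conservative
when the source populations are much larger than S/2: the iterations are
then nearly independent and the median of N roughly-uniform p-values
concentrates near 0.5, so small summary p-values require most subsamples
to agree. Rejection-rate calibration of the statistic itself is therefore
assessed in the regime where each subsample spans its source population
(populations of exactly S/2 events), where the summary p reduces to the p
of a single FR comparison; there the type-I rate at 0.05 is 4–5% and W is
standard normal to good approximation. Second, raising S or N for
genuinely different populations drives the summary p down (more events in
the MST increase |W|; more iterations stabilize the median), while a
self-comparison stays non-significant — the expected control behavior,
asserted as a monotonicity property in the acceptance suite.

No multiple-testing correction is applied across a comparison matrix (raw
binned p-values are reported); Bonferroni is available behind a flag for
users who want it.

## Pseudotime (linear trajectories)

A deliberately simplified, deterministic ensemble-graph pseudotime for
single non-branching lineages. A k-NN graph (k = 30, Euclidean distance on
the transformed trajectory markers) is subsampled into an ensemble of 20
graphs, each keeping a random l of each node's k edges; disconnected
components are bridged by their shortest connecting edge with a warning.
Per graph, shortest-path distance from the start cell initializes the
ordering, which is refined against 150 random waypoints by iterated
weighted averaging of waypoint-relative distances; weights fall off as a
Gaussian of graph distance to the waypoint (sigma = 20% of the trajectory
span) so that each cell is corrected mainly by nearby waypoints.
Refinement stops when the mean absolute change drops below 1e-3 of the
span or after 20 iterations. The ensemble mean is normalized to [0, 1]
with the start cell pinned at exactly 0. The start cell comes from a
predicate on markers (for the B lineage: the most CD34-high, CD19-low
event) or an explicit index.

Two parameters deviate from the commonly quoted ensemble settings as this
package's own choices: l defaults to 25 (not half of k) and the waypoint
weights are the Gaussian kernel above (not inverse distance). At
desk-scale lineages (3,000 cells, 5 markers) sparser 15-edge subgraphs
fragment the continuum and inverse-distance weighting lets distant
waypoints drag the ordering; the chosen defaults recover the latent
coordinate with Spearman ~0.95 versus ~0.90.

Channel trends along pseudotime are sliding-window medians: positions
evenly spaced in pseudotime rank, each taking the median over the window
fraction (default 5%) of cells nearest in rank, reported at the
pseudotime value of the position. Rank-based windows make trends depend
only on the ordering, so they commute with monotone relabelings.

## Numerical and engineering choices

- Per-stage seeds are derived from the single run seed by hashing the
  stage name, so inserting or skipping a stage does not perturb the seeds
  of later stages; all derived seeds stay below 2^31.
- FCS support is a minimal reader (FCS 3.0/3.1, list mode, float32/64) and
  writer (FCS 3.1, float32, little-endian) written for this package; truth
  labels travel in a `<file>.labels.tsv` sidecar, never in the FCS TEXT
  segment. Float32 storage bounds round-trip error at ~1e-3 counts for
  typical ranges.
- Degenerate inputs: singleton tables get a finite density via a distance
  floor; constant bootstrap samples collapse the CI to a point; an empty
  gate list keeps everything; a zero-spillover rule is a no-op.

## Limitations

Annotation rules assume the designed marker separations; on real data
they require per-panel tuning. The bead normalizer does not reproduce
dedicated tools' smoothing. The debarcoder omits Mahalanobis-distance
refinement. The pseudotime stage assumes a single linear trajectory — no
branch detection. Acceptance-style checks run at the desk-scale problem
sizes listed above; conclusions about real instruments, panels, or donors
require real data.
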