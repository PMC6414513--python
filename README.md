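# cytosynth

Analysis pipeline for single-cell mass-cytometry (CyTOF) experiments that
pulse-label the three biosynthesis activities of a cell alongside its
phenotype: IdU (5-iodo-2′-deoxyuridine, read on the iodine channel) marks
nascent DNA, BRU (5-bromouridine, read with a lanthanide-tagged anti-BrdU/BrU
antibody) marks nascent RNA, and puromycin (tagged anti-puromycin antibody)
marks nascent protein. One acquisition therefore answers, per cell: *what is
this cell, and how actively is it replicating, transcribing, and
translating right now?* — across cell-cycle phases, stimulation time
courses, and developmental hierarchies such as human bone marrow.

The package covers the full path from raw ion-count event tables to the
study-level results:

- **I/O** — FCS 3.0/3.1 and delimited text; YAML configs; ground-truth
  labels in sidecar tables.
- **Synthetic data** — a first-class generator producing labeled event
  tables with the signal structure the analysis assumes (cell-cycle
  phases, inhibitor dose–response, palladium barcodes with doublets,
  calibration beads, dead/apoptotic cells, isotope spillover, a B-cell
  developmental continuum), so every stage is testable without downloads.
- **Preprocessing** — bead normalization, single-cell debarcoding, the
  arcsinh transform, threshold gating, IdU positivity.
- **Clustering** — SPADE-style: density-dependent downsampling to 15% of
  events, average-linkage agglomeration to a target node count, minimum
  spanning tree over node medians, nearest-median upsampling, rule-based
  population annotation.
- **Population statistics** — transformed medians and shifts vs control,
  IdU-positive fractions with a 4% reporting rule, nonparametric bootstrap
  CIs (R = 1000, 95%).
- **Friedman–Rafsky testing** — MST-based multivariate equivalence of
  biosynthesis distributions between populations, with subsample-and-iterate
  sampling (S = 200, N = 100) and an exact enumeration oracle.
- **Pseudotime** — simplified ensemble-graph ordering of a linear lineage
  with waypoint refinement and channel trend curves.

## The statistics at the core

All statistics run on arcsinh-transformed counts, `y = asinh(x/c)` with
cofactor `c = 5`. Population activity is the transformed median; condition
effects are differences of transformed medians vs the matched control
population. DNA-synthesis activity is the fraction of cells with more than
10 raw IdU counts.

Population equivalence on the (BRU, puromycin) plane uses the
Friedman–Rafsky two-sample MST test: pool the two samples, build the
Euclidean minimum spanning tree, count cross-sample edges `R`. Under random
labeling `E[R] = 2 n1 n2 / n`, the variance follows the conditional formula
given the tree's degree structure, and
`W = (R − E[R]) / sqrt(Var[R])` is referred to the one-sided lower normal
tail — few cross edges mean the populations segregate. The test draws S/2
cells per population, N times, and summarizes with the median p across
iterations. Both moments are verified in the test suite against exhaustive
enumeration of all labelings of fixed trees (`fr_exact_null`).

## Worked example

Reproduce the cell-cycle analysis on a synthetic asynchronously dividing
cell line (20,000 events, cisplatin/caspase-gated, phases called from
CyclinB1 / p-HH3 marker gates):

```python
from cytosynth import pipeline

report = pipeline.scenario_report("cellcycle", seed=1, n_events=20_000)
print(report["phase_medians"].round(3))
```

```
            n    IdU    BRU  Puromycin  p4EBP1
phase
G0G1     9646  0.199  4.792      4.788   2.490
S        5470  4.377  4.780      4.780   2.475
G2       3171  0.199  4.786      4.805   2.490
M_early   202  0.198  3.566      4.815   3.836
M_late    151  0.199  3.501      3.646   3.197
```

Columns are transformed medians. Reading it: IdU is high only in S phase
(4.38 ≈ 200 counts, vs 0.2 ≈ 1 count background) — DNA synthesis is
confined to replicating cells. BRU drops from 4.79 in G2 to ~3.5 in
mitosis — RNA synthesis shuts down as cells divide — while puromycin stays
high in early mitosis and falls only in late mitosis (3.65), when protein
synthesis is finally suppressed; p-4EBP1 peaks in early mitosis (3.84),
the mTOR-driven state that keeps translation running. Mitotic cells are
~2% of events, the transient state the method is built to resolve.

The same entry point produces the stimulation-kinetics shift table
(`scenario_report("pbmc_timecourse", ...)`: an RNA-synthesis burst in every
immune population during the first hour that resolves by 5 h, protein
synthesis and CD69 rising at 2–5 h) and the bone-marrow tables
(`scenario_report("marrow_hierarchy", ...)`: per-population IdU fractions
with bootstrap CIs and the FR comparison matrix against HSCs, where the
HSC-vs-HSC control always carries the largest probability of equivalence).

A CLI mirrors the library: `cytosynth simulate | preprocess | cluster |
frtest | trajectory | run | report` (see `cytosynth --help`).

### Config files

Pipeline configs are YAML with these keys (all optional; defaults in
parentheses): `panel` — list of `{name, mass_tag, kind}` channel entries,
where kind is one of phenotype / biosynthesis / barcode / bead / viability
/ dna_content / signaling; `cofactor` (5) — arcsinh cofactor; `gates` —
ordered list of `{channel, op: gt|ge|lt|le, threshold, action:
keep|drop|flag, scale: raw|transformed}`; `barcode_keys` — list of
channel-name lists, one per sample, with `barcode_min_separation` (1.5);
`clustering` — `{channels, downsample_target: 0.15, n_nodes: 150,
density_k: 15}`; `stats` — `{bootstrap_R: 1000, ci_level: 0.95,
idu_threshold: 10, idu_report_min: 0.04}`; `fr` — `{S: 200, N: 100,
channels: [BRU, Puromycin]}`; `trajectory` — `{k: 30, l: 25, n_graphs: 20,
n_waypoints: 150}`; `scenario` — a synthetic scenario name for the
simulate stage; `stages` — the stage list for `run`; `annotations` —
population rules `{name, high, low, threshold}`; `seed` (0). Channels
referenced by gates, keys or clustering must exist in the panel.

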