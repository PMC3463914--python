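# Methods

## Data model

An expression table is a genes × zones matrix of RPKM values (reads per
kilobase of exon model per million mapped reads) over an ordered
developmental gradient; the default gradient is the four maize leaf zones
basal, transitional, maturing, mature, youngest to oldest. RPKM is
non-negative and spans orders of magnitude, so all noise modelling is
multiplicative on a log scale. Cells printed in source tables as "0*"
(hardly any or no expression) are stored as 0.0 with a per-cell
below-detection flag rather than an invented small value; the flag survives
write/read round trips, which are bit-exact (floats are serialized with
shortest-round-trip text).

Gene identity is the gene model, not the isoform symbol. The packaged
aquaporin catalogue therefore holds 32 records carrying 33 isoform names:
ZmPIP1;3 and ZmPIP1;4 share gene model GRMZM2G392975 and identical RPKM
rows, and `collapse_duplicates` merges such rows explicitly, refusing (never
averaging) rows that share an id but disagree on values. ZmPIP1;2 has no
published identifier and carries a flagged placeholder id.

## Profiling

* **Detection**: a gene is detected iff its maximum RPKM across zones is ≥
  `min_detect`. Default 1.0 RPKM — a conventional RPKM noise floor; on the
  packaged table every printed isoform has max RPKM ≥ 1.72, so the 24-isoform
  detection count is insensitive to any cutoff in (0, 1.72]. Tallies fold
  PIP1 + PIP2 into PIP, as family sizes are quoted.
* **Stage-silenced calls** ("specifically expressed in stage X" *sensu* the
  source study — note the inversion relative to ordinary usage): a detected
  gene is flagged for every zone where its RPKM < `low_threshold` (default
  1.0). Genes flagged in more than `max_low_zones` zones can be suppressed
  from reports; by default nothing is suppressed. The classifier is
  parameterised rather than hard-coded because no single threshold
  reproduces every published stage-specific list.
* **Fold change**: (RPKM_a + c)/(RPKM_b + c) with pseudocount c = 0 by
  default; a zero denominator yields +inf with an explicit flag instead of
  an arbitrary capped value.
* **Peak zone**: argmax over zones; ties break toward the younger zone and
  are recorded.

## Network construction

Pearson correlation between every pair of profiles; zero-variance profiles
have *undefined* correlation (carried as NaN, excluded from ranking, never
edges — a flat profile carries no pattern). Each gene sorts all others by
descending correlation, ties broken by ascending gene_id so results are
deterministic; rank(g,h) is 1-based and generally asymmetric. An edge needs
`cc > min_cc` (strict inequality) **and** the rank condition. The rank
condition is read as a disjunction — one gene within the `max_rank` most
correlated genes of the other — with a stricter mutual-rank
(`both_directions`) mode offered; at the default `max_rank = 50` on a
23-gene matrix the choice is inert. The ranking sorts raw pairwise
correlations; no averaged similarity score is interposed.

Defaults `min_cc = 0.95`, `max_rank = 50`. With only four zones per profile
the null distribution of the sample correlation of independent profiles is
uniform on [−1, 1] (density ∝ (1−r²)^((m−4)/2) with m = 4), so ~2.5% of
unrelated pairs exceed 0.95 by chance — the stringent floor is what makes
the regime workable at all, and this fragility is deliberately exposed by
keeping the zone count parameterisable. No p-values or FDR are computed;
negative correlations are never edges at the default floor and no
absolute-value mode is provided.

Implementation: correlation via vectorised numpy; graphs are networkx
objects; exports are Cytoscape-readable SIF (cc to 4 decimals), GraphML
with cc/rank attributes, and an edge-list TSV. Graph statistics (degree
distribution, mean clustering, per-component diameter and mean path length)
come from networkx.

## Modules

A module is a connected component of the thresholded network with at least
`min_module_size` (default 2) members; smaller components are reported as
leftovers, never dropped, so modules + leftovers always partition the node
set. Connected components are the minimal faithful reading at a 0.95
correlation floor; an average-linkage hierarchical alternative (scipy, on
correlation distance 1 − cc, cut at `n_modules`) is available behind a flag
for exploratory use, with undefined correlations placed at maximal
distance. Modules are labelled **early** when a strict majority of members
peak in the younger half of the zones, **late** for the older half,
**mixed** otherwise; each module also carries the per-zone mean of z-scored
member profiles (flat members contribute zeros).

On the packaged table the defaults yield a 10-gene early module, a 7-gene
late module and six leftover genes. The published bipartition of all 23
gene models (14 + 9) is not asserted anywhere: the original partitioning
method is unstated and may have used the genome-wide graph, so the module
report is emitted for comparison, not tested.

## Associations

"Exhibits the same expression pattern" between a query set (aquaporins) and
a target set (GO:0055085 transmembrane transporters) is exactly the network
edge criterion — no additional filter. Correlations and ranks are computed
over the full supplied matrix (both families plus any other genes),
matching the genome-wide framing; a pairs-only mode is deliberately not
offered. Query and target sets must be disjoint and resolve in the matrix.
Records carry cc and both directional ranks; the shared-target report lists
transporters tracking ≥ 2 aquaporins first (descending count, then id). GO
terms from the catalogue pass through as metadata; no enrichment statistics
are computed.

## Synthetic data

The generator emulates the structure the analysis assumes, and its defaults
are the study conditions: 4 zones; two anti-correlated prototypes (early:
monotone geometric descent 500 → 2 RPKM; late: its reverse — realistic
magnitudes spanning the printed table's range); 10 module genes per
prototype; 5 transporters per prototype generated from the prototype the
same way as module genes; 20 independent background genes (per-zone
log-normal, 2^N(4, 2)); multiplicative log-normal noise with σ = 0.05 on
the log2 scale per cell. A module/transporter gene is
prototype × gene-scale × noise with gene-scale 2^U(−2, 2). Everything is
drawn from one seeded numpy Generator, so a spec + seed is bit-reproducible.
Ground truth labels every gene (prototype index or background) and its role
(module / transporter / background).

What the generator does *not* emulate: count noise at low RPKM,
length/depth-dependent variance, correlated background structure, or more
than two expression programmes. Passing recovery tests therefore show the
method recovers clean planted structure in its own operating regime, not
that real gradients are this clean.

**Recovery scoring.** Module recovery is scored as the adjusted Rand index
between planted prototype labels and recovered module labels over the
prototype genes (module members + transporters). Background genes are
excluded from the score by design: with four zones the null correlation is
uniform, so ~2.4% of background–module pairs exceed the 0.95 floor by
chance and occasional background genes legitimately attach to a component —
the planted-structure question is about the prototype genes. At zero noise
recovery is exact (components equal the planted blocks); at default noise
the mean ARI over 20 seeds is required to reach 0.9 and in practice sits
at 1.0.

`perturb_gene` rebuilds one profile at an exactly prescribed correlation to
a reference: mix the standardized reference direction (weight ρ) with a
random centered direction orthogonal to it (weight √(1−ρ²)), then map
affinely (positive slope, correlation-invariant) back to non-negative RPKM
at the reference's scale. The realized sample correlation equals the target
exactly; the only failure mode is a flat reference, which raises a
calibration error.

## Pipeline and numerical choices

The CLI chains profile → network → modules → associate; every stage is
independently invokable, outputs are written atomically (temp file +
rename) so failures leave no partial state, and each invocation writes a
JSON manifest (config, package version, input SHA-256) for reproducibility.

Numerical details: correlations are clipped to [−1, 1] against floating
round-off; rank ties break by gene_id; module ordering is descending size
then lexicographically smallest member; association and report orderings
are fully deterministic. Problem sizes used in validation — brute-force
cross-checks on ≤ 12-gene random instances (200 of them), recovery over 20
seeds of the 50-gene default synthetic matrix — keep the whole suite and
the acceptance script in the low seconds while exercising every code path
at the scale the fixture data actually has.

## Known limitations

* Pearson on four points is intrinsically fragile; the package exposes the
  regime honestly rather than papering over it (no significance testing is
  attempted, matching the method being implemented).
* The 812-gene transporter catalogue and its 481 expressed members live in
  the article's supplementary download, which is not redistributed here;
  transporter-side analyses run on user-supplied or synthetic catalogues.
* Connected components at a hard threshold are a brittle partitioner near
  the threshold (one edge can merge two modules); the hierarchical
  alternative is provided for sensitivity checks.
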