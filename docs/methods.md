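# Methods

## Scope and model

`cnvnet` operationalizes a CNV-to-candidate-gene workflow for
neurodevelopmental disorder (NDD) cohorts: interval set algebra over
loss/gain calls, extraction and filtering of scored protein–protein
interaction networks, heat-kernel network propagation, a centrality-based
role taxonomy, and dosage-sensitivity-flagged candidate reporting. The
package does not call CNVs from raw array data, does not classify CNV
pathogenicity, and performs no live database queries; gene panels, dosage
scores and interaction networks always enter as user-supplied (or
synthetically generated) tables.

## Interval algebra

Coordinates are 0-based half-open throughout (BED convention); readers
accept 1-based inclusive input behind an explicit `one_based` flag. The
merge/intersect/subtract/overlap-join primitives are delegated to pyranges,
whose defaults match the bedtools behavior this workflow assumes:
book-ended intervals coalesce on merge, and one base of overlap suffices for
gene annotation (no minimum-overlap fraction is imposed).

Per-type merging deliberately drops sample identity: the cohort loss (gain)
track is the union over all samples. The three derived tracks are defined
set-theoretically — *shared* is the per-base intersection of the merged loss
and gain tracks, *unique loss/gain* are the per-base differences — so that
`unique_loss ⊎ unique_gain ⊎ shared` always partitions `loss ∪ gain`. Note
that the natural-language description of such workflows sometimes crosses the
tool names (subtraction described as yielding the "both" track and
intersection the "only" tracks); we follow the set-theoretic meaning of the
track names, which is unambiguous, and verify every track against a
brute-force per-base oracle in the test suite. Downstream stages default to
the unique tracks; the shared track is emitted as its own file for audit.

## Scored networks

Networks are undirected `networkx` graphs with a `confidence` edge attribute
in [0, 1]. Ingest uppercases symbols, drops self-loops, and keeps the
maximum confidence on duplicate pairs; no alias or ortholog resolution is
attempted. Confidence filtering *retains* edges at or above the threshold
(default 0.63, the HIPPIE medium-confidence operating point) and drops nodes
left isolated — the filtered interactome counts only connected genes.
First-neighbor extraction returns the induced subgraph on
`query ∪ neighbors` (neighbor–neighbor edges included) by default; an
`incident` mode keeps only query-touching edges. Query symbols absent from
the network are reported back, never fatal.

## Heat diffusion

Propagation uses the heat kernel `h(t) = exp(−tL) h₀` with `L = D − A` the
**unweighted** Laplacian (the cited diffusion tooling propagates on
topology; a confidence-weighted Laplacian is available behind the `weighted`
flag as an extension). `h₀` places unit heat on each seed. The kernel action
is computed with `scipy.sparse.linalg.expm_multiply` (truncated-series
algorithm); on graphs up to a few thousand nodes it agrees with a dense
eigendecomposition far below the documented 1e-8 tolerance. Because `L` is
symmetric with zero row sums, total heat is conserved and heat flattens to
`(#seeds in component)/|component|` as `t → ∞`; both limits are tested. The
diffusion time defaults to `t = 0.1`, the default of the diffusion app this
workflow emulates, since no other value is specified anywhere; it is a
config field.

Ranks are an ordinal permutation (descending heat, ties broken
lexicographically by node name; a tie at the selection boundary is logged).
Selection supports two cuts: `rank_cutoff` keeps ranks ≤ v (v = 99 → 100
genes, the "smallest" propagated interactome), and `output_size` keeps the v
hottest nodes, counting non-seed nodes and re-adding the seeds when
`include_query` is set (v = 310 is the documented operating point of the
larger propagated network). The source workflow reports an 824-node network
from the 310 setting; that number depends on its specific appendix networks
and cannot be reconstructed from counts alone, which is why both modes and
the seed-retention switch are exposed rather than hard-wired.
`include_query` intentionally does not affect `rank_cutoff`: in the 100-gene
subnetwork only a subset of the query genes appears, so seeds are evidently
not force-included there.

## Centrality and roles

Per node: degree; exact betweenness by Brandes accumulation, undirected and
unnormalized (a normalized variant exists for cross-network comparison
plots); closeness as `(reachable nodes) / (summed distance)` within the
node's component; and ASPL as the mean hop distance to reachable nodes.
Singletons carry undefined closeness/ASPL (NaN, never 0) and are excluded
from the medians.

Network-level thresholds follow the workflow's stated summarization: the
**mean** for degree and betweenness, the **median** for closeness and ASPL.
(That convention is statistically counterintuitive — means do not "minimize
outliers" — but it is applied as stated; `medians_everywhere=True` switches
all four thresholds to medians.) Threshold comparisons are boundary-inclusive
(≥, and ≤ for ASPL), since the taxonomy is defined with up/down arrows
rather than strict inequalities. Labels are a pure function of the profile
table and the fitted summary — node order never matters, and rescaling all
betweenness values by a positive constant leaves labels unchanged.

The classifier is packaged sklearn-style (`CentralityRoleClassifier` with
`fit`/`predict`, and `HeatDiffusion` with `fit`/`transform`) so both compose
with sklearn tooling; the rest of the pipeline is set algebra and stays
functional.

## Candidate report

Dosage flags are boundary-inclusive: haploinsufficiency at pHaplo ≥ 0.55 and
triplosensitivity at pTriplo ≥ 0.68 — the operating points this workflow
reports — with the stricter literature cutoffs (0.86/0.94) available as the
`strict` preset. Missing scores never set a flag and are listed in an audit
column. The headline flag pairs losses with the haplo flag and gains with
the triplo flag, but both flags are always computed. Diagnostic yield is
rounded half away from zero to a whole percent (9/29 → 31). The summary
block's distinct-node count uses inclusion–exclusion over the CNV-derived
and panel memberships of the propagated subnetwork and is asserted
consistent (`|A∩S∩P| ≤ min(|A∩S|, |P∩S|)`) on every output. Reports are
byte-stable TSV + versioned JSON.

## Synthetic data

The generator emulates the study conditions at desk scale, with one global
seed driving independent per-component substreams
(`SeedSequence(seed, component_key)`), so regenerating one component never
perturbs another and identical configs give byte-identical outputs.

* **Cohort** — 29 samples (the number passing QC in the emulated study),
  3 loss + 3 gain calls each on two chromosomes of 60 kb and 40 kb. Small
  chromosomes keep the per-base oracle exact and cheap; every call set is
  validated against it at generation time.
* **Loss/gain overlap** — unplanted calls are drawn in disjoint genome
  windows, so overlap fraction 0 guarantees an empty shared track; a planted
  fraction (default 0.25) of gain calls copies a distinct loss interval
  exactly, so fraction 1 with equal counts makes the unique tracks empty.
* **Network** — 300 nodes: two preferential-attachment communities
  (Barabási–Albert, m = 3) joined only through the planted bottlenecks.
  Each bottleneck attaches to the two top-degree nodes of each community
  (degree 4, all cross-community traffic → low degree, high betweenness).
  Each provincial hub anchors on a distinct community hub and duplicates
  eleven of its neighbors (degree 12 confined to one community; its links
  are redundant with the anchor's, so it brokers little). Each planted hub
  attaches to 15% of all nodes uniformly (degree ≈ 45, high betweenness) —
  note hub edges may themselves bridge the communities, so the
  "bottleneck-only joint" property holds for the construction before hub
  planting (and exactly when no hubs are planted). With these defaults the
  planted hubs classify as hubs and the bottlenecks as
  connector–bottlenecks in ≥ 90% of seeded replicates, which the acceptance
  suite measures over 50 seeds.
* **Confidences** — Beta(4, 2) per edge: the 0.63 filter then removes a
  nontrivial minority (≈ 35%) of edges, exercising the filter meaningfully.
* **Dosage scores** — pLI from a U-shaped Beta(0.3, 0.3), pHaplo/pTriplo
  from Beta(0.7, 0.7) (mimicking the bimodality of real constraint
  metrics, and in [0, 1] by construction), LOEUF and sHet log-normal.

What the generator does **not** emulate: real degree distributions of
curated interactomes (hundreds of thousands of edges), realistic CNV size
spectra or recurrence hotspots, correlated dosage scores, or genome-scale
chromosomes. Passing tests therefore demonstrate algorithmic correctness
and the recoverability of planted topology — not clinical performance on
real cohorts.

## Numerical and degenerate-input choices

* Diffusion tolerance 1e-8 (documented; measured agreement is ~1e-15);
  negative round-off heats are clipped at 0.
* Ties in heat ranking break lexicographically; boundary ties are logged.
* Empty call tables, empty networks, zero-gene configs and header-only
  reports are all valid and return typed empty outputs; zero QC denominators,
  start ≥ end intervals, out-of-range confidences and duplicate report
  symbols raise with context (line numbers where files are involved).
* Selection values beyond the node count select everything with a warning.

## Problem sizes

The default test suite and the acceptance script run interval-oracle
equivalence on 200 random call sets (chromosomes ≤ 100 kb), diffusion-oracle
equivalence on 40 graphs of ≤ 12 nodes, betweenness-oracle equivalence on
200 graphs of ≤ 8 nodes, and role recovery on 50 replicates of the 300-node
default network — sizes chosen so the full suite completes in about half a
minute on one core while still exercising every code path.

## Known limitations

* Symbol matching is exact after uppercasing; no alias resolution.
* Diffusion and centrality assume undirected, simple graphs.
* The intermediate network sizes of the emulated study (e.g. 3,106/4,320 or
  824/1,221 nodes/edges) depend on its private appendix networks and
  external services and are not reproduction targets of this package; the
  package reproduces the *procedures* and validates them against
  independent oracles instead.
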