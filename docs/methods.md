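# Methods

## Scope and model

`phytonet` implements the integrative screening chain used in
network-pharmacology studies of multi-component medicines: evidence
ingestion → target-space overlap → gene-set over-representation →
tripartite network topology → median-threshold screens. It deliberately
stops at the evidence layer: it does not identify compounds from raw
spectra, query live databases, or run docking engines — identified
components, predictions, disease-gene records, annotations, literature
counts and affinities arrive as plain tables, and everything downstream is
deterministic, auditable computation.

## Evidence ingestion

Tables are tab-separated UTF-8 with mandatory headers; thousands
separators in numeric cells are stripped. Gene symbols are upper-cased
before any set operation; no alias mapping is attempted, because the
screening chain being modelled performs none and silent re-mapping would
change set sizes untraceably.

A compound detected in both ion modes appears once downstream; its
response is the maximum across modes (configurable to sum or mean).
Maximum is monotone, invariant to mode order, and matches the convention
of quoting a single response per compound; sum would double-count
compounds ionising well in both modes.

## Target space

The Tanimoto cutoff is inclusive (≥ 0.7): a prediction scored exactly at
the cutoff is evidence, and the case-study tables include boundary scores.
Source-score thresholds are strict (>), applied per record before the
union, so a gene failing in one source can still enter via another. The
overlap of drug targets and disease genes is an exact set intersection —
ordering and duplication cannot affect it.

## Enrichment

The statistic is the hypergeometric upper tail P(X ≥ k), summed in
log-space from `scipy` log-pmfs; this is exact to ≥ 10 significant digits
for backgrounds up to 10⁴ (checked against exhaustive rational-arithmetic
summation for all parameterizations with N ≤ 30). The EASE variant
(tail at k−1) reproduces the deliberately conservative convention of the
DAVID service; the default is the plain upper tail. The default background
is the union of all annotation genes, configurable to an explicit
universe. Multiple-testing correction defaults to *none* because screening
studies of this type conventionally report raw p < 0.05 term counts;
Benjamini–Hochberg per namespace is available and recommended when the
term collection is large. Terms with zero query overlap are not reported.
Curated pathway selections (e.g. "the 34 disease-relevant pathways") are a
manual judgement; they enter as an explicit allow-list file, never
inferred.

## Network topology

The tripartite graph is undirected and unweighted; edges run only
component–target (a retained prediction whose target survived the overlap
and pathway coverage) and target–pathway (membership). Compound abundance
deliberately does **not** weight edges — it enters once, as the
quantitation screening criterion — because no principled weighting of
prediction edges by parent-compound abundance exists.

Centralities follow Cytoscape Network Analyzer conventions so values are
comparable with the published tables: closeness of v is (m−1)/Σd(v,u)
within v's connected component (0 for isolates; cross-component distances
are undefined, not infinite); betweenness excludes endpoints and is
normalised by 2/((n−1)(n−2)) with n the whole-graph node count. Both are
verified against brute-force oracles (hand-written Floyd–Warshall;
explicit simple-path enumeration) on hundreds of random graphs. Metrics
are computed on the whole graph; screening medians are then taken within a
partition.

## Screening

Degree comparators are strict (>) — consistent with a "greater than the
median" rule and with the case-study tables, where the smallest listed hub
degree (7) exceeds the stated median (6). Literature and response
comparators are inclusive (≥) — a compound whose study count equals the
bar is selected in the case study, which only an inclusive comparator
reproduces. All comparators and the 2-of-3 vote threshold are
configurable; tightening any single criterion can only shrink the
selection (property-tested).

The literature median is computed over the topology-passing candidate
compounds: the criterion exists to corroborate the topological shortlist,
so its bar is set within that shortlist. An explicit
`--literature-cutoff` override is exposed because the population for this
median is the one genuinely ambiguous choice in the chain. Missing
literature rows count as 0 studies. Medians use the standard convention
(mean of the middle two for even counts) and are always recomputed from
the inputs and printed in the report — published values are test
expectations, never constants in code.

Known limitation: one case-study compound (rutin: degree 7 vs component
median 8, 4 studies) is not derivable from the printed thresholds under
any comparator configuration; the package reproduces the *rule*, and the
reference tables transcribe the published selection as printed, including
three rows whose printed degree differs from their listed target count.

## Synthetic data

The generator emulates the statistical shape of a real evidence bundle:
heavy-tailed per-compound target counts (log-normal, mean 6, σ=0.6);
log-normal responses (μ=11, σ=1.5 — spanning two orders of magnitude, as
real response tables do); zero-inflated negative-binomial literature
counts (r=1, mean 3, 30 % extra zeros — most minor constituents are never
studied); source scores drawn on their native scales (GeneCards-like
0–30, DisGeNET-like 0–0.5) with passing/failing regions matching the
thresholds. Structural classes are drawn 45 % flavonoid / 35 % flavonoid
glycoside / 20 % other, echoing flavonoid-dominated extracts.

Planting is *guaranteed per planted unit*, not just in expectation:

* hub compounds receive at least multiplier × baseline-mean predicted
  targets (4 × 6 by default), with the heavy tail on top, and draw their
  literature counts from a plain negative binomial with mean 10 (the extra
  zero mass models unreported minor compounds, so it applies to the
  non-hub baseline only);
* planted hub targets are sampled preferentially by all compounds and are
  seeded into the drug–disease overlap first (the overlap fraction of the
  drug-target union, 0.2 by default, is unchanged; the remainder is
  uniform). Without this, planted truth is structurally unrecoverable
  downstream of the overlap filter and recovery scores measure nothing;
* planted enriched terms draw ~80 % of their members from the overlap.

The seed fully determines every output byte. What the generator does *not*
emulate: real mass spectra and retention behaviour (placeholders),
correlated target promiscuity across chemically similar compounds, gene
aliasing noise, and literature counts correlated with response. Passing
the recovery benchmark therefore shows the screening chain recovers
planted structure under realistic marginals — not that it is robust to
those real-data pathologies.

The recovery benchmark runs the full pipeline on 25 seeded default bundles
(80 compounds, 500 targets, 900 disease genes, 150 terms) and scores
planted-hub-compound recall under default 2-of-3 screening; these sizes
keep a full benchmark run in single-digit seconds while leaving non-trivial
per-bundle variability.

## Numerical and degenerate-input choices

Hypergeometric tails clip at 1.0 after log-space summation; k = 0 returns
exactly 1. Networks with fewer than 3 nodes have all-zero betweenness.
Empty median populations, degenerate (edge-free) networks, unknown
evidence sources, and conflicting module-label maps raise typed errors
naming the offender. Result ordering is fully specified (p-value then term
id; degree descending then node id; criteria count, degree, compound id),
so reruns are byte-identical; the run manifest records SHA-256 digests of
every input and output.

## Case-study replication levels

The packaged reference tables support desk-scale recomputation (hub screen
over the 31 transcribed targets; component degrees from transcribed
edges). Full replication — the 105-gene overlap, the 160-node / 729-edge
network, the 19 components above the degree-8 median — requires the
study's supplementary evidence exports, which are distributed only with
the study itself; the replication tests document the exact files and fail
with that explanation when the files are absent.
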