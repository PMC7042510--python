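# Methods

## Setting and model

The package analyses a two-condition transcriptome contrast — unstretched
control endothelial cells versus cells under cyclic circumferential
stretch — under the competing-endogenous-RNA (ceRNA) hypothesis: a lncRNA
carrying miRNA response elements sponges miRNAs away from their mRNA
targets, so a stretch-induced *loss* of the lncRNA frees miRNA
(miRNA up), which then represses its targets (mRNA down). Two observable
signatures follow and both are exploited: (i) directional consistency,
sign(lncRNA) = sign(mRNA) = −sign(miRNA) across the contrast, and (ii) an
excess of shared interacting miRNAs between the lncRNA and the mRNA.

## Differential expression

Per gene, a two-sample t-test on log2-normalized values with pooled
variance (Student form; Welch behind a flag for unequal variances),
log2FC = mean(stretch) − mean(control). Genes flat in both groups get
t = 0, p = 1. Benjamini–Hochberg FDR is computed jointly over all tested
genes of all three biotypes (a per-biotype mode exists); adjusted values
are reported but the selection gate uses the raw P by default, because
downstream network inclusion in this field conventionally gates on
FC ≥ 1.5 ∧ P ≤ 0.05. Published top-DE tables in this domain print the FC
column on the log2 scale while quoting the criterion on the linear scale
(their smallest retained |FC| values, e.g. 1.14, are only consistent with
the 1.5 cutoff as 2^1.14 ≈ 2.2), so `apply_de_filter` takes a linear-scale
threshold and applies |log2FC| ≥ log2(threshold). A zero log2FC is classed
Down for determinism; such rows can never pass the gate.

Normalization, when requested, is counts-per-million followed by
log2(x + pseudocount), pseudocount 1.0. The synthetic generator emits
log2-scale data directly, so the pipeline's defaults never depend on a
normalization guess.

## ceRNA pair selection

Candidate triples are enumerated from post-gate DE tables over the typed
interaction set and kept under the sign rule above (an orientation flag
restricts to the stretch-typical Down–Up–Down case). Triples are grouped
into (lncRNA, mRNA) pairs; each pair records

- its evidence set: the direction-consistent, differentially expressed
  shared miRNAs (gate: at least `min_shared`, default 1);
- the shared-miRNA hypergeometric test on the *full* interaction sets:
  with N background miRNAs, K partners of the lncRNA, n of the mRNA, k
  shared, the upper tail P(X ≥ k) (gate: default p ≤ 0.01; the recovery
  experiment uses 0.05). The background defaults to all miRNAs appearing
  in the interaction set — the sampling frame the interaction resource
  actually covers — and is configurable.

Two stricter, optional filters mirror what integrative ceRNA toolkits
apply: positive lncRNA–mRNA Pearson co-expression (r > 0, p ≤ 0.05 from
the t-transform with n−2 df), and the sensitivity correlation
senscor = r(l,m) − partial r(l,m | μ) averaged over shared miRNAs μ, with
the first-order partial correlation
(r(l,m) − r(l,μ)r(m,μ)) / √((1−r(l,μ)²)(1−r(m,μ)²)). Both are off by
default since the core selection criteria are directional consistency
plus shared miRNAs; whether the original analyses of this kind applied
them is generally not recoverable. A miRNA perfectly correlated with a
partner makes the partial correlation singular and is skipped with a
warning. Pair-level BH FDR on hypergeometric p-values is reported, never
gating. Output order is deterministic: p ascending, k descending, then
lexicographic.

## Network analysis

The pair table induces a tripartite graph: lncRNA/miRNA/mRNA nodes,
edges (lncRNA, μ) and (μ, mRNA) per shared miRNA, deduplicated; edges
within a biotype or lncRNA–mRNA directly are structurally impossible and
checked. "Hub" means plain degree (incident edge count) — the Degree
method of the usual network-analysis plugins; other centralities are out
of scope. The hub report takes the top k = 20 nodes with degree strictly
greater than 5, ranked degree-descending with the deterministic tie-break
biotype (lncRNA < miRNA < mRNA) then lexicographic id. The published hub
list bundled as a fixture follows no recoverable within-tie rule at
degrees 11 and 10, so the worked example asserts the printed order up to
ties (the first seven rows, with distinct degrees or lex-ordered ties,
reproduce exactly). The ego subnetwork of a lncRNA contains the center,
its miRNA neighbours, mRNAs adjacent to those miRNAs *within the ceRNA
network* (not the raw interaction set), and all induced edges; it is
idempotent and never reaches past graph distance 2.

## Enrichment

Over-representation analysis is the same upper-tail hypergeometric on a
gene-set collection supplied as GMT, with enrichment ratio =
observed/expected overlap = k/(n·K/N) as the ranking key (ties by p, then
term id). The background defaults to the union of collection members plus
the query; published term lists are annotation-version dependent and are
not a reproduction target.

## 2^−ΔΔCt

Relative quantification with amplification efficiency fixed at 2:
ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control,
RQ = 2^−ΔΔCt, replicates averaged on the Ct scale before differencing
(the common Livak convention). log2(RQ) = −ΔΔCt exactly and swapping
conditions inverts RQ.

## Synthetic data generator

Defaults emulate the motivating study design: 3 control + 3 stretch
samples; 50 lncRNAs, 100 miRNAs, 200 mRNAs; 20 planted triples. Baselines
are drawn uniformly in [4, 14] log2 units with Gaussian residual sd 0.3
(a realistic per-gene replicate noise for log-scale RNA-seq of cultured
cells). Planted lncRNAs shift by Δ = −2 log2 units under stretch; each
planted miRNA is its baseline minus β·(lncRNA deviation) plus noise
(β = 0.8), each planted mRNA its baseline minus β·(miRNA deviation) plus
noise — giving the negative couplings and the opposite group shifts the
ceRNA mechanism predicts. The interaction table holds the planted edges
plus Bernoulli(0.02) decoy edges over every non-planted (miRNA, target)
pair. One global seed drives four deterministic substreams (baselines,
planted-gene choice, noise, decoys), so outputs are bitwise reproducible.
Flags provide a Poisson count-scale mode (to exercise normalization) and
multi-miRNA triples (to exercise the hypergeometric gate).

What the generator does **not** emulate: library-size and GC artifacts,
batch effects, count overdispersion beyond Poisson, correlated null
genes, and the dense, hub-skewed degree structure of real interaction
databases. Passing recovery tests therefore demonstrate correctness of
the inference chain under the stated model, not performance on real
interaction resources.

### Power at the default conditions

Two analytic facts shape recovery at the default settings and are worth
stating because they are easy to miss. First, the mRNA leg of a planted
triple carries the doubly attenuated shift β²Δ ≈ −1.28 log2 units against
a marginal sd of 0.3·√(1+β²+β⁴) ≈ 0.43, so the pooled t-test at 3-vs-3
(4 df) detects it with probability ≈ 0.77 at p ≤ 0.05 — the per-triple
joint DE power is ≈ 0.75 even with a perfect interaction table. Second,
decoy edges give each planted lncRNA and mRNA about two extra miRNA
partners, so a planted pair typically presents (k=1, K≈3, n≈3, N=100)
to the hypergeometric test, whose tail probability ≈ 0.09 then exceeds
a 0.05 gate; cross-triple decoy-linked pairs (all direction-consistent
by construction) also contribute false discoveries. Measured recovery at
these conditions is accordingly TPR ≈ 0.1–0.35 with FDP ≈ 0.2–0.7,
and the acceptance suite records the measured values; under null
conditions (Δ = 0, β = 0) recovery collapses to zero, confirming the
chain manufactures no signal. Raising k_planted, lowering noise, or
shrinking the decoy rate moves recovery toward 1, but the defaults are
kept as the stated study conditions rather than tuned.

## Problem sizes and numerical choices

The test and acceptance workloads use: the full 350-gene default
generator config (recovery, 1 dataset + 20 null seeds), 2,000 null genes
for the type-I-error check, exhaustive hypergeometric enumeration for
all backgrounds N ≤ 12 (tests) / N ≤ 10 (acceptance script), 100 random
p-vectors of length ≤ 1000 for the BH oracle, and 200 random tripartite
graphs for the structural invariants — sizes chosen so the whole suite
completes in seconds while each check retains full coverage of its
parameter space. Oracle agreement is asserted to 1e-12 (the enumeration
is exact; differences are floating-point roundoff). Equal-mean,
zero-variance genes and zero-variance correlation inputs are handled by
explicit conventions (p = 1, r = 0 with warning) rather than NaNs.

## Known limitations

- Recovery metrics compare (lncRNA, mRNA) pairs only; miRNA identity
  within a recovered pair is not scored.
- The t-test assumes approximate normality on the log2 scale; with n = 3
  per group, count-model alternatives (negative binomial) would be more
  powerful for real count data and are out of scope.
- The hypergeometric background treats miRNA partners as exchangeable;
  real interaction databases are hub-skewed, which inflates k for
  promiscuous miRNAs.
- GraphML round-trips preserve node/edge sets and biotypes; other node
  attributes are not modelled.
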