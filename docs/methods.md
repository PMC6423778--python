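# Methods

## Detection model

Bead arrays report, per sample, a signal for every gene probe and a set
of negative-control beads measuring pure background.  We treat the
controls as an empirical null and define the detection p-value of gene
*g* in sample *s* as the add-one upper-tail rank

    p[g, s] = (1 + #{controls in s with signal >= signal[g, s]}) / (n + 1),

with ties counted as exceedances.  The add-one form keeps p strictly
positive; its granularity is 1/(n + 1), so the signature threshold
p < 0.001 is attainable only when a sample carries at least 999 control
beads.  The synthetic generator therefore defaults to 1000 controls,
and `BeadSummaryMatrix` warns below 100.

Detection p-values are rank statistics and should be computed on
signals that share a scale with the controls.  The pipeline computes
them on the **raw** matrix: background correction subtracts the same
per-sample constant from genes and controls and so cannot change the
ranks — except through its ε-floor, which piles sub-background values
onto one tied value and (under the ties-as-exceedances rule) pushes
roughly half of the null genes to p = 1, destroying calibration.
Corrected matrices remain valid input for callers who want them.

## Preprocessing

* **Background correction** subtracts each sample's median control
  signal and floors at ε = 1.0 signal unit so log transforms stay
  defined.  Median subtraction is the simplest defensible variant and
  is isolated behind one function so it can be swapped.
* **Quantile normalization** maps every column onto the row-wise mean
  of the sorted columns.  Tied values within a column receive the mean
  of the reference quantiles spanned by their ranks, which makes the
  result independent of input row order.  Rows of the sorted matrix
  that are constant map to that constant bit-exactly, so repeated
  normalization is a true fixed point.  Downstream clustering and
  heatmaps operate on log2(normalized + 1); detection p-values stay on
  the linear scale.
* **Group-level detection** reduces a group's per-sample p-values to
  one per gene under a single named policy — `max` (conservative for
  "expressed in the whole group"), `min`, or `single:SAMPLE` — applied
  uniformly to all groups rather than mixing directions silently.  The
  combined MSC reading pools fMSC and aMSC samples.

## Signature rule

    aging:        p_MSC < 0.001  and  p_iMSC > 0.1  and  p_iPSC > 0.1
    rejuvenation: p_MSC > 0.1    and  p_iMSC < 0.001 and  p_iPSC < 0.001

Inequalities are strict; the dead zone [0.001, 0.1] belongs to neither
set, and the contradictory MSC requirements make the sets disjoint by
construction.  Thresholds are parameters of `SignatureRule`.

## Differential testing

The default test is the classical pooled-variance two-sample t on log2
signals.  The moderated variant shrinks each gene's pooled variance
toward the across-gene mean variance s₀² with prior weight d₀ = 4 and
refers the statistic to t with df + d₀ degrees of freedom; this is an
empirical-Bayes stand-in for moderated linear-model statistics, and the
unmoderated test remains the default for reproducibility.  FDR control
uses Storey q-values: π₀ is estimated from tail counts
#{p > λ} / (m(1 − λ)) over λ ∈ {0.05, …, 0.95}, smoothed with a cubic
least-squares fit and read off at λ = 0.95 (clamped to (0, 1]);
Benjamini–Hochberg is available as an alternative and equals the
q-values at π₀ = 1.  Up/down calls require q ≤ 0.05 and a linear-scale
mean ratio strictly above 1.33 or strictly below 0.75; the significance
threshold is configurable because published analyses have used both
q ≤ 0.05 and p ≤ 0.01 gates.

## Clustering

Sample distances are 1 − Pearson r over log2 signals; trees come from
average-linkage agglomeration (complete/single/ward available).  Leaf
order is canonicalized by placing, at every internal node, the subtree
containing the smallest original leaf index on the left, so output is
invariant to sample order.  Trees serialize to Newick; cutting at k
clusters renumbers communities by first appearance.

## Protein-association networks

From a BioGRID-style table, rows are kept when both organism columns
equal the target taxid (default 9606); symbols are uppercased,
self-interactions dropped, duplicates collapsed, with counts recorded
in provenance.  The signature network keeps every edge touching a seed
protein.  The reduction keeps the n = 30 non-seed proteins with the
most **distinct seed partners** (ties lexicographic by symbol);
ranking by total degree is an option because either reading of "most
interactions" is defensible, and seed-partner count scopes the claim to
the original sets.  Edges among retained interactors are included by
default (`seed_edges_only` gives the narrow reading).

Community detection is Girvan–Newman: repeatedly recompute Brandes
edge betweenness (unordered-pair convention, endpoints included) on the
remaining graph, remove the highest-betweenness edge (ties broken by
lexicographically smallest edge label), and track components.  The
returned partition maximizes Newman–Girvan modularity

    Q = Σ_c [ m_c/m − (d_c/2m)² ]

evaluated on the *original* graph along the removal sequence, earliest
partition winning ties.  All tie-breaking is lexicographic, so equal
input files yield identical removal sequences and memberships.

## Secretome densitometry

Spot density is the pixel sum inside the spot disc minus disc-area ×
local background, where background is the median in an annulus of inner
radius r and outer radius 2r; if the annulus overlaps another spot's
disc the global image median is used instead (with a warning).
Negative densities clip to 0; duplicate spots of one analyte are
averaged at the raw-density stage.  Reference spots occupy three
positions (upper-left, lower-left, lower-right); each position may hold
a duplicate pair sharing one label, so position averages fall out of
the duplicate-averaging rule and the grand mean of the three positions
defines 100%.  Classes are strict: abundant iff percent > 20, secreted
iff 5 < percent <= 20, else not secreted.  Integrated density with
annulus background was chosen over mean density / rolling-ball because
it is linear in spot mass and fully reproducible; layout coordinates
are authoritative (no auto-registration; a `--flip` flag handles
mirrored scans).

## Synthetic-data model

The bead generator draws, per gene, a log2 *level* shared across
samples — N(signal_mu = 11, signal_sigma = 0.5) where the gene is
expressed, N(null_mu = 7, null_sigma = 0.25) where it is not — plus
per-sample noise N(0, noise_sigma = 0.4); signals are 2^value.  Control
beads draw per-bead levels from the same null, so null detection
p-values are calibrated by construction.  The default effect size is 4
log2 units, and the default design holds 3 fMSC, 3 aMSC, 3 iPSC, 3
iMSC and 2 ESC samples over 1000 genes with 40% background expression,
mirroring a small multi-preparation bead-chip study.  Planted
rejuvenation genes are expressed in iMSC, iPSC and ESC samples only;
planted aging genes in fMSC and aMSC only; other genes are expressed in
all groups or none.  Gene-level (rather than fully independent) draws
are what give co-expressed samples positive correlation, so planted
group structure is recoverable by correlation clustering.

Membranes render each spot as a Gaussian blob (σ = radius/4, so
> 99.96% of its mass falls inside the disc) whose integrated intensity
is abundance × 200,000 counts on a 500-count background with additive
read noise (σ = 20 counts, 0 for noise-free renders), quantized to
16-bit.  Reference spots render at abundance 1.0, defining 100%.
Interaction fixtures are planted-partition graphs (within-community
edge probability p_in, across p_out) serialized with BioGRID TAB-3
column names plus decoy rows at a non-human taxid to exercise the
filter.

What the generators do **not** emulate: probe-sequence effects,
bead-level (pre-summary) variation, batch effects, spatial membrane
artifacts (bleed, bubbles, gradients), scanner saturation, and the
heavy-tailed abundance distributions of real secretomes.  Passing tests
therefore demonstrate correctness of the computations under the stated
noise model, not robustness to every artifact of real data.

## Problem sizes and numerics

The test suite and the acceptance script run the signature pipeline at
1000 genes × 14 samples with 1000 controls, calibration at 10,000 null
gene-sample draws, betweenness verification on 200 random graphs of up
to 8 nodes against explicit path enumeration, community recovery on a
2 × 8-node planted partition (p_in = 0.9, p_out = 0.02), and membrane
checks on ~300 × 340-pixel renders — sizes at which the brute-force
oracles stay exact and the whole run completes in seconds.  Exact
checks (quantile-normalization idempotence, modularity worked examples,
ddCt) use equality or 1e-9 tolerances; stochastic checks use the
margins stated in the tests.

## Known limitations

* The moderated t is a one-parameter shrinkage stand-in, not a full
  replication of limma's hierarchical model.
* π₀ smoothing uses a cubic least-squares fit rather than a smoothing
  spline with df = 3; on flat π₀(λ) profiles the difference is
  negligible, on strongly sloped ones q-values can differ slightly.
* Girvan–Newman recomputes betweenness after every removal (O(m²n));
  fine for signature-scale networks (tens of nodes), slow beyond ~10³
  edges.
* The secretome module quantifies; it does not register.  Misaligned
  scans must be corrected upstream.
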