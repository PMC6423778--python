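# stemsig

Presence/absence gene-signature extraction from bead-array detection
calls, with protein-association networks and cytokine-membrane
densitometry.

## The problem

Mesenchymal stromal cells (MSCs) age with their donor, while MSCs
re-derived from induced pluripotent stem cells (iMSCs) appear
rejuvenated.  One way to quantify this is to ask which genes switch
cleanly between *detected* and *undetected* across cell states on an
Illumina-style bead array.  Each sample carries negative-control beads;
a gene's **detection p-value** in sample *s* is the empirical upper-tail
probability of its signal against that sample's control distribution,

```
p[g, s] = (1 + #{controls in s >= signal[g, s]}) / (n_controls + 1)
```

and a gene with p <= 0.05 counts as expressed.  Two signatures follow
from combinations of per-group detection p-values:

```
aging:        p_MSC  < 0.001  and  p_iMSC > 0.1  and  p_iPSC > 0.1
rejuvenation: p_MSC  > 0.1    and  p_iMSC < 0.001 and  p_iPSC < 0.001
```

i.e. genes robustly present in parental MSCs but absent after
reprogramming, and vice versa.  The package implements this pipeline
end to end:

* **`stemsig.microarray`** — background correction, quantile
  normalization, detection p-values, group-level expression calls;
* **`stemsig.differential`** — pooled and moderated t tests, Storey
  q-values / Benjamini–Hochberg, ratio-based up/down calls (up iff
  ratio > 1.33 and q <= 0.05; down iff ratio < 0.75), Venn region
  partitioning, and 2^-ddCt relative quantification for qPCR;
* **`stemsig.signatures`** — the signature rule above, Pearson-distance
  hierarchical clustering (1 − r on log2 signals), annotation-subset
  heatmap matrices, hypergeometric enrichment;
* **`stemsig.network`** — protein-association networks: keep every
  interaction touching a signature protein (human taxid 9606 only), add
  the n = 30 interactors with the most distinct signature partners, and
  split into communities by Girvan–Newman edge-betweenness clustering
  with the maximum-modularity cut — Brandes betweenness, removal
  sequence and Newman–Girvan Q are implemented here with deterministic
  tie-breaking;
* **`stemsig.secretome`** — cytokine-array membranes: integrated spot
  density minus annulus background, percent of the mean of three
  reference positions, classes not-secreted / secreted (> 5%) /
  abundant (> 20%);
* **`stemsig.synthetic`** — generators for all of the above with
  planted ground truth (bead matrices, 16-bit membrane images,
  BioGRID-style interaction files).

## Worked example

```python
from stemsig import synthetic, microarray, signatures, network

# bead-summary matrix: 1000 genes, 5 cell groups, 50 + 50 planted genes
cfg = synthetic.SimConfig.with_planted(n_aging=50, n_rejuvenation=50, seed=7)
matrix, truth = synthetic.generate_bead_summary(cfg)

det = microarray.detection_pvalues(matrix)
group_p = signatures.signature_group_pvalues(det, policy="max")
result = signatures.extract_signatures(group_p)
print(f"aging signature: {len(result.aging)} genes")
print(f"rejuvenation signature: {len(result.rejuvenation)} genes")
planted = set(cfg.planted_rejuvenation)
print(f"planted rejuvenation genes recovered: {len(result.rejuvenation & planted)}/50")

# protein-association network from a planted-partition interaction file
records, _ = synthetic.generate_interaction_file(
    2, [8, 8], p_in=0.9, p_out=0.02, seed=7, path="scratch/interactions.tsv")
edges, provenance = network.parse_biogrid("scratch/interactions.tsv")
seeds = {f"C1N{i}" for i in range(1, 5)} | {f"C2N{i}" for i in range(1, 5)}
pan = network.augment_top_interactors(
    network.extract_signature_network(edges, seeds), edges, seeds,
    network.AugmentConfig(n_interactors=8))
part = network.girvan_newman_communities(pan)
print(f"PAN: {pan.n_nodes} proteins, {pan.n_edges} edges, "
      f"{len(set(part.membership.values()))} communities, Q = {part.Q:.3f}")
```

prints

```
aging signature: 49 genes
rejuvenation signature: 50 genes
planted rejuvenation genes recovered: 50/50
PAN: 16 proteins, 52 edges, 2 communities, Q = 0.481
```

49 of the 50 planted aging genes and all 50 planted rejuvenation genes
pass the strict detection thresholds (one aging gene drew a borderline
null signal in a pluripotent sample), with no false positives among the
900 unplanted genes.  The community clustering recovers the two planted
interaction communities exactly; Q ≈ 0.48 is close to the maximum
attainable for a two-block partition of this graph.

A console script exposes the same stages from a shell:

```
stemsig simulate --out-dir fixture --seed 1
stemsig preprocess --data-dir fixture --out pre
stemsig signatures --data-dir fixture --out signatures.tsv
stemsig pan --interactions biogrid.tsv --seeds seeds.txt --out-prefix pan
stemsig secretome quantify --image membrane.png --layout layout.csv --out profile.tsv
```

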