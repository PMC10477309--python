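# digestnet

Genome-resolved co-occurrence network analysis for anaerobic-digester
(AD) microbiome time series.

Full-scale anaerobic digesters convert municipal sludge to renewable
natural gas through a relay of hydrolysers, fermenters, syntrophic
oxidizers, and methanogens. Because syntrophy is only thermodynamically
feasible when a partner methanogen consumes the H₂/formate produced,
these guilds co-occur tightly in time — and a time-resolved co-occurrence
network over amplicon sequence variants (ASVs), annotated with genomes
(MAGs) and their expression, can expose the consortia that drive methane
production. `digestnet` implements that workflow end to end for
microbiome researchers and digester operators with a dated,
configuration-labelled ASV table in hand.

## What it computes

- **Community structure** — low-abundance filtering, Bray–Curtis
  dissimilarity, hierarchical clustering, PCoA, PERMANOVA across process
  configurations, core-microbiome screen (prevalence ≥ 80 %).
- **Physicochemical integration** — natural cubic-spline interpolation of
  parameter series to sampling dates, ASV–parameter correlations, and the
  exhaustive bioenv/BEST search for the parameter subset whose distance
  structure best rank-correlates with community structure.
- **Co-occurrence network** — nodes are ASVs present in ≥ 25 % of
  samples; edges are multiple-test-corrected biweight midcorrelations
  (bicor, a median/MAD-weighted robust correlation; BH, q < 0.05,
  positive only), with a sparse inverse-covariance alternative
  (CLR + graphical lasso + StARS penalty selection).
- **Indicator taxa** — group-equalized IndVal
  `stat = sqrt(specificity × fidelity)` per configuration with a label
  permutation test and BH correction.
- **Genome linking** — V4 extraction from MAG 16S genes via the
  515F/806R primer sites, ASV–MAG pairing at > 99.5 % identity over the
  full query (≤ 1 mismatch per 273 bp), lowest-common-ancestor taxonomy
  concordance, MIMAG-style quality tiers, TPM expression per MAG, and the
  metagenome↔metatranscriptome abundance correlation (methanogens
  excluded, since their transcription decouples from genome abundance).
- **Methanogen subnetworks** — 2-hop neighbourhoods around
  hydrogenotrophic-methanogen nodes (merged when overlapping), with
  syntroph/methanogen guild enrichment tested against 10,000 random node
  draws and its multivariate-hypergeometric closed form.
- **Synthetic data** — a first-class generator that plants configuration
  blocks, correlated syntroph–methanogen modules, compositional
  multinomial noise, coupled parameter series, MAG 16S fixtures at exact
  mismatch distances, and matched MG/MT gene-count tables — so the whole
  pipeline is testable without any sequencing data.

## Worked example

```python
from digestnet.simulate import default_scenario, simulate_timeseries
from digestnet.network import build_network, avg_clustering_coefficient
from digestnet.linking import assign_guilds
from digestnet.subnetworks import extract_subnetworks, guild_enrichment
from digestnet.indicators import indicator_test

table, taxonomy, params, truth = simulate_timeseries(default_scenario(seed=1))
net = build_network(table)
print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges, "
      f"avg clustering {avg_clustering_coefficient(net):.3f}")

guilds = assign_guilds(taxonomy)
for node in net.nodes:
    net.nodes[node]["guild"] = guilds.get(node, "other")
subs = extract_subnetworks(net)
for s in subs[:3]:
    print(f"subnetwork {s.id}: {s.size} nodes, "
          f"{s.n_syntrophs} syntrophs, {s.n_methanogens} methanogens")
res = guild_enrichment(net, subs[0], n_perm=10_000, seed=1)
print(f"enrichment of subnetwork 1: empirical p = {res.probability:.4f}, "
      f"exact (hypergeometric) p = {res.exact_probability:.4f}")

indicators = [r for r in indicator_test(table, n_perm=999, seed=1) if r.q < 0.05]
print(f"{len(indicators)} indicator ASVs, e.g. {indicators[0].asv_id} -> "
      f"{indicators[0].group} (IndVal {indicators[0].stat:.2f}, q {indicators[0].q:.3f})")
```

prints

```
network: 299 nodes, 19 edges, avg clustering 0.048
subnetwork 1: 4 nodes, 2 syntrophs, 1 methanogens
subnetwork 2: 3 nodes, 2 syntrophs, 1 methanogens
subnetwork 3: 3 nodes, 2 syntrophs, 1 methanogens
enrichment of subnetwork 1: empirical p = 0.0003, exact (hypergeometric) p = 0.0002
12 indicator ASVs, e.g. ASV0000 -> SOI (IndVal 0.90, q 0.025)
```

Of the 300 simulated ASVs, 299 pass the 25 % prevalence filter; the 19
significant robust-correlation edges recover the five planted
syntroph–methanogen modules as the top subnetworks, whose guild
composition is far richer than random draws from the network
(p ≈ 2×10⁻⁴), and the twelve configuration-shifted module members are
all recovered as indicators for their planted configuration.

## Command line

```sh
digestnet simulate inputs/ --seed 1          # write a synthetic input bundle
digestnet all --config pipeline.yaml         # run every stage
digestnet network --config pipeline.yaml     # or re-run one stage
```

A single YAML config carries input paths, stage toggles, thresholds, and
one explicit seed per stochastic stage; every run writes a
`run_report.json` with a config hash for provenance, and identical
configs reproduce byte-identical outputs.

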