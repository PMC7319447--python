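# mirnet

Rule-defined miRNA networks, score overlays and enrichment statistics —
an offline library and CLI.

`mirnet` builds undirected networks whose nodes are mature miRNAs, under
three rule families:

* **Seed2_7** — edges between matures sharing the identical seed
  (nucleotides 2–7 of the mature sequence); components are miRNA families.
* **Genomic_Distance_2k / _50k** — edges between matures whose precursor
  loci sit on the same chromosome closer than 2 kb (polycistronic
  clusters) or 50 kb (tolerant of genomic reorganization), plus the
  `Genomic_Distance_50k_clusters_3+` variant keeping only clusters of
  size ≥ 3.
* **Diana50 / TargetScan54 / DianaTarBase50** — edges between matures
  sharing more than 50 % / 54 % / 50 % of predicted mRNA targets
  (min-denominator overlap coefficient by default, Jaccard optional),
  plus the single-pass `TargetScan54_degree_10+` degree filter.

User score tables (log2 fold change, expression, −log10 P, …) are
overlaid on the nodes (diverging color scale, semi-transparent
unmeasured nodes) and tested for hit enrichment:

* **local binomial test** — upper-tail probability that a family/cluster
  contains at least its observed number of hits, given the network-wide
  hit proportion among measured nodes (log-space summation, accurate for
  very small tails); batch mode adds Benjamini–Hochberg adjustment;
* **global permutation test** — counts hit pairs (edges with both
  endpoints hits) against seeded randomizations of the hit labels among
  measured nodes, holding the hit count fixed;
* **exact paired Wilcoxon signed-rank** — for family export contrasts
  (e.g. vesicle minus parental cell), exact over all 2ⁿ sign assignments
  for tie-free n ≤ 25, normal approximation with continuity and tie
  corrections otherwise;
* **per-miRNA hypergeometric gene-set enrichment** on predicted targets.

A deterministic synthetic-fixture generator (`mirnet.synthetic_fixtures`)
emits miRBase-style mature FASTA, precursor GFF3, target tables and score
tables with planted families, genomic clusters and hit enrichment, so the
whole pipeline is testable without any downloads.

## Test

```sh
python -m pytest -q tests/
```

The suite includes property-based checks (clique structure of seed
networks, threshold monotonicity, agreement of every statistic with an
independent enumeration/PMF-summation oracle, planted-family recovery
power, null calibration) and `tests/test_acceptance.py` with the
published numeric values.

## CLI

```sh
# generate a synthetic dataset
mirnet simulate --seed 3 --families 4,3 --out fix/

# build a network (any of the eight predefined rules, or custom)
mirnet build-network --rule Seed2_7 --fasta fix/mature.fa --gff3 fix/loci.gff3 --out net/
mirnet build-network --rule TargetScan54 --fasta fix/mature.fa \
    --targets fix/targets.tsv --threshold 0.54 --out tnet/

# genomic clusters with bp spans
mirnet list-clusters --fasta fix/mature.fa --gff3 fix/loci.gff3 \
    --threshold-bp 50000 --out clusters.tsv

# overlay scores, style nodes, run local + global tests, render SVG
mirnet overlay --network net/network.json --scores fix/scores.tsv \
    --column score --expression-column expression \
    --hit-threshold 1.0 --n-trials 100000 --seed 0 --out results/

# individual tests
mirnet test-local  --network net/network.json --scores fix/scores.tsv --column score --out local.tsv
mirnet test-global --network net/network.json --scores fix/scores.tsv --column score --out global.json
mirnet test-family-export --scores expr.tsv --members hsa-miR-320a,hsa-miR-320b \
    --pairs exoA:cells,exoB:cells

# deterministic SVG rendering
mirnet render --network net/network.json --styles results/node_styles.tsv \
    --layout-seed 5 --out net.svg
```

Every run writes its effective configuration (`run_config.yaml`) next to
its outputs; re-running with the recorded parameters reproduces the
outputs bit-for-bit. Networks are exported as GraphML and a JSON graph
dialect; tables as TSV; the global test result as JSON (including seed
and trial count).

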