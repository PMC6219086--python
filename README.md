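# netmotif

A headless toolkit that couples **multi-network selection synchronization**
with **regulatory-motif regulon exploration**:

* import biological networks from SIF, XGMML or zipped session archives
  (e.g. Cytoscape `.cys` files), attach tab-delimited node attributes, and
  compare per-node topology (degree, clustering coefficient, connected
  components, exclusive-edge partitions) across networks;
* propagate node selections across all networks of a session through the
  shared-name identity key, optionally bridged by user-supplied identity
  maps (e.g. human/mouse homolog tables), and export selections as flat
  gene lists;
* feed such a gene list into a motif pipeline: strand-aware upstream-region
  extraction from a GenBank genome, ZOOPS-model motif discovery by
  expectation-maximization, genome-wide PWM scanning with exact
  dynamic-programming p-values against an order-3 Markov background and
  Benjamini–Hochberg q-values, rejection of genic occurrences, per
  downstream-gene aggregation with hit counts, and iterative expansion of
  the selection until the candidate regulon converges;
* generate deterministic synthetic fixtures (planted-motif genomes with
  GenBank output, toy network pairs with homolog renaming) so every stage is
  testable offline.

## CLI

```bash
# synthetic fixtures
netmotif simulate networks --n-shared 10 --homolog-rename --seed 1 --out fixtures/nets
netmotif simulate genome --n-genes 20 --seed 1 --out fixtures/genome

# import / metrics
netmotif import --sif fixtures/nets/net_a.sif
netmotif metrics --sif fixtures/nets/net_a.sif --out metrics.tsv

# selection propagation across networks (with an identity map)
netmotif select --sif fixtures/nets/net_a.sif --sif fixtures/nets/net_b.sif \
    --names genes.txt --map fixtures/nets/mapping.tsv --out selections/

# motif discovery -> genome scan -> aggregation, iterated to convergence
netmotif regulon --genbank fixtures/genome/genome.gbk --genes genes.txt \
    --nmotifs 5 --evt 1000 --order 3 --p-threshold 1e-4 \
    --iterate --top-k 20 --max-iter 10 --seed 1 --out results/
```

Every subcommand is reproducible: identical inputs and `--seed` yield
byte-identical outputs (timestamps only appear in stderr logs).  A YAML
config can pre-set flags (`--config cfg.yaml`); explicit flags win.

The `regulon` output directory contains one TSV per motif with columns
`downstream_gene, sequence, index_downstream, index_upstream, p-value,
q-value, hit_count, relative_position`, a `motifs.txt` in minimal
letter-probability-matrix format, a `summary.txt` (iterations, selection
sizes, convergence) and a `run_manifest.yaml` echoing all parameters.
`index_downstream`/`index_upstream` are 0-based positions of the flanking
genes in the discovery stage's ordered score list; `-1` marks genes absent
from the discovery input — the candidates that drive the iterative
expansion.

## Layout

```
src/netmotif/
  network_session.py  SIF/XGMML/session-archive I/O, attribute tables
  sync_select.py      selections, identity maps, propagation closure
  topo_metrics.py     degree / clustering / components / exclusive edges
  genome_io.py        GenBank I/O, upstream extraction, Markov background
  motif_core.py       ZOOPS EM discovery, PWM scan, p/q-values, consensus
  regulon.py          genic rejection, flank assignment, aggregation,
                      iterative expansion to convergence
  synthetic_data.py   planted-motif genomes, toy network pairs
  cli.py              command-line entry point
```
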