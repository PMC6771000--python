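# panlin

Comparative bacterial genomics toolkit: greedy identity-threshold protein
clustering into a pangenome, core/accessory/unique partitioning with a
homology-based false-positive filter, accumulation curves with a power-law
openness fit, fragment-based average nucleotide identity (ANIb-style),
reciprocal-best-hit average amino-acid identity (AAI), degradation-pathway
homology screening, and LinA dehydrochlorinase isoform typing — plus a
synthetic-data module that generates pangenomes, genome pairs and variant
sets with known ground truth so every stage is testable offline.

## Library overview

| module | contents |
|---|---|
| `panlin.sequence_io` | FASTA/Newick I/O, genome statistics (length, GC, coding fraction), patristic distances |
| `panlin.align_core` | exact global/local affine-gap alignment (numba kernels), percent identity under shorter-sequence or alignment-length denominators, Karlin–Altschul e-values |
| `panlin.clustering` | greedy incremental clustering at identity `c` (default 0.8) and length-difference cutoff `s` (default 0.9), CD-HIT-compatible outputs |
| `panlin.pangenome` | core/accessory/unique partition, homology filter for unique clusters, seeded accumulation curves (median/IQR), Heaps-law openness verdict, unique-count vs tree-distance Spearman correlation |
| `panlin.ani_aai` | genome fragmentation, one-way and symmetrised ANIb, RBH-based AAI |
| `panlin.pathway_screen` | thresholded homology screen against a `route=`-labelled reference FASTA, copy-number summaries, LinA variant typing with diagnostic residues (D25/H73/R129 catalytic triad; K20/L96/A131 enantiomer preference) |
| `panlin.synthetic_data` | seeded generators: pangenomes with known core/accessory/unique families, mutated genome pairs for ANI calibration, LinA-like variant sets |
| `panlin.cli` | `panlin` command-line interface and the `run` pipeline orchestrator |

## CLI

```bash
panlin simulate --config sim.cfg -o data/        # synthetic pangenome + truth
panlin stats data/g01.fna                        # genome statistics
panlin cluster data/*.faa -c 0.8 -s 0.9 -o out/  # greedy clustering
panlin pangenome data/*.faa --tree data/tree.nwk -o out/
panlin ani data/g01.fna data/g02.fna
panlin aai data/g01.faa data/g02.faa
panlin screen data/g01.faa refdb.faa -o hits.tsv
panlin lina query.faa lina_refs.faa
panlin run --config run.cfg                      # full pipeline + manifest
```

Config files are flat `key=value` text; CLI flags override config values.
Every `run` emits TSV reports and a JSON manifest (version, parameters,
seed, input checksums) sufficient to re-run bit-identically.

## Tests

```bash
python -m pytest -q tests/
```

The suite covers unit behaviour per module, property tests (alignment
scores vs an exhaustive DP oracle, clustering threshold soundness,
accumulation-curve monotonicity, generator determinism) and the acceptance
criteria in `tests/test_acceptance.py`. Two tests are gated on local copies
of deposited data (`PANLIN_PHFW_FASTA`, `PANLIN_LINA_FASTA`) and skip when
those environment variables are unset.

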