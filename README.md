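# coretree

Automatic multi-locus, genome-scale phylogenies from annotated sequence
files alone. Orthologues are identified with a strict single-copy
heuristic: starting from a seed genome, every *singleton* (a gene with no
homologue in its own genome) is queried against all other genomes, and only
loci that occur as singletons everywhere (or in at least `--presence`% of
genomes, with no multi-copy occurrence anywhere) are kept. Selected loci
are aligned independently, concatenated into a partitioned supermatrix, and
a tree is inferred from the combined alignment. By construction every
selected cross-genome pair is a reciprocal best hit, so no orthogroup
clustering step is needed.

## Pipeline

```
extract    parse GenBank (or proteome FASTA) -> one protein FASTA per genome
databases  one similarity-search database per genome
screen     seed-genome singletons -> presence matrix -> locus selection
align      per-locus alignments -> supermatrix + partition files
trees      combined tree (and optional per-locus trees + congruence report)
```

Every stage is checkpointed (content hashes + parameters), so interrupted
runs resume where they stopped and any parameter change triggers a clean
re-run of the affected stages.

## Command line

Quick start — run in (or point at) a folder of GenBank files:

```bash
coretree                      # current directory, all defaults
coretree genomes/ --output run_out
```

Useful flags (see `coretree --help` for all):

- `--tag TEXT` — CDS qualifier used as locus identifier (default
  `locus_tag`; e.g. `protein_id` for RefSeq-style files).
- `--presence PERCENT` — minimum percentage of genomes a locus must be a
  singleton in (default 100).
- `--maxloci INT` — cap on the number of loci (lexicographic truncation, or
  a seeded random sample with `--rng-seed`).
- `--seed-genome ID` — genome whose singletons seed the screen (default:
  lexicographically first).
- `--build-all` — also build one tree per locus plus a congruence report
  (normalized Robinson–Foulds of each locus tree vs the combined tree).
- `--max-evalue FLOAT` — homologue-detection threshold (default 1e-3).
- `--resume STAGE` — force a re-run from `extract|databases|screen|align|trees`.
- `--config FILE` — YAML file mirroring the flags; explicit flags win.

Proteome-only input (no nucleotide GenBank files) works transparently: put
one protein FASTA per genome in the input folder.

Synthetic test data with planted orthologue structure (single-copy core,
duplicated families, accessory genes, known generating tree):

```bash
coretree-fixture --n-genomes 6 --n-core 10 --out fixture/
coretree fixture/ --max-evalue 1e-10
```

## Outputs

```
<output>/
  fasta/<genome>.fasta        extracted proteomes
  dmnd/<genome>.json          per-genome search databases
  screen/presence_matrix.tsv  locus x genome status (S/M/A + best match)
  screen/selected_loci.txt    the selected orthologous loci
  aligns/<locus>.fasta        per-locus alignments
  aligns/combined.fasta       concatenated supermatrix
  aligns/partitions.txt       RAxML-style partition file
  aligns/partitions.nex       NEXUS sets block
  trees/combined.nwk          combined-alignment tree (newick)
  run.log, checkpoint.json, run_manifest.json
```

## Library overview

- `coretree.extract` — GenBank/FASTA parsing into per-genome protein sets.
- `coretree.search_backend` — exact Smith–Waterman search (BLOSUM62, affine
  gaps 11/1, Karlin–Altschul E-values) + external-tool adapter.
- `coretree.screen` — singleton detection, presence matrix, locus selection.
- `coretree.align` — per-locus alignment and supermatrix concatenation.
- `coretree.trees` — neighbour-joining fallback plus FastTree/IQ-TREE
  adapters.
- `coretree.metrics` — parsimony-informative sites, branch-support
  summaries, Robinson–Foulds and mean-normalized-RF congruence.
- `coretree.fixtures` — synthetic genomes and sequence simulation along
  known trees.
- `coretree.cli` — orchestration, checkpoints, configuration.
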