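# trcensus

A desk-scale, fully testable census of thioredoxin-reductase (TR)
subfamilies in prokaryotic proteomes. The pipeline:

1. **Detects PNDO-domain proteins** with a fixed-width position-specific
   scoring profile built from the concatenated BoxA+BoxB regions of a
   seed panel, accepting everything at or above the *trusted cutoff*
   (the minimum bit score of the profile's own building members).
2. **Groups homologs** in a protein similarity network (global-alignment
   identity) anchored on reference seeds for the TRi, TR1 and TR3
   subfamilies.
3. **Extracts the BoxA (31 aa) and BoxB (20 aa) motif regions** from a
   seed-anchored star alignment, builds sequence logos and consensus
   motifs (e.g. the NADPH-binding `HRRD` vs the `TQGK`/`NGK` patterns).
4. **Iteratively enriches** each group with a trusted-cutoff BoxB
   profile until membership is constant.
5. **Splits groups** by the two active-site cysteines (TR1 vs FdR) and
   by genome-level presence of a Trx3-like partner (TR3 vs dcTR1,
   Smith–Waterman with a Karlin–Altschul E-value threshold of 1e-10).
6. **Builds neighbor-joining trees** (Gblocks-style block selection,
   Poisson-corrected distances), roots them by the outgroup approach and
   flags duplication and horizontal-gene-transfer candidates by
   incongruence with a reference taxonomy tree.

A synthetic-proteome generator (`trcensus.synthetic_data`) plants
family-specific motif templates, FdR decoys without the active-site
cysteines, optional Trx3 partner genes, background proteins and a
class-structured taxonomy, so every stage runs and is validated offline.

## CLI

```sh
# generate a synthetic dataset (FASTA proteomes + taxonomy + truth + tree)
trcensus simulate --n-genomes 20 --composition TR1=1,TRi=1,TR3=1,FdR=1 \
    --frac-trx3 0.5 --mutation-rate 0.02 --seed 7 --out-dir data/

# classify an on-disk dataset
trcensus census --genomes-table data/genomes.tsv --proteome-dir data/proteomes \
    --seeds-fasta data/seeds.fasta --seed-labels data/seed_labels.tsv \
    --out-dir census_out/

# full reproducible run: simulate -> census -> logos -> trees -> summary.json
trcensus report --out-dir run1 --seed 7

# other tools
trcensus scan --profile PREFIX --fasta proteins.fasta
trcensus logo --fasta boxb_strings.fasta --out logo.tsv
trcensus tree --msa aligned.fasta --outgroup o1,o2 --out tree.nwk
trcensus compare --tree tree.nwk --reference ref.nwk --classes classes.tsv
```

Exit codes: 0 success, 2 validation error, 3 stage failure. All
randomness derives from the single `--seed`.

## Layout

| module | role |
|---|---|
| `io_formats` | FASTA / genome-table TSV / seed / Newick / report I/O |
| `synthetic_data` | template-based proteome generator with ground truth |
| `profile_search` | log-odds profiles, bit scores, trusted cutoffs, PNDO scan |
| `psn_grouping` | similarity network, components, seed-anchored groups |
| `box_motifs` | star alignment, BoxA/BoxB extraction, logos, consensus |
| `classifier` | iterative enrichment, split rules, full census |
| `phylo` | block selection, distances, NJ, rooting, RF, incongruence |
| `pipeline` / `cli` | orchestration, configuration, `trcensus` entry point |

Notable simplifications (documented in the module docstrings): a PSSM
with ungapped window search stands in for a profile HMM (the modeled
regions are fixed-width), and neighbor joining with optional bootstrap
stands in for Bayesian inference.
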