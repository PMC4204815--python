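# plastomark

Comparative-plastome marker discovery. Starting from a multiple alignment
of colinear plastomes (aligned FASTA), the pipeline:

1. builds two consensus tracks — a **best-base** track (per-column majority,
   gaps ignored in the vote) and an **ambiguous** track (an explicit base
   only where every sequence agrees perfectly; `N` otherwise);
2. finds perfect di-/tri-nucleotide **SSRs** (≥ 4 complete units,
   homopolymers excluded) on the best-base track and flags them polymorphic
   when an ambiguous column lies inside the repeat or within 4 bp of it;
3. scans for 300-bp hypervariable **barcode blocks** satisfying: divergence
   ≥ 2%, divergence ≤ 10% (genus) / 15% (family), no run of > 7 consecutive
   ambiguous columns, and ≥ 5 (genus) / ≥ 8 (family) SNPs each bordered by
   5 perfectly conserved bases per side; overlapping accepted windows are
   merged;
4. designs **primer pairs** drawn exclusively from perfectly conserved
   sequence within 300 bp of a target marker (product size 100–280 bp,
   nearest-neighbor Tm, GC and dimer screens);
5. builds a **K80 + neighbor-joining tree** with column-resampling
   bootstrap support (default 50 replicates);
6. **simulates** plastome families on a tree under K80 with planted
   conserved islands, hypervariable blocks, length-polymorphic SSRs and
   indels — with a realized-statistics truth table — so every stage is
   verifiable without external data.

All coordinates are 0-based half-open alignment columns; TSV columns
suffixed `_1based` are the only 1-based values.

## CLI

```sh
# simulate a 20 kb, 5-taxon family with planted markers
plastomark simulate --out-dir run/sim --seed 11

# full pipeline on any aligned FASTA
plastomark all --alignment run/sim/family.fasta --out-dir run/out --seed 3

# or stage by stage
plastomark consensus --alignment aln.fasta --out-dir out
plastomark ssr       --alignment aln.fasta --out-dir out
plastomark barcode   --alignment aln.fasta --out-dir out --level family
plastomark primers   --alignment aln.fasta --targets out/blocks_family.tsv --out-dir out
plastomark tree      --alignment aln.fasta --out-dir out --outgroup Musa --seed 1
plastomark make-fixtures --out-dir fixtures --seed 0
```

Outputs: consensus FASTA, marker TSV + BED6, primer TSV, newick tree with
bootstrap supports, distance-matrix TSV, and a resolved-config JSON beside
every stage for provenance. Thresholds can be overridden with
`--config file.json` (JSON object; unknown keys are rejected) — flags
override file values.

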