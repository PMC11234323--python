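# covarna

Does an RNA alignment show evidence of an **evolutionarily conserved
secondary structure**? `covarna` answers that question with the
covariation-plus-power framework:

1. **Significance.** Column-pair covariation (G-test by default, MI
   optionally, both with average product correction) is scored against an
   ensemble of *phylogenetic null alignments* — synthetic alignments that
   carry the same per-branch substitution events (from Fitch-parsimony
   ancestral samples on a neighbor-joining tree) with every substitution
   re-placed at a random eligible position. Nulls preserve per-sequence
   composition and, by default, the exact gap structure. Each pair gets an
   empirical E-value (exponential tail extrapolation beyond the pooled null
   maximum); pairs with E < 0.05 significantly covary.
2. **Power.** From the per-column substitution counts, an isotonic
   calibration curve estimates how much significant covariation a *true*
   conserved structure would have produced (single- or double-substitution
   mode).
3. **Verdict.** Observed vs expected covariation classifies an alignment as
   STRUCTURAL (>= 3 significant pairs), CANNOT_TELL (no covariation, no
   power), NEGATIVE (no covariation despite high double-subs power),
   INCONSISTENT_POWER, or INCONCLUSIVE.

The package also ships:

* a **codon-evolution model** (BLOSUM62-derived amino-acid rate matrix x
  stationary codon biases) that explains within-codon covariation in
  protein-coding alignments and predicts its MI trajectories vs divergence;
* **synthetic-data generators** for structure-constrained alignments on
  trees and for the classic artifact scenarios: occupancy-biased gaps,
  conserved-column traps (why conservation-mixing scores like RAF must not
  be used for significance), pseudogene dilution, and shifted-helix
  misalignments;
* Stockholm/aligned-FASTA I/O with WUSS consensus-structure parsing and
  Newick tree I/O.

## CLI

```bash
# full analysis of a Stockholm alignment (SS_cons optional)
covarna analyze my.sto --nulls 20 --stat gtest --gap-preserving \
    --evalue-cutoff 0.05 --seed 7 --out-pairs pairs.tsv --out-json call.json

# synthetic data with truth labels
covarna simulate -s 30 -l 80 --pairs 10 --branch-length 0.5 --seed 1 \
    --out sim.sto --out-truth truth.json
covarna simulate --scenario gap-bias --out gapbias.sto --seed 2

# expected within-codon MI trajectories
covarna codon-mi --aa SRL --pair c1c3 --t-grid 0.05:2.0:40 --out mi.tsv
```

`covarna analyze` writes a per-pair TSV (1-based coordinates, raw and
APC-corrected scores, E-values, substitution counts, powers) and an
alignment-level JSON verdict.

## Library sketch

```python
from covarna import read_alignment, analyze

aln = read_alignment("my.sto")
result = analyze(aln, n_nulls=20, seed=7)
print(result.call.classification, len(result.significant))
```

Modules: `msa_io` (alignments, WUSS, column profiles), `phylo` (NJ trees,
Fitch sampling, substitution maps), `nullgen` (phylogenetic nulls),
`covstats` (MI, G-test, RAF diagnostic, APC), `evidence` (E-values, power
curves, classification), `codonmodel` (genetic code, amino-acid rate
matrix, within-codon MI, exon simulation), `synth` (simulators and
artifact scenarios).

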