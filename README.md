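# allopoly

Analysis toolkit for allotetraploid genomes: partition a tetraploid genome
into its two parental subgenomes, date the progenitor divergence and the
genome merger, quantify homoeolog expression bias, and measure CG
methylation divergence between homoeologs — plus a fully seeded synthetic
allotetraploid generator so that every stage can be exercised and verified
at desk scale against planted ground truth.

## What it does

- **`allopoly.simulate`** — generates a toy allotetraploid: two subgenome
  chromosome sets and a diploid relative evolved under a two-class
  Jukes–Cantor process calibrated to a molecular clock, gene models (GFF3),
  a homoeolog/triplet table, diploid-alignment depth windows, a TE table
  whose insertion history plants a divergence "bubble", tissue FPKM
  matrices with subgenome-B-biased and silenced pairs, stress
  treatment/control expression, and replicate Bismark-style cytosine
  reports. Ships a machine-readable truth record for parameter-recovery
  tests.
- **`allopoly.assignment`** — effective coverage (depth ≥ 5) of
  diploid-relative alignments per chromosome, subgenome labelling (higher
  coverage ⇒ B, identity as tie-breaker) and A01/B01-style chromosome
  naming.
- **`allopoly.dating`** — Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor
  correction, Ks-distribution peak finding (Gaussian KDE, Silverman
  bandwidth), molecular-clock dating T = K/(2r), per-chromosome Ka/Ks
  asymmetry (paired Wilcoxon), TE divergence landscapes and merger dating
  from the non-overlapping TE interval (T_merge = T_div · d_low/d_high).
- **`allopoly.expression`** — expressed-gene filtering (FPKM > 1),
  two-fold dominance labels with a +1 pseudocount, bias summaries,
  32-fold extreme sets, Ward/Pearson co-expression clustering, triplet
  fate classification (conserved / sub- / neo- / nonfunctionalization)
  against a diploid outgroup, and the summed-expression stress DEG
  comparison.
- **`allopoly.methylation`** — conserved-site filtering (≥ 5 reads in all
  replicates), binomial mCG calling, genome-wide pcg, the exact
  binomial-tail gene-body methylation test, DmCG change rates over
  homoeologous site maps, metagene profiles and the promoter
  hypomethylation test for dominant vs suppressed homoeologs.
- **`allopoly.pipeline`** — one seeded run of all stages with persisted
  intermediates and a consolidated JSON + text report.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact clock and
merger arithmetic, Ks-peak and TE-bubble recovery on synthetic data, and
the property suites).

## CLI

```sh
allopoly simulate --out run/sim --seed 1
allopoly assign --depth run/sim/depth.tsv --pairs run/sim/chrom_pairs.tsv \
    --identity run/sim/identity.tsv --out run/assignment.tsv
allopoly date --cds cds.fasta --pairs run/sim/homoeologs.tsv --rate 3.51e-9 --out run/ks.tsv
allopoly te-date --te run/sim/te.tsv --assignment run/assignment.tsv \
    --size-a 45600000 --size-b 45600000 --t-div 23e6
allopoly expression --fpkm run/sim/fpkm.tsv --pairs run/sim/homoeologs.tsv --out run/expr
allopoly stress --treatment run/sim/treatment.tsv --control run/sim/control.tsv \
    --pairs run/sim/homoeologs.tsv --out run/stress.tsv
allopoly methylation --cx run/sim/cytosine_rep1.tsv --cx run/sim/cytosine_rep2.tsv \
    --cx run/sim/cytosine_rep3.tsv --gff run/sim/genes.gff3 --out run/meth
allopoly run-all --out run --seed 1          # full pipeline + report
```

`allopoly run-all` accepts a TOML config (`--config`) whose keys mirror
`allopoly.pipeline.PipelineConfig`; CLI flags override config values.

## File formats

Plain text throughout: FASTA for sequences, GFF3 (1-based inclusive) for
gene models, TSV for depth windows (0-based half-open), TE tables,
homoeolog tables, FPKM matrices and cytosine reports (1-based positions,
contexts CG/CHG/CHH), and JSON for truth records and reports.
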