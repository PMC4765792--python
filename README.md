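# allomirna

Discovery, evolution, and expression partitioning of miRNAs in allopolyploid
plant genomes — a reusable, tested re-implementation of the computational
pipeline behind allotetraploid small-RNA studies (the motivating system is
*Brassica napus*, A\_nA\_nC\_nC\_nC, and its progenitors *B. rapa* and
*B. oleracea*), exercisable end to end on synthetic data with planted ground
truth.

## What it does

Given an allotetraploid genome, its two progenitor genomes, collapsed
small-RNA libraries, degradome (PARE) tags, transcripts, and a reference set
of known mature miRNAs, the pipeline:

1. **Cleans and normalizes libraries** — 18–44 nt length filter, exact-match
   removal of snoRNA/tRNA/rRNA/rasiRNA reads, RPM = count / clean reads × 10⁶.
2. **Predicts MIRNA loci** — exact read→genome mapping, cluster + hairpin
   excision, folding with a simplified nearest-neighbor energy model, and
   Mireap-style duplex gates: ΔG < −18 kcal/mol, >16 matched nt and <4
   bulges in the miRNA/miRNA\* duplex, mature–star spacing < 300 nt, ≥2
   reads in some library. Matures at edit distance ≤2 from a known miRNA are
   *conserved* (family inherited), the rest *novel* (`bna_novel_miRX{n}`).
3. **Predicts and validates targets** — Allen-style complementarity
   expectation (seed positions 2–13 doubled, cutoff 3.0), cleavage opposite
   miRNA positions 10–11, degradome-validated when a tag 5′ end lies within
   5 nt of the predicted cleavage site.
4. **Calls MIRNA gains and losses** — seed-and-extend homology search
   (coverage > 90%, E < 1e−5, top 5 hits) plus microsynteny over the 10
   flanking protein-coding genes per side (classes 1–3 = syntenic); a
   progenitor locus with no tetraploid hit is *lost*, a tetraploid locus
   with no syntenic progenitor partner is *gained*.
5. **Partitions expression between subgenomes** — per-mature and per-Mb read
   densities, the C\_n/A\_n ratio, a two-sided Wilcoxon rank-sum test, the
   double-counting rule for reads mapping to both subgenomes, >2-fold
   differential expression, and additive vs non-additive heredity in derived
   double-haploid lines against the mid-parent value (≥2-fold rule).

A first-class **synthetic-data generator** builds all of these inputs with a
fully known `PlantedTruth` ledger (loci, losses, gains, expression bias,
cleavage sites, non-additive loci), so every stage can be scored against
what was planted.

## Worked example

```sh
allomirna run-all --workdir run --seed 7
```

runs simulate → preprocess → discover → targets → synteny → express →
report on a default synthetic dataset (2+2 chromosomes × 1 Mb, 100 homeolog
locus pairs, 10 planted losses, 5 gains, planted C:A expression bias 0.55,
twelve 10⁶-read libraries). `run/report.json` then contains, among others:

```json
"discover": {"total": 181, "conserved": 73, "novel": 108,
             "subgenome_A": 84, "subgenome_C": 97},
"synteny":  {"n_lost": 10, "n_gained": 5, "n_opposite_subgenome": 0},
"express":  {"partition": {"T/N:E1:per_mature": {"ratio": 0.592, "p": 8.3e-05}},
             "heredity": {"ratio_non_additive": 0.279}}
```

Reading: 181 of the 195 planted tetraploid loci were recovered and split
into conserved/novel families and subgenomes; all 10 planted losses and 5
planted gains were called back exactly; the planted 0.55 C:A expression
bias was estimated at 0.59 with rank-sum p ≪ 0.01; and the planted 30%
non-additive fraction was called at 28%. Stage tables
(`mirna_loci.tsv`, `target_interactions.tsv`, `gain_loss.tsv`,
`partition_report.tsv`, `heredity.tsv`, per-Mb density tracks) are written
next to the report.

Each stage is also a library call — see `allomirna.discovery`,
`allomirna.targets`, `allomirna.synteny`, `allomirna.expression` — and a
CLI subcommand (`allomirna discover --workdir run`, …).

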