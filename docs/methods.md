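# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `allomirna`. It states no empirical result that the
test suite or `scripts/acceptance.py` do not themselves compute.

## Overview of the procedure

The pipeline treats an allotetraploid genome as two labelled subgenomes
(A and C) inherited from two progenitor species. Collapsed small-RNA reads
are mapped exactly to the tetraploid genome; read clusters are excised with
flanking windows and folded; candidates passing the hairpin/duplex gates
become MIRNA loci, classified conserved or novel against a set of known
mature miRNAs. Targets are predicted by complementarity scoring and
validated against degradome tag 5′ ends. Locus orthology between tetraploid
and progenitors is established by precursor homology plus microsynteny of
flanking protein-coding genes, from which losses and gains are called.
Expression is quantified as RPM per mature miRNA and compared between
subgenomes, between tissues/conditions, and between derived homozygous
lines and their mid-parent value.

## Acceptance gates (discovery)

All thresholds are exposed in `PipelineConfig` and default to the values the
analysis is defined by:

| parameter | default | meaning |
|---|---|---|
| `dg_cutoff` | −18 kcal/mol | hairpin ΔG must be strictly below this |
| `min_matched` | 17 | >16 mature nt paired in the miRNA/miRNA\* duplex |
| `max_bulges` | 3 | <4 unpaired mature nt |
| `max_spacing` | 299 | mature–star loop span <300 nt |
| `min_reads` | 2 | ≥2 reads in at least one library |
| `conserved_max_mismatch` | 2 | edit distance to a known mature for "conserved" |
| `expectation_cutoff` | 3.0 | target-site penalty gate |
| `degradome_window` | 5 | validated iff a tag 5′ end is within 5 nt (inclusive) |
| `flank_genes` / `top_hits` | 10 / 5 | microsynteny context size / homology hits kept |
| `min_coverage` / `max_evalue` | 0.9 / 1e−5 | homology-hit retention gates |
| `fold` / `epsilon` | 2.0 / 0.1 RPM | fold-change threshold / zero-rescue pseudo-count |

Boundary conventions: the ΔG, matched, bulge, spacing and DE gates are
strict inequalities; the conservation distance, degradome window, and
heredity twofold rule are inclusive. The pseudo-count is applied to a fold
change only when one term is zero, so exact twofold boundaries on positive
values are decided by the raw ratio.

## Folding model

The default backend (`nn`) is a simplified nearest-neighbor free-energy
model: Watson–Crick and G:U pairs; helix stacking energies from a shipped
6×6 table; tabulated hairpin, bulge, and internal-loop length penalties with
Jacobson–Stockmayer log extrapolation (RT at 37 °C); minimum hairpin loop
3 nt; internal/bulge loops bounded at 12 unpaired nt; an asymmetry penalty
capped at 3 kcal/mol; no multibranch loops, pseudoknots, dangling ends, or
terminal-mismatch terms. The dynamic program is a Zuker-style V/W recursion
(numba-accelerated); the exterior loop may carry several helices at zero
cost. Absolute energies therefore differ from full Turner-parameter values
by a few kcal/mol, but the −18 kcal/mol gate is applied to whichever backend
is configured and the backend name is recorded in stage metadata. A
pair-maximization backend (`maxpair`, Nussinov) exists for oracle testing,
and ViennaRNA (`vienna`) is pluggable behind the same contract; a test
checks that the shipped model and ViennaRNA rank hairpin-forming sequences
the same way.

The miRNA\* arm is delimited from the pair table as the span of positions
paired with the mature, extended by the 2-nt 3′ overhang of Dicer
processing. A mature that pairs with itself spans the loop and is rejected.
Candidate windows are `[mature−300, mature_end]` and
`[mature_start, mature_end+300]`; after a first fold, the precursor is
excised around mature + star (±10 nt) and refolded, and the gates are
evaluated on the excised fold. Per cluster, the candidate mature is the most
abundant read (ties: lexicographically smallest); among accepted windows the
lowest-ΔG locus is kept. The same mature at two genomic positions yields two
loci.

## Target scoring

Sites are scored on the antiparallel duplex with per-position penalties 0
(Watson–Crick), 0.5 (G:U), 1 (mismatch), and 2 per bulged target nucleotide;
penalties are doubled at miRNA positions 2–13. At most one target-side bulge
of ≤3 nt is considered; the scan is exact (verified against exhaustive
alignment enumeration) and vectorized per transcript. The predicted cleavage
position is the transcript nucleotide paired to miRNA position 10 from the
5′ end, the canonical AGO slicing register. Degradome tags are exact-matched
to transcripts on the sense strand only; multi-transcript tags count on
every match.

## Homology and microsynteny

Precursor homology uses seed-and-extend ungapped alignment (13-nt exact
seeds every 4 nt, both strands, match +1 / mismatch −2, X-drop 12).
Significance is a Karlin–Altschul E-value (λ=1.33, K=0.621) with the
database length as the search-space correction — a reproducible stand-in
for an unversioned BLASTN. Retained hits must cover >90% of the query with
E < 1e−5; at most the five best are kept (ties: chromosome, then start).
Because substitution-only divergence is modelled, ungapped extension is
exact for the generator's data; indel-containing real genomes would need a
gapped aligner behind the same interface.

Microsynteny compares ortho-family labels of the ≤10 nearest protein-coding
genes per side. Each query side is intersected with the union of the subject
sides (a hit on the opposite strand reverses gene order, so side-to-side
matching would depend on orientation); class 1 = both query sides share ≥1
gene, 2 = upstream only, 3 = downstream only, 4 = neither; classes 1–3 are
syntenic (the flag is symmetric in query and subject). Gene identity across
genomes is carried by `ortho_family` GFF3 attributes; real data requires a
user-supplied ortholog map. A progenitor locus is lost iff it has no
retained hit in the tetraploid; a tetraploid locus is gained iff no hit in
either progenitor is syntenic; best hits on the non-corresponding subgenome
(A_r↔C_n, C_o↔A_n) are tallied as opposite-subgenome matches.

## Expression statistics

A read counts toward a mature miRNA when an alignment lies entirely within
the mature's genomic span ±2 nt (configurable slack); a read inside mature
spans on both subgenomes contributes its full count to both tallies. The
partition statistic is total RPM per unique mature sequence (or per Mb of
subgenome); the p-value is a two-sided Wilcoxon rank-sum on per-mature RPM,
exact by enumeration for groups of ≤10 and normal-approximated otherwise.
Environments are analysed separately, never pooled. Heredity compares the
derived-line mean with the mid-parent value (MPV); |deviation| ≥ twofold is
non-additive.

## The synthetic-data generator

The generator's defaults are the study conditions the tests run under:
2 chromosomes × 1 Mb per subgenome, 100 homeolog locus pairs, 120
protein-coding genes per chromosome, 10 losses, 5 gains, C:A expression
bias ρ = 0.55, twelve libraries (parents T and N plus 4 DH lines × 2
environments) of 10⁶ reads, 30% repeat background with a C:A repeat bias of
2.1, 30% non-additive DH loci at factor 4 (drawn from {4, ¼}), 0.5%
tetraploid divergence, and 43% conserved families.

Construction details:

- **Hairpins** are mature (21 nt) + loop (40–80 nt) + reverse complement of
  the mature with 1–3 substitutions. Discoverability is guaranteed by
  construction: star variants are re-drawn until the assembled precursor
  passes the discovery gates under the shipped energy model, so recovery
  tests measure the pipeline, not the generator.
- **Homeolog pairs** share a family; the two matures differ by ≥1
  substitution so subgenome attribution by exact mapping is well defined
  (loops are independent, so homeolog precursors are not globally similar —
  a deliberate simplification that makes locus identity resolvable).
- **Chromosomes** are assembled from an explicit element list (spacers,
  genes with `ortho_family` labels, MIRNA loci, repeat windows); the
  tetraploid copies the progenitor element lists with per-site substitution
  at `mutation_rate`, excises `n_losses` loci, and inserts `n_gains`
  precursor copies between genes on a *different* chromosome than their
  source (an insertion next to the source would be a tandem duplication and
  syntenic by definition, hence not a detectable gain).
- **Expression** is lognormal(0, 1) per locus; C-subgenome expectations are
  scaled by ρ with an *independent* lognormal variate (a scale relation in
  expectation, not a per-pair copy — a deterministic copy would make the
  rank-sum null degenerate). Parents multiply locus expectations by
  lognormal(0, 0.5) line effects; DH lines use the mid-parent mean except
  planted non-additive loci.
- **Libraries** are multinomial draws: mature reads by expectation, 24-nt
  background reads from repeat-window positions (C:A weight 2.1, start
  positions subsampled every 7 nt so libraries stay collapsible), a 2%
  ncRNA-fragment component, and 1% out-of-range "junk" lengths that the
  length filter removes. Clean-read totals equal the drawn depth.
- **Degradome** tags (20 nt) start exactly at planted cleavage positions;
  decoy sites receive their tags 8 nt downstream; positional noise is
  uniform over starts *outside* the ±5 nt validation neighborhood of every
  planted site — noise models decay fragments unrelated to the interrogated
  sites, which is what makes validation specificity measurable exactly.

What the generator does **not** emulate: sequencing error and quality
scores, adapters, isomiR heterogeneity, indel divergence, transposon
biology beyond positionally uniform repeat windows, realistic chromosome
sizes, and correlated expression between homeologs. Passing recovery tests
therefore demonstrates correctness of the pipeline's logic under the stated
statistical model, not performance on real sequencing data.

## Problem sizes and determinism

Scaled study reproductions (in `allomirna.replication`, used by
`scripts/acceptance.py` and the acceptance tests) run at desk scale:
discovery recovery on the 4-Mb default genome with twelve 10⁶-read
libraries; the partition ratio on 300 homeolog pairs at depth 10⁶ (three
seeds, parental E1 libraries); the null calibration on 200 replicate
datasets of 60 pairs at depth 10⁵ with background disabled (the genome is
fixed and expectations/libraries are resampled per replicate); gain/loss on
a 10-loss/5-gain fixture; degradome validation on 50 planted + 50 decoy
sites at 20% noise; heredity on 100 pairs at depth 10⁶. All randomness
flows from `numpy.random.PCG64` seeded from a single integer; identical
configuration and seed reproduce byte-identical files, and stage outputs
are written with sorted keys and fixed column orders for that reason.

## Known limitations

- The energy model is deliberately simplified; loci near the −18 kcal/mol
  boundary can be decided differently than under full Turner parameters.
  The gate's meaning is therefore tied to the recorded backend.
- Exact (0-mismatch) read mapping makes all downstream counts reproducible
  but undercounts isomiRs and SNP-bearing reads on real data.
- Ungapped homology search does not model indels.
- The four microsynteny classes are a documented interpretation of a
  flanking-gene scheme whose original definition is not restated here;
  "identical" flanking genes carry no similarity threshold and are decided
  by the ortho-family labels supplied with the annotation.
- Whether RPM denominators should be taken before or after ncRNA filtering
  is ambiguous in the field; the default here is the post-length-filter,
  pre-ncRNA-filter total, and it is configurable.
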