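# Methods

## Scope and model

`seqbalance` implements the quantitative planning and quality-control layer
of a large-scale, multiplexed short-read whole-genome sequencing operation:
deciding read lengths and flow-cell counts, quantifying and sizing pooled
PCR-free libraries before loading, equalizing per-sample data volume across
flow cells (iDeal), filtering contaminated samples, profiling which genomic
regions a protocol can reach, and enumerating pedigree structures in a
three-generation cohort. The alignment/variant-calling pipeline itself
(BWA/GATK), contamination *estimation* (VerifyBamID), and array concordance
checks are out of scope; the package consumes their outputs (read counts,
freemix fractions, binned depth) as plain text.

## Planning arithmetic (`platform`)

Each sequenced base consumes one chemistry cycle, so a kit with `A` actual
cycles and `i1 + i2` index cycles supports a symmetric paired read length of
`floor((A - i1 - i2)/2)`. Kits ship spare cycles beyond their nominal label
(a "300-cycle" HiSeq SBS kit holds 325, the NovaSeq equivalent 338), which
is what makes 162 bp PE (no index reads, one sample per flow cell) and
161 bp PE (8+8 bp dual index) possible instead of the de facto 150 bp.

Yield is `clusters x L x 2` for paired-end; expected coverage is the
Lander–Waterman ratio `yield / G`. Defaults: `G = 3.0e9 bp` — with ~90 Gb
per genome this gives the quoted "approximately 30x"; 3.1e9 would not.
Gigabases are decimal (1 Gb = 1e9 bp) and platform yield labels are
reproduced by rounding to the nearest integer Gb, which matches the
90/97/155 Gb labels simultaneously.

Preset table: cluster counts per flow cell are published only for the HiSeq
2500 Rapid Run (300 million read pairs); the other presets back-compute
clusters from the per-flow-cell yield label as `yield_bp / (2L)`. The
259 bp PE protocol's cycle budget is not derivable from its "500-cycle" kit
label (2x259 > 500), so that preset carries only its output label.

`flowcells_needed` is demand arithmetic:
`ceil(n_samples x coverage x G / per_flowcell_yield)`. The pool size is
recorded but does not enter the formula.

## Library QC (`libqc`)

**Loading volume (pool-level quantification).** New 96-plex pools are
quantified with a dsDNA dye against a previously sequenced reference pool
and loaded at equal DNA mass: `v_new = v_ref c_ref / c_new`. This assumes
the new pool's library size distribution matches the reference, which the
sizing step verifies independently.

**Sizing.** PCR-free libraries carry Y-shaped adapters and migrate
anomalously as dsDNA (>1000 bp for a ~600 bp library); the package flags
observed sizes above 1000 bp as this artifact. Sizing is therefore done
denatured against an RNA ladder. Because RNA ladders migrate ~30 nt slower
than DNA ladders under denaturing conditions, the observed size is corrected
by `+30 nt` (configurable), and the insert size is the corrected library
size minus ~140 bp of adapter (configurable): 616 nt observed → 646 bp
library → 506 bp insert, consistent with the 550 bp fragmentation target.

**Molarity helper.** `nM = (ng/uL) x 1e6 / (660 x bp)`, using 660 g/mol per
dsDNA base pair.

**Filters.** Contamination: samples with freemix `>= 0.03` are excluded —
the boundary is inclusive by design, and the threshold is configurable
(gnomAD's 5% is a common looser alternative). Duplication and base-balance
checks are qualitative in practice; the package exposes them as configurable
numeric flags with package-chosen defaults `max_dup = 0.20` and
`max_base_skew = 0.02` (on |f(A)−f(T)| and |f(G)−f(C)|). Missing metrics
yield explicit "not-evaluated" flags rather than silent passes. An optional
yield-inflation factor for saliva DNA (10–20% bacterial content) exists in
coverage planning via the configurable genome size; it defaults to off.

## Data equalization (`balance`)

With an equal-volume pool, each sample's demultiplexed read share (index
ratio) estimates its relative molar concentration. Rates `reads_i /
volume_i` are normalized to mean 1 over samples with nonzero reads;
zero-read samples are flagged failed and carry no estimate.

Re-pooling targets equal cumulative totals. Given round-1 totals `t_i`,
concentrations `c_i`, and `K` remaining runs of `R` reads:

* target `T = (Σ t_i + K R)/n`; deficit `d_i = max(T − t_i, 0)`;
* samples with `d_i = 0` are excluded (`deficit-met`), failed libraries are
  excluded for a fresh pool (`failed-library`);
* raw volumes `u_i = d_i / c_i` are scaled so `max u_i = vmax` (default
  30 uL); anything below `vmin` (default 1 uL) is raised and flagged
  `below-pipettable`;
* projected finals follow the multinomial share model
  `t_i + K R c_i v_i / Σ c_j v_j`, which lands exactly on `T` whenever no
  clamp triggers.

"Equal final totals with zero-deficit clamping" is the minimal formalization
of making the read distribution "as even as possible"; absolute pipetting
scales are package choices since none are published. Multi-round schedules
(e.g. three initial + three adjusted flow cells on DNBSEQ-T7, one + two on
NovaSeq) are expressed as `(initial_runs, balanced_runs)`; pooled initial
runs are summed before estimating concentrations. Equalization targets equal
*totals*; a per-run read-length weighting (for equal coverage across
mixed-length runs) is not implemented.

Spread metrics: `maxmin_ratio = max/min`, `max_rel_dev = 100 max|x−mean|/
mean`, and the population CV in percent. The "<10% variation" claim is read
as `max_rel_dev`, the strictest of the three; CV is also reported.

## Coverage accessibility (`covprofile`)

Input is precomputed binned depth (bedGraph/TSV), typically restricted to
MAPQ ≥ 20 at pileup time — the MAPQ floor is provenance, not something this
package recomputes, because the bespoke content is the aggregation and
classification, not pileup. Aggregation is the per-bin arithmetic mean
across samples (all tracks must agree on contig/bin/extent). A bin is *low*
when its mean depth is below `rel_threshold x global_mean`
(default 0.25); runs of at least `min_region_bins` (default 2) low bins
become inaccessible intervals; the complement is accessible. Both knobs are
package choices — published accessibility calls are visual, with no printed
threshold. `protocol_diff(a, b)` returns bins inaccessible under `b` but not
under `a`, i.e. what protocol `a` (say, 161–162 bp reads) recovers over `b`
(150 bp). Coordinates are 0-based half-open throughout.

## Pedigrees (`pedigree`)

Standard 6-column PED input ("0" = unknown parent). A *trio* is any
individual with both parents present — counted per child, which uniformly
covers parent–child and grandparent–parent trios and makes each complete
seven-member family contain exactly three trios. A *hepta-family* is a child
with both parents and all four grandparents present. A *duo* is a child with
exactly one parent present; by default only the maternal line counts
(mothers/grandmothers as reference), and a both-parents child is a trio, not
two duos — the pair semantics are configurable (`maternal`/`paternal`/`any`)
because published "pair" counts are not precisely defined. Graphs are
validated acyclic; parent ids absent from the dataset are retained but never
form structures.

## Simulator (`simulate`)

The generator emulates: (i) library-prep concentration heterogeneity —
lognormal(0, σ) scaled to mean 1, default σ = 0.2, chosen so a 96-plex
equal-volume pool shows a >2-fold read-count range in ≳90% of seeds, the
regime reported for real initial runs; (ii) read allocation — multinomial
over `conc x volume x eps` with per-sample lognormal noise of CV 3% per run
(default); (iii) binned depth tracks with planted low-coverage regions for
plant-and-recover tests. It does **not** model base errors, quality scores,
duplication, index hopping, lane effects or GC bias — so passing tests
demonstrate the balancing arithmetic and classification logic, not
instrument behaviour.

Reads per flow cell default to 1e7 (production scale is ~1e9); the balancing
math is scale-invariant, verified by property test. When `run_noise_cv = 0`
the simulator returns exact expected counts instead of a multinomial draw
("auto" sampling), giving the closed-loop noiseless limit its exact-zero
residual; explicit `"multinomial"`/`"expected"` modes override this. All
randomness flows through one `numpy` generator seeded from the config, so a
fixed seed is byte-reproducible (frozen golden test).

One scheduling note: adding rebalanced flow cells does *not* monotonically
shrink the final residual in this model. The residual is dominated by the
round-1 concentration-estimate error, which applies to the rebalanced
fraction `K/(K+1)` of the total — larger for larger `K` — while per-run
noise averages down as `1/sqrt(K)`. At defaults the median final
`max_rel_dev` is ~6.0% for K=1 and ~6.6% for K=2; both sit far below the
initial ~13–60% spread, which is the property the tests assert.

## Numerical and degenerate-input choices

* Ties/degenerate: zero-read samples → failed-library; all-samples-excluded
  → explicit error; zero global mean depth → degenerate-profile error;
  all-zero pool → invalid; odd leftover cycles are dropped by the floor.
* Floats are written with 4 decimals in TSV, full precision in JSON; every
  writer emits a version + config-hash provenance line and round-trips
  through its paired reader.
* Exit codes: 0 success, 1 usage/config error, 2 data/validation error.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the 96-sample, 3-flow-cell
experiment at 1e7 reads per flow cell, Monte-Carlo sweeps over ≤100 seeds,
depth profiles of ≤60 bins x ≤1000 samples, and pedigrees of ≤30 individuals
(against a brute-force subset oracle). These sizes were chosen so the whole
suite completes in seconds while keeping every estimate comfortably inside
its sampling-error bounds.
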