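# seqbalance

Library QC and data balancing for large-scale multiplexed short-read
whole-genome sequencing.

Population-scale WGS runs 96-plex pools across several flow cells. Library
molar concentrations coming out of prep vary enough that an equal-volume
pool yields a more than twofold spread in per-sample reads — some samples
end up under-covered and need costly top-up runs. `seqbalance` implements
the operational math that keeps such a project even and efficient:

* **iDeal re-pooling** (initial-run-based data equalization): sequence the
  equal-volume pool on the first flow cell, read each library's relative
  concentration off its demultiplexed read share (the *index ratio*), then
  re-pool with adjusted volumes so cumulative totals converge on a common
  target over the remaining flow cells. With round-1 totals `t_i`,
  concentrations `c_i`, and `K` remaining runs of `R` reads, the target is
  `T = (Σt_i + KR)/n` and re-pool volumes follow `v_i ∝ max(T − t_i, 0)/c_i`.
* **Planning arithmetic**: symmetric read length from a cycle budget
  (`floor((cycles − index)/2)` — e.g. 325 spare-cycle kits support 162 bp PE),
  flow-cell yield `clusters x 2L`, Lander–Waterman coverage `yield/G`, and
  flow-cells-needed demand math, with a preset table of common platforms.
* **Pool QC**: equal-mass loading volumes against a previously sequenced
  reference pool, denatured sizing of Y-adapter PCR-free libraries
  (RNA-ladder +30 nt correction, −140 bp adapters), dsDNA molarity, an
  inclusive ≥3% freemix contamination filter, and duplication/base-balance
  flags.
* **Coverage accessibility**: per-bin mean depth across ~1000 samples
  (MAPQ ≥ 20 provenance), classification of inaccessible regions below a
  fraction of the global mean, and protocol-vs-protocol diffs showing what
  longer reads recover.
* **Pedigree enumeration**: duos, trios and seven-member (hepta-) families
  from PED files.
* **A seeded simulator** generating every input above with known ground
  truth.

## Worked example

Simulate a 96-plex pool sequenced on three flow cells (one equal-volume
initial run, two rebalanced runs of 1e7 reads each, lognormal σ = 0.2
concentration spread, 3% per-sample run noise):

```console
$ seqbalance simulate ideal --seed 42
initial: max/min 2.38, max dev 58.7%, cv 15.4%
final:   max/min 1.11, max dev 6.2%, cv 2.2%
```

The equal-volume initial run spreads 2.38-fold between the best- and
worst-represented libraries; after re-pooling, the cumulative totals sit
within 6.2% of the mean — inside the <10% band a well-run equalization
should achieve. The same computation is available as a library:

```python
from seqbalance import DemuxCounts, rebalance_volumes

round1 = DemuxCounts.from_reads("run1", {"A": 100, "B": 300})
plan = rebalance_volumes(round1, remaining_runs=1, per_run_reads=400,
                         vmax=30, vmin=0)
print(plan.volumes)                                  # {'A': 30.0, 'B': 3.333...}
print([e.expected_final_reads for e in plan.entries])  # [400.0, 400.0]
```

Sample A (underrepresented 100 vs 300 reads) gets the full 30 uL, sample B
a ninth of that; both project to exactly the 400-read equal target.

Planning and sizing one-liners:

```console
$ seqbalance plan --cycles 325 --index 0
max symmetric read length: 162 bp PE (325 cycles, 0+0 bp index)
$ seqbalance plan --clusters 3e8 --read-length 150
yield: 90.0 Gb (90Gb) -> 30.0x on a 3.0 Gb genome
$ seqbalance size --observed 616
observed 616 nt -> library 646 bp -> insert 506 bp
```

Other subcommands: `quantify` (relative concentrations from demux stats,
generic TSV or BCL-Convert CSV), `rebalance` (plan TSV + JSON report),
`qcfilter`, `coverage aggregate|classify|diff` (bedGraph in, BED out) and
`pedigree` (PED in, structure counts out). See `docs/methods.md` for the
model, defaults and their rationale.

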