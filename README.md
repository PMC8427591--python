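# cotupipe

Consensus DNA barcode reference sequences from multiplexed amplicon NGS
reads.

Building a DNA barcode reference library means sequencing a marker amplicon
(ITS, *matK*, *rbcL*, ...) for each of hundreds of single-species samples.
Pooling everything into one short-read run makes this cheap, but pushes the
work into software: reads must be merged, demultiplexed by inline DNA tags,
grouped, aligned, and distilled into one reliable sequence per sample and
gene. `cotupipe` implements that pipeline for the two-round labelling-PCR
design in which every amplicon carries

```
label + introducer + fwd primer + insert + rc(rev primer) + rc(introducer) + rc(label)
```

with a sample-unique 10-nt label and the fixed 14-nt introducer
`GTAGACTGCGTACC`, and builds the final sequence with a consensus-based OTU
(Cotu) caller.

## The consensus method

For an alignment of `n` reads, the caller:

1. finds the **core range** — the span between the first window of 3
   consecutive columns, from each end, each covered by > 50% of reads;
2. drops **insertions**: inside the core, columns where gaps outnumber
   bases; outside it, columns covered by < 20% of reads;
3. **extends the ends**: columns outside the core covered by ≥ 20% of reads
   are still called, so agreeing minority read ends lengthen the sequence
   beyond what a strict majority-coverage consensus keeps;
4. removes per-column **noise** — bases below 10% of the column's bases —
   before applying the **majority rule**, emitting IUPAC codes for ties.

Bins need ≥ 10× depth; at most the first 500 reads are used. Upstream,
read bins are formed by greedy centroid clustering (identity 0.97 for ITS,
0.99 for plastid markers) and aligned with a center-star MSA under affine
gap scoring. Downstream, output is scored by Kimura two-parameter distance
`d = −½ln(1−2P−Q) − ¼ln(1−2Q)` (ambiguous sites ignored pairwise), per-site
base-frequency error profiles, and recovery/length/depth summaries.

A fully seeded simulator generates multiplexed runs with the exact construct
layout, substitution and homopolymer-biased indel errors, decaying
qualities, lognormal depth bias — plus a truth manifest, so the whole
pipeline is testable for exact recovery without any sequencing data.

## Worked example

```python
from cotupipe import SimParams, run_end_to_end, summarize_run
from cotupipe.simulate import simulate_run

sim = simulate_run(SimParams(n_samples=2, depth_mean=60, seed=7))
res = run_end_to_end(sim.r1, sim.r2, sim.sheet, sim.primers)

print(f"merged {res.n_merged}/{res.n_pairs} read pairs")
summary = summarize_run(res.consensus_sets(), n_samples=2,
                        demux_summary=res.demux.summary)
print(summary.recovery.to_string(index=False))

key = ("S001", "ITS1")
cons = res.consensus[key].results[0]
truth = sim.manifest.entries[key].insert
print(f"S001/ITS1: {len(cons.seq.seq)} nt consensus from {cons.depth_used} reads, "
      f"mean support {sum(cons.support)/len(cons.support):.3f}, "
      f"exact match to truth: {cons.seq.seq == truth}")
```

prints

```
merged 725/744 read pairs
 gene  created  samples  recovery_percent
 ITS1        2        2             100.0
 ITS2        2        2             100.0
matK1        2        2             100.0
matK2        2        2             100.0
rbcL1        2        2             100.0
rbcL2        2        2             100.0
S001/ITS1: 321 nt consensus from 51 reads, mean support 0.997, exact match to truth: True
```

i.e. all 12 (sample, gene) bins of the simulated run yield a consensus
(recovery 100%), and the S001/ITS1 consensus — called from 51 merged reads
carrying 0.5% substitution errors — reproduces the true 321-nt insert
exactly, with 99.7% of column bases agreeing with the calls.

The same steps are available as a CLI (`cotupipe simulate / merge / demux /
cluster / align / consensus / run / eval / profile`); `cotupipe run
--config run.toml --outdir out/` executes the whole pipeline from a TOML
file pointing at FASTQ, sample-sheet and primer-table inputs, and writes one
FASTA per (sample, gene).

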