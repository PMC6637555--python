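# Methods

## Scoring model

A spectrum is reduced to a sparse boolean vector over m/z bins of width
*w* (the fragment tolerance, default 0.5 Da): bin ⌊mz/w⌋ is set for every
peak. Intensities are carried through the readers but ignored by scoring;
the spectrum dot product of an experimental vector *c* and a theoretical
vector *t* is the size of their bin-set intersection, an integer bounded
by min(|c|, |t|). Binning is exact-index — a peak matches a fragment only
if both fall in the same bin; no neighbour-bin matching is attempted, so
the effective matching window for a fragment is up to ±w depending on
where it sits in its bin. Theoretical spectra contain singly-protonated
b- and y-ions only (b_i = prefix residue sum + proton, y_i = suffix
residue sum + water + proton); a/c/x/z ions, multiply-charged fragments
and neutral losses are out of scope.

Candidate retrieval works in neutral-mass space: the query mass is
(precursor m/z − proton) × charge and the precursor tolerance (default
3 Da) is applied symmetrically to the mass-sorted peptide index via
binary search (`numpy.searchsorted` on both edges), giving a half-open
window that provably equals the linear-scan filter.

The two scoring drivers share one ranking contract: score descending,
ties broken by smaller |peptide mass − precursor mass| then lexicographic
sequence, zero scores dropped, at most k = 10 results. Sequences are
unique in the index (identical peptides from different proteins collapse
into one entry carrying all provenances), which makes the ordering total
and is what lets the fused single-pass driver reproduce the two-pass
reference bit-for-bit while holding only a k-element sorted buffer.

## Digestion and masses

Enzymes follow Expasy rules: trypsin cleaves after K/R unless P follows,
LysC after K, AspN before D. Peptides with up to 2 missed cleavages
(concatenations of up to 3 adjacent fully-cleaved fragments) and lengths
6–50 are generated by default; all three limits are configurable. Masses
are monoisotopic, taken from pyteomics' residue table, with one water
(18.010565 Da) per peptide and a proton of 1.007276 Da; fixed
modifications (default: carbamidomethylation of cysteine, +57.021464 Da)
are added per matching residue, in both precursor and fragment masses.
Variable modifications and semi-enzymatic digestion are non-goals.
Peptides containing residues outside the standard 20 letters are skipped
with a logged warning rather than failing the whole database.

## Scheduler

Work is divided into chunks and assigned proportionally to per-worker
weights. A weight starts as the throughput measured by a sample probe
and is penalized when the worker looks overloaded: if CPU utilization
exceeds 0.9 the weight is multiplied by (1 − memory utilization) and
divided by (1 + run-queue length per core). Memory utilization is
(MT − MF − Buffers − Cached)/MT from the usual /proc/meminfo quantities;
the three load statistics have no canonical combination formula, so a
monotone bounded one was chosen. Proportional allocation uses the
largest-remainder rounding rule with worker-id tie-breaks, making the
partition deterministic and scale-invariant in the weights.

During execution the feedback loop runs at every chunk-completion
report: the worker's observed throughput (completed chunks per unit busy
time) is folded into its weight by geometric smoothing
w ← α·w_old + (1 − α)·w_observed with α = 0.5 by default (α = 1 freezes
the weights), and unstarted chunks are moved from the worker with the
largest projected finish time to the smallest while the projected
imbalance exceeds the threshold (default 0.08) and a move still narrows
the gap. Started chunks never move, so no unit of work is lost or
duplicated. Final balance is measured as (max − mean)/mean over
per-worker busy totals; the metric has no canonical definition, and this
deviation-of-the-maximum form was fixed once. On a simulated 3-worker
1:1.5:2 heterogeneous workload of 300 chunks the median final imbalance
is about 3%, comfortably below the 8% threshold.

Live /proc probing (two-sample CPU utilization, loadavg, meminfo) exists
behind the same interface for the CLI `probe` command; every test and
simulation uses seeded simulated workers instead, so results are
hardware-independent.

## Pipeline

The search runs in four phases: (1) load the FASTA and MGF inputs, build
the index and partition the spectra into chunks via a scheduler probe;
(2) the "unrefined search" — precursor-window candidate retrieval for
every spectrum; (3) per-chunk fragment scoring on a thread pool fed
through a pair of bounded circular queues (request and response), each
with head/tail counters and default capacity 2, which realizes double
buffering: one chunk is in transit while another is being scored;
(4) global merge ordered by (spectrum source index, rank) and TSV
report. Because scoring one spectrum depends on nothing else and the
merge is a sort, the report is byte-identical for any worker count,
chunking or driver — this exact equivalence replaces any
similarity-based accuracy comparison. A worker that dies mid-chunk
requeues its in-flight chunk before exiting (supervised requeue), which
preserves exactly-once processing as long as at least one worker
survives; queue enqueue/dequeue counters verify conservation.

Python threads are the worker transport. The point of the pipeline here
is the execution contract (bounded in-flight work, conservation,
determinism), not wall-clock speedup; no timing claims are made or
tested.

## Synthetic data

The fixture generator emulates a spike-in experiment: random proteins
(uniform residue composition, lengths 80–160, 40 by default) are
digested, and 200 distinct peptides are turned into spectra from their
own b/y fragments with 30% of fragments removed at random, 5 uniform
noise peaks in 100–1500 m/z, charges drawn from {2, 3}, precursor m/z
perturbed uniformly within ±0.5 Da (inside the 3 Da tolerance at these
charges) and uniform (0, 1] intensities. The same spec and seed yield
byte-identical files. What this does **not** model: realistic fragment
intensity patterns, isotope envelopes, co-eluting chimeric spectra,
biological amino-acid frequencies, decoy statistics. Passing the
spike-in recovery test therefore demonstrates the engine's correctness
and determinism, not identification sensitivity on real instrument data.

Scheduler workloads are lognormal per-chunk costs (σ = 0.1 around unit
cost), a mild heterogeneity consistent with spectra chunks of equal size
but varying candidate counts.

## Numerical and design notes

- Bin indices are int64; bin width mismatches between two spectra are a
  hard error, not a silent rescale.
- Report masses are printed to 5 decimal places; scores are integers, so
  the report round-trips losslessly.
- The tie-break on equal intensity in top-N peak filtering is (intensity
  desc, m/z asc); top-N filtering is disabled by default.
- Degenerate inputs: empty spectra files produce a header-only report;
  empty candidate windows produce no PSMs; all-zero worker loads define
  imbalance 0.
- Problem sizes in the test battery (e.g. 200 randomized databases for
  the equivalence check, 10,000 vector pairs for the kernel oracle,
  10,000 chunks for queue conservation, 50 scheduler seeds) were chosen
  to exercise each property densely while keeping the whole suite in the
  tens of seconds.

## Known limitations

No decoy/FDR machinery, E-values or hyperscores — the rank-1 SDP match
is reported as-is. Exact-bin matching makes scores sensitive to where a
peak falls within a bin. The scheduler's overload-combination formula
and the imbalance metric are reasonable fixed choices, not fitted to any
measured system. MGF is the only spectra dialect on the test surface.
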