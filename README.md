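# hfrmap

Detection of donor-derived recombination tracts and pooled selection
mapping for bacterial conjugation crosses.

When an Hfr donor strain conjugates with a divergent recipient and the
recombinants are selected for a marker allele, each surviving clone carries
one or more contiguous donor tracts, one of which must span the selected
locus. `hfrmap` is a toolkit for the computational side of such crosses,
aimed at microbial geneticists doing QTL-style trait mapping by
conjugation:

* **Polymorphic sites** — extract core-genome ancestry markers from a
  two-genome XMFA alignment, with synteny filtering (blocks ≥ 110 bp, no
  > 100 kb donor-coordinate jumps, majority strand), plus
  homology-opportunity density (runs of ≥ 20 / ≥ 27 bp strict identity per
  100-kb bin).
* **Competitive read classification** — label each read donor-better /
  recipient-better / tie / genome-specific, from bwa alignments (`AS`
  scores) or with a built-in exact-seed classifier for synthetic data.
* **Tract delineation, two independent ways** — a 2-state Bernoulli HMM
  (Viterbi) over ordered binary read labels, and exact penalized
  changepoint segmentation (PELT, SSE cost, penalty 3) of per-site
  donor-allele frequencies; concordance reports, fragment statistics, and
  coverage-downsampling robustness.
* **Pool mapping** — 1-kb binned donor/recipient profiles from pooled
  recombinant sequencing; the argmax of log10(donor/recipient) localises
  the selected locus to ~±1.5 kb, a counter-selected cassette appears as a
  dip, and decay/insertion-density profiles support the analysis.
* **Interval-intersection model** — the shared donor region across n
  selected recombinants has E(Λn) = 2μ/n with μ = 1/E(1/L) the harmonic
  mean of the marker-covering tract lengths: short tracts dominate μ, so
  tract-length heterogeneity *improves* mapping precision. Monte-Carlo
  simulator plus closed forms.
* **Synthetic crosses** — a generator for genome pairs (tunable core
  divergence, accessory segments), recombinant clones (1–16 tracts,
  ~1 kb–1 Mb, one forced over the marker), reads, and pools, with
  machine-readable truth (FASTA/FASTQ/BED/TSV/JSON) for every stage.

## Worked example

How tightly can a pool of selected recombinants localise the selected
locus? First the model's prediction for n = 100 clones with tract lengths
log-uniform on [10 kb, 1 Mb]:

```sh
$ hfrmap model --n 100 --reps 10000 --seed 1
{
  "n": 100,
  "mean_lambda": 922.5694332663195,
  "harmonic_mean_mu": 46516.87056553628,
  "analytic_2mu_over_n": 930.3374113107255,
  "n_mean_lambda_over_mu": 1.9833007294988558
}
```

The harmonic mean μ ≈ 46.5 kb (versus an arithmetic mean of ~215 kb — the
short tracts dominate), so the donor region shared by all 100 clones
shrinks to ~0.9 kb; the simulated constant n·E(Λn)/μ ≈ 1.98 confirms the
2μ/n law.

Now an in-silico pool: 50 selected recombinants on a 1 Mb genome at 1%
divergence, marker at 500 kb, 100x aggregate coverage, 0.1% read error:

```sh
$ echo 'n_clones: 50' > pool.yaml
$ hfrmap pool --config pool.yaml --seed 1 --outdir pool_run
{
  "peak_position": 499500,
  "peak_value": 2.7315887651867388,
  "interval": [
    499000,
    500000
  ],
  "tie": false,
  "marker_position": 500000,
  "abs_error": 500,
  "half_decay_left": 25500.0,
  "half_decay_right": 28500.0
}
```

The profile peak lands 500 bp from the true marker — within one 1-kb bin,
matching the ±1.5 kb localisation the method is built for — and donor
presence decays to half its peak ~25–30 kb to either side, reflecting the
tract-length distribution. `pool_run/` contains the binned profile (TSV and
BEDGRAPH), the peak BED, the pool manifest, and the resolved configuration.

The clone-level pipeline works the same way (`hfrmap segment --seed 1`):
it simulates clones, classifies their reads, delineates donor tracts with
both methods, and writes per-clone BEDs plus a concordance table. Real data
enters at any stage: XMFA into `hfrmap sites`, bwa SAMs into
`hfrmap classify`, and the library functions accept the corresponding
tables directly.

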