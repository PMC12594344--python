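# Methods

`hfrmap` analyses genomes produced by conjugative crosses between two
divergent bacterial strains: an Hfr donor transfers chromosomal DNA into a
recipient, homologous recombination integrates it as one or more contiguous
tracts, and selection for a marker allele guarantees that every surviving
recombinant carries donor DNA over the selected locus. The package answers
two questions: *which intervals of a recombinant genome are donor-derived*,
and *where is the locus under selection*, given only sequencing reads and
the two parental genomes.

## The synthetic cross

All validation runs on synthetic crosses with exact ground truth, generated
by `hfrmap.synthetic`.

**Genome pair.** A random ancestor of length `genome_length` is the
recipient core; the donor core differs at Bernoulli(`divergence`) positions
(substitutions only, uniform over the three alternative bases). Optional
accessory segments — random sequence inserted into one genome only — model
strain-specific regions; they are excluded from the polymorphic-site truth
table and generate the DONOR_ONLY / RECIPIENT_ONLY read classes. The truth
coordinate map (maximal co-linear core blocks) and site table are emitted
with the FASTA genomes.

Defaults mirror the experimental design this emulates: strain pairs whose
core genomes differ at roughly 1% of sites, 150-bp reads, ~10x coverage for
single clones and ~100x for pools. The standard test fixture is a 1 Mb
genome at 1% divergence — a deliberate scale-down from a ~4.6 Mb
enterobacterial chromosome that preserves site density (the quantity the
methods actually consume) while keeping the whole suite fast; fragment
lengths and bin sizes are kept at their real scales, so peak precision and
boundary resolution are unchanged.

**Recombinants.** Each clone receives one marker-covering fragment whose
length L is drawn from a configurable `FragmentLengthDistribution`
(default log-uniform on 10–500 kb, matching the observed three
orders-of-magnitude spread of tract lengths) and whose left overhang over
the marker is uniform on [0, L) — the conditional law of a uniformly
positioned interval given coverage of a point. A Poisson(λ = 1.5) number of
extra fragments (observed strain means range from ~1.65 to ~7.125 total
fragments per clone; λ = 1.5 puts the default total near the low end of
that range) is placed uniformly within a 500-kb window around the marker
fragment ("neighbourhood" placement; a genome-wide mode covers the minority
pattern of distant tracts). Overlapping fragments are merged. The
recombinant sequence is the recipient with donor alleles substituted inside
the fragments; because divergence is substitution-only, clone coordinates
equal recipient coordinates and sequence length is conserved.

A counter-selected locus is modelled as an interval (e.g. a ~3-kb
resistance cassette) that no fragment may overlap; offending fragments are
redrawn. This reproduces the biology of a cassette whose loss is lethal
under selection and yields a donor-free zone whose profile signature the
pool stage must localise.

**Reads and pools.** Single-end, fixed-length (150 bp) reads with uniform
start positions and i.i.d. substitution errors (default 1e-3), constant
Phred quality; read count = round(depth × genome / read length). The
paired-end layout of real data adds no information to per-read
classification, so it is not simulated. Pools draw multinomial per-clone
read counts proportional to clone weights and record the true contribution
per clone in a JSON manifest. What the generator does *not* emulate —
indels and rearrangements between cores, GC/coverage bias, insertion-
sequence dynamics, quality-score structure — bounds what green tests prove:
they validate the statistical machinery on the model's assumptions, not
robustness to real-data artefacts.

## Polymorphic sites (`core_sites`)

For real data, sites come from a two-genome core alignment in XMFA format
(read via Biopython's Mauve parser). Blocks are filtered before extraction:

* length ≥ 110 bp ("shorter than" reads strictly less; sub-110 bp blocks
  are typically spurious homologies in accessory genes);
* majority relative orientation (absolute strand is alignment-arbitrary,
  so "opposite strand" is interpreted as the minority orientation);
* donor-coordinate jump from the previous retained block ≤ 100 kb, walking
  blocks in recipient order. The distance is measured on the donor side
  because a recipient-side gap is an ordinary accessory region, whereas a
  large donor-side jump marks a translocated or spurious homology.

The filter order (length → strand → distance) is configurable; the three
rules commute except on contrived inputs. Site extraction keeps aligned
columns where both characters are unambiguous nucleotides and differ; gaps
and ambiguity codes are skipped, and duplicate recipient positions from
overlapping blocks keep the first occurrence. On synthetic pairs the truth
coordinate map bypasses the aligner entirely (`blocks_from_pair`), and
extraction must reproduce the generator's site table exactly — a round-trip
the suite enforces.

The same aligned columns yield the homology-opportunity track: maximal runs
of strict identity of length ≥ k (k = 20 and 27 bracket the minimal
efficient substrate for RecA-mediated strand exchange), counted per 100-kb
bin at the run midpoint.

## Read classification (`classify`)

Reads are compared against both parents and labelled DONOR_BETTER,
RECIPIENT_BETTER, TIE, DONOR_ONLY, RECIPIENT_ONLY, or UNMAPPED; the
partition is exhaustive and exclusive.

`classify_from_sam` consumes competitive alignments (one SAM/BAM against a
`donor|`/`recipient|` two-genome reference, or two per-genome files) and
compares best alignment scores (AS tag); equal scores are ties,
single-genome hits are the `*_ONLY` classes, and alignments under a
configurable mapping-quality floor (default 0) are ignored.

`classify_builtin` is the aligner-free equivalent used on synthetic data:
reads are placed by exact 21-mer seeds tried at up to seven offsets, first
on the recipient index, then on the donor index with projection through
the core coordinate map (a read that cannot be projected — i.e. it touches
donor-specific sequence — is DONOR_ONLY). Placed reads are scored by the
majority vote of donor vs recipient alleles at covered polymorphic sites;
the vote margin is the score. Ambiguous seeds (repeated 21-mers) are
skipped; at 1% divergence and 1e-3 error, a read has several informative
sites on average and seed placement fails only in pathological windows.
Both classifiers agree on error-free reads, which a bwa-based integration
test checks end to end.

Each label records the read's leftmost recipient coordinate (used for
binning) and the first/last covered site supporting its winning allele.
Segmentation uses the site-based coordinates: a boundary read extends up to
a read length beyond its last discriminating site, so read-start boundaries
would inflate the fragment by ~150 bp, while site-based boundaries are
accurate to the local inter-site spacing — the information-theoretic limit.

Donor-allele frequencies per site count reads carrying each parental
allele; bases matching neither (errors) are excluded from both counts, and
uncovered sites are flagged rather than given a frequency.

## Tract delineation (`segmentation`)

**HMM on read labels.** Informative reads, ordered by genomic position,
give a 0/1 series (1 = donor-better). A homogeneous 2-state chain with
Bernoulli emissions (defaults e_d = 0.95, e_r = 0.05: a label flips only
when sequencing errors overwhelm the few discriminating sites a read
covers) and symmetric switch probability t = 1e-3 per observation (tracts
span thousands of reads at 10x; t trades boundary sharpness against
over-segmentation and is deliberately not distance-scaled, since
observation density is roughly uniform — a distance-scaled variant would
matter only for very uneven coverage) is decoded exactly by Viterbi; the
suite proves exactness against full path enumeration for n ≤ 12 and against
an independent HMM implementation. Forward–backward posteriors flag
"unresolved" clones — mixed colonies whose ancestry never commits (max
posterior < 0.8 over > 20% of observations). Optional EM refinement of the
emission/transition parameters exists nowhere: parameters are fixed for
reproducibility and the defaults are insensitive over the regime the
generator produces (vote margins are rarely marginal).

**Changepoint segmentation of site frequencies.** The covered-site donor
frequency series is partitioned under a piecewise-constant-mean model,
minimising within-segment sum of squares plus a penalty of 3 per
changepoint (the value small enough to keep kb-scale tracts while ignoring
single-site error blips; min segment length 2 sites). The optimiser is
PELT with pruning constant 0 — exact for this cost — and the suite checks
equality with an unpruned O(n²) dynamic program for n ≤ 30. Segments with
mean donor frequency > 0.5 become donor fragments; adjacent donor segments
merge.

Both methods report fragments half-open in recipient coordinates with
boundaries at the first/last supporting site, making them comparable
base-for-base: `compare_methods` reports the per-base Jaccard index of
donor territory and matched fragment pairs (reciprocal overlap ≥ 0.5).
`fragment_stats` summarises lengths per clone and compares
marker-containing vs other fragments by a two-sided Mann–Whitney test.
`downsample_robustness` subsamples classified reads without replacement
(per-read classification is independent of other reads, so this is
identical to subsampling the FASTQ) and re-runs both segmentations at each
fraction.

## Pool mapping (`pool`)

Informative pool labels are binned (1 kb default) into donor/recipient
counts; the profile carries the donor fraction (undefined on empty bins)
and log10((donor + c)/(recipient + c)) with pseudocount c = 1 — the
pseudocount only matters in donor-free bins, where it pins the ratio floor.
The selected locus is the argmax bin's centre (leftmost on ties, flagged),
with a support interval of contiguous bins within log10(2) of the peak. A
counter-selected locus is the mirror image: because every bin the forbidden
cassette shadows sits at the ratio floor, single-bin argmin placement would
be decided by noise among tied bins, so the dip is reported at the centre
of the contiguous run of bins within log10(2) of the minimum. Localising
that dip to a few bins requires pool sizes in the hundreds of clones —
bins abutting the cassette are reachable only by fragments that begin or
end within a few kb of it — which matches how pooled selections are
actually sequenced (the whole selection plate, not dozens of colonies).

`decay_profile` re-indexes bins by signed distance to the marker and
reports the half-decay distance on each side (first bin whose donor
fraction falls below half the marker bin's value); longer tract-length
distributions decay more slowly, and for fixed L the decay is linear,
vanishing at distance L. `insertion_density` bins a transposon
insertion-site table at 250 kb and expresses, per bin, the distinct-site
count and the summed read coverage as log2 fold-changes against the mean
per-bin value inside the Ter macrodomain (supplied as BED — no organism
coordinates are hard-coded), plus the correlation between the two metrics.

## The interval-intersection model (`interval_model`)

With n selected recombinants, the region that must contain the selected
locus is the intersection of n marker-covering fragments:
Λn = min(U_i) + min(L_i − U_i) with U_i | L_i ~ Uniform[0, L_i). The
simulator draws this law directly (genome edges ignored — fragments are
small relative to the genome); the large-n expectation is

    E(Λn) = 2μ/n,   μ = 1/E(1/L),

the harmonic mean of the marker-covering fragment lengths. μ is computed in
closed form per distribution family (for log-uniform on [a, b]:
μ = ln(b/a)/(1/a − 1/b)). The distribution parameter is interpreted as the
law of *marker-covering* fragment lengths — length-biased sampling is
already folded in, matching the definition of μ; apply length-biasing
upstream if starting from a genome-wide tract-length law. Because the
harmonic mean is dominated by its short tail, admixing kilobase-scale
tracts shrinks E(Λn) far below what the arithmetic mean would suggest —
heterogeneous tract lengths *sharpen* pooled mapping. The suite verifies
the n = 1 and n = 2 closed forms, pathwise monotonicity in n, and
convergence of n·E(Λn)/μ to 2 (within 5% at n = 100) for fixed,
log-uniform, and two-point length laws.

## Numerical and degenerate-input conventions

* Coordinates 0-based, half-open, recipient frame; genomes linear
  (fragments never wrap the origin).
* All randomness flows from integer seeds through `numpy.random.default_rng`;
  every pipeline is a pure function of (inputs, config, seed) and reruns are
  bitwise identical.
* Viterbi and the HMM likelihood run in log space; forward–backward uses
  scaled recursions.
* Empty series/profiles: empty read sets and site lists classify to empty
  tables; segmentation of an empty series is an empty fragment list; a
  profile with no informative bin raises rather than inventing a peak.
* Argmax/argmin ties resolve leftmost and are flagged.
* PELT tie-breaks prefer the earlier candidate (stable argmin), matching
  the oracle DP's strict-improvement rule.

## Known limitations

* Substitution-only divergence: indels or rearrangements between cores
  would shift coordinates and are not handled; real data with structural
  variation relies on the external aligner upstream.
* The builtin classifier requires exact seed matches; error rates ≫ 1% or
  heavily repetitive genomes would degrade placement (real data should go
  through bwa and `classify_from_sam`).
* The HMM is homogeneous per observation, not per base; extreme coverage
  unevenness would distort the effective switch rate.
* Fragment boundaries are only resolvable to the local inter-site spacing;
  at 1% divergence this is ~100 bp on average but locally variable.
* The counter-selection dip estimator assumes a single forbidden locus;
  multiple counter-selected sites would need the profile minimum search
  run per candidate region.
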