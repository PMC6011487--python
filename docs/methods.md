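# Methods

## Model and procedure

`linkscaf` infers contig adjacency from droplet-barcode co-occurrence. The
generative picture: long DNA molecules (exponentially distributed lengths,
mean tens of kbp) are sampled across the genome; each is sequenced to low
depth (≪ 1×) with short paired-end reads carrying the droplet barcode; one
barcode tags several molecules (barcode reuse). A molecule crossing the
junction between two contigs deposits reads near both facing contig ends, so
the ends share its barcode.

Only the terminal *e* bp of each contig (head and tail regions) are
considered; interiors are masked. This keeps memory proportional to contig
*ends* rather than assembly size, suppresses noise from mid-contig mappings,
and makes barcode sharing specific to junctions.

### Read mapping

Canonical kmers (lexicographic min of kmer and reverse complement) of all
end regions are hashed to their end; kmers occurring in more than one end
are discarded as ambiguous, so a lookup can never attribute a read to the
wrong end. Strand folding means reads map identically from either
sequencing strand — necessary because orientation inference must come from
barcode sharing alone, not read strand. A read maps to the end maximising
the fraction of its kmers found for that end (`score_j`); the denominator is
all valid read kmers, including those dropped from the index, so scores are
comparable across reads. Mapping requires `score_j ≥ j` (default 0.55),
a unique maximum (ties discarded), and both mates of a pair on the same
contig end (head vs tail of one contig counts as disagreement — the
stricter reading, which costs little and reduces noise).

### Barcode filters

Three thresholds control noise, mirroring the tool's command-line flags:
`-m lo-hi` drops barcodes whose total read-pair multiplicity in the dataset
falls outside [lo, hi] (degenerate or over-amplified droplets); `-c` requires
at least c read pairs behind each (barcode, end) association; `-l` requires
strictly more than l shared barcodes per emitted edge.

### Orientation test

For each contig pair the four orientation tallies (HH, HT, TH, TT) are
compared. When more than one orientation has support, the two largest
counts c₁ ≥ c₂ are tested against Binomial(c₁+c₂, ½) with an exact
two-sided p-value (total probability mass of outcomes no more likely than
the observed one, computed in integer arithmetic — no normal
approximation); the edge is kept with the winning orientation iff
p < r (default 0.05). A pair supported in a single orientation needs no
arbitration and is accepted outright, carrying the degenerate p-value of c₁
successes in c₁ trials so the output schema is uniform.

### Gap-size estimation

Because the Jaccard-versus-distance relationship depends on depth and
molecule lengths, it is learned from the run itself: every contig longer
than 2e supplies one training sample — its head/tail barcode-set Jaccard
index against the known inner separation (length − 2e). A candidate join's
gap is the median separation of the B (default 20) training samples with the
nearest Jaccard index; ties break by training order, an even-count median is
the rounded mean of the central pair, and B is capped at the sample count.
Estimates are therefore always inside the training range: the estimator can
interpolate but never extrapolate. Empty barcode sets score Jaccard 0 so
estimates stay defined.

### Path building

Full-featured downstream scaffolders are deliberately out of scope; layouts
come from a conservative reciprocal-best walk. An end extends through its
strongest edge only if that edge is also the strongest at the partner end
and the runner-up support at both ends is ≤ a (default 0.5) times the best.
Each end then carries at most one accepted link; components are simple
chains or cycles, and cycles are broken at their weakest link
(deterministic tie-breaks throughout). Joins are written as N-runs of the
estimated gap (floored at 10 N so joins stay visible to downstream tools),
or 100 N without an estimate. Contigs below the `-z` length floor, and
those too short to form two non-empty ends, pass through unscaffolded.
Contigs shorter than 2e are split at the midpoint into non-overlapping
halves so a molecule spanning the whole contig still discriminates its ends.

## Simulator

The generator emulates Chromium sequencing of a fragmented draft: a uniform
random genome; contigs as a near-even split with ±25 % length jitter by
default (configurable up to heavily dispersed); inter-contig gaps
Uniform(lo, hi) whose sequence is removed from the draft but retained in the
read source, then shuffled contig order and random strand flips; molecules
started uniformly with Exponential(mean) lengths truncated at the genome
end; Poisson(rate × length) read pairs per molecule with Normal(400, 50)
inserts and 150 bp reads; optional uniform substitution errors (0 by
default, since exact-kmer mapping is tested separately from error
robustness). Truth tables record contig order/strand/gaps and per-pair
molecule provenance. Everything derives from one seed; outputs are
byte-identical across reruns.

Defaults define the package's reference conditions: 2 Mbp genome, 40
contigs, gaps 0–5 kbp, 50 kbp mean molecules, 10 molecules per barcode,
0.35 read pairs per molecule-kbp (≈ 0.1× per-molecule depth, typical of
Chromium data) and 760 barcodes, giving ≈ 20× genome depth.

What the simulator does *not* model: GC or mappability bias, chimeric
molecules, barcode sequencing errors or whitelists, real insert/quality
profiles, and genomic repeats (the genome is i.i.d. random, so the
multimapped-kmer path is exercised only lightly). Passing tests demonstrate
algorithmic correctness under the stated generative model, not performance
on real libraries.

## The desk-scale regime and its limits

Two dimensionless ratios control how informative linked reads are here:
molecule length relative to contig length, and per-barcode molecule
footprint relative to genome size. On real genomes both are small; at
desk scale they are not, and the reference conditions deliberately sit in
the hostile corner:

- With 50 kbp molecules over ~50 kbp contigs, a large fraction of
  junction-spanning molecules also reach the far end of a contig, so the
  same barcode supports several orientation quadrants at once. The binomial
  arbiter then (correctly) refuses many true pairs: measured adjacency
  recall at the reference conditions is ~65–70 %, while accepted joins
  remain > 95 % correct — the test trades recall for precision exactly as
  designed.
- Each barcode's 10 molecules cover ~25 % of a 2 Mbp genome, so unrelated
  end pairs share O(10) barcodes by reuse alone, inflating every tally cell.
- Training separations (contig length − 2e ≈ 15–37 kbp) sit far above the
  0–5 kbp gaps, so gap estimates clamp to the low edge of the training range
  and carry essentially no resolving power there (reported correlation ~0).

Shrink either ratio and the same code recovers the expected behaviour: the
test suite includes a configuration with 15 kbp molecules over 40–90 kbp
contigs (perfect adjacency/orientation recovery) and a gap-recovery
configuration with dispersed contig lengths whose training domain covers the
gap range (estimate-versus-truth Pearson r ≥ 0.8 across ≥ 25 joins, with the
monotone-decreasing Jaccard–distance trend). On real data the published
regime corresponds to the favourable corner.

## Numerical and design choices

- Coordinates are 0-based half-open; pair keys always carry the
  lexicographically smaller contig id, with orientation re-expressed
  accordingly; edge and layout outputs are sorted for byte-identical reruns.
- Within-end kmer repeats are kept — only cross-end ambiguity is discarded.
- Barcode multiplicity is counted over all read pairs of the dataset
  (mapped or not) in a first pass; `-c` counts read pairs, not reads.
- The binomial p-value uses exact integer arithmetic (`math.comb`); the
  suite cross-checks it against `scipy.stats.binomtest` and an independent
  Fraction enumeration.
- `-t` (threads) is accepted for interface compatibility and validated, but
  execution is sequential; outputs are defined to be thread-count invariant
  and tested as such.
- The `evaluate` scorer calls a join correct only when the two contigs are
  genomic neighbours *and* both face the same genomic direction with the
  predecessor on the correct side (mirror layouts count, reflecting scaffold
  strand arbitrariness).

## Known limitations

- The path builder is a stand-in for full downstream scaffolders: no
  multi-round distance-binned linking, no use of gap estimates during path
  choice, no repeat-aware node splitting.
- Gap estimates inherit the estimator's inability to extrapolate below the
  shortest training separation; drafts whose contigs are uniformly long
  relative to e cannot resolve small gaps.
- Exact kmer matching is sensitive to sequencing error at large k (an
  error-free default is assumed upstream, as with barcode whitelisting);
  the simulator's error knob exists for stress testing, not calibration.
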