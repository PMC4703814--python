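# Methods

This note records the models, conventions and numerical choices behind
`massdiv`, in the order the pipeline runs.

## Alignment and identity conventions

All identity computations share one aligner (`massdiv._align`): global
alignment with affine gaps, BLOSUM62 (open −11, extend −1) for protein and
match +2 / mismatch −3 (open −5, extend −2) for nucleotides.  Three
denominators are used, each matched to its question:

* **exclude** (default): identical columns / aligned span, terminal gap
  columns excluded — comparing a partial amplicon fragment against a
  full-length reference.  Internal gaps count as mismatches.
* **count**: identical columns / all alignment columns, computed on a
  strict end-to-end alignment — used by the chimera scorer, where two
  reads are expected to correspond end to end and free terminal gaps
  would let a half-matching read masquerade as identical.
* **shorter**: identical columns / length of the shorter sequence — used
  for family classification, where a lucky 15-residue window of an
  unrelated reference must not outscore a genuine 70%-identity full-length
  match.

Identity is made symmetric by canonicalizing argument order before
alignment (aligner tie-breaking is otherwise order-dependent).

## Coordinate system

All positional claims are expressed in the coordinates of a reference
MasD protein ("anchor"): diagnostic motif at position 435, catalytic
cysteine at 477, clustering region columns 398–500 (1-based; 103 columns).
The bundled anchor is *synthetic* — a deterministic random protein
carrying those features at exactly those coordinates — because the
genuine database sequence is not redistributed with the package.  Every
coordinate-dependent operation (motif check, cysteine check, region
extraction) takes the anchor as a parameter, so a real reference panel
can be substituted without code changes.  Public APIs are 0-based
half-open; 1-based anchor positions are converted at the boundary.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not a
sequencer:

* **Community**: `n_otus` reference proteins evolved from the anchor
  fragment on a star topology (radial divergences spread over 6–45%,
  motif and catalytic cysteine protected; substitution count is the
  deterministic `round(d·L)`).  Global OTU abundances are lognormal
  (σ = 1 on the log scale — a moderately uneven community); the most
  abundant `cosmopolitan_fraction` of OTUs occur at every site, the rest
  at a random `site_overlap` fraction of sites.  Per site, reads are
  multinomial draws of size `reads_per_site`.  Defaults (12 sites, 40
  OTUs, 200 reads/site) are a desk-scale rendering of a multi-site seep
  survey; tests and the acceptance script state the sizes they use.
* **Reads**: barcode (8 nt) + a concrete realization of the degenerate
  forward primer + a seeded back-translation of the OTU's protein + the
  reverse-complemented reverse primer.  Back-translation chooses
  synonymous codons uniformly (one seeded draw per reference, so reads of
  an OTU share a coding sequence) and then repairs codon choices so no
  homopolymer run exceeds 8 bp — real coding sequences essentially never
  contain 9-base runs, and without the repair the generator would plant
  false positives for its own homopolymer filter.
* **Errors**: per-base substitutions; per-base indels whose probability
  is multiplied (default ×8) at bases extending a run of ≥ 3 — the 454
  idiom that motivates the homopolymer filter.  Insertions duplicate the
  base; deletions drop it.  Phred qualities are drawn from a truncated
  normal clamped to [2, 40], *independently* of the planted errors (a
  documented simplification: quality-based filters exercise their
  mechanics, not error enrichment).
* **Chimeras / off-targets**: a deterministic `round(fraction·n)` count
  of reads per site is replaced.  Chimeras join two parent reads at a
  crossover uniform in the central 60% of the read (so both segments are
  long enough to be detectable); off-target reads are back-translated
  fragments of motif-free NmsA/BssA-like references carried by the same
  primers.  Every read receives one truth record.
* **Strain pairs**: strains on a star phylogeny around a 16S/protein
  anchor pair.  Radial 16S divergences are spread evenly up to
  `max_16s_divergence` (default 12%); each strain's protein divergence is
  set so the *pairwise* identities obey `S_prot = intercept + slope·S_16S`
  with Gaussian scatter `noise_sd`.  Because mutations of different
  strains can coincide (homoplasy), realized identities bend slightly
  upward at high divergence; the fitted slope is attenuated by a few
  percent, but mapped thresholds — the quantities that matter — stay
  within ±1 point of the design line under the default ranges.

## Read quality control

Rules run in a fixed order — primer → length → homopolymer → mean quality
→ ambiguity → chimera — and a read is counted in the ledger under its
first failure, so ledgers are reproducible and sum to the input count.
"> 8 homopolymers" is read as "maximum homopolymer run length > 8 bp", the
convention of amplicon QC tools; "average quality < 20" is the mean Phred
over the post-trim read.  The reverse primer is not required (fragments
may end before it) but is trimmed when found near the 3′ end (≤ 2
mismatches); the 200-bp length test runs after trimming.

The chimera screen is a deliberately simple abundance-ordered two-parent
scorer with the same contract as full-featured detectors (and is pluggable
behind `QCParams.run_chimera_check`).  Dereplicated sequences are
processed in decreasing abundance (ties by smallest member id); candidate
parents are previously accepted sequences with ≥ 2× the query's abundance
(capped at the 20 most abundant, then narrowed to the 4 closest by
full-length identity).  At each crossover point in {0.25, 0.5, 0.75} the
query and every parent are split at the same relative position; the score
is `min(left, right segment identity to the best distinct parents) −
max(full-length identity to those two parents)`.  Genuine reads score ≤ 0
because both segments choose the read's nearest neighbour; measured on
simulated data the screen attains recall 0.80–0.84 at zero observed false
positives with the default threshold 0.05.  The threshold is a score
*excess*, bounded above by roughly half the parents' distance — values
above ~0.3 are unreachable by construction.

## Translation screen

Reads are translated in the three forward frames only (amplicons are
orientation-fixed by the forward primer; a config flag enables
reverse-complement scanning).  Frame choice prefers motif-and-no-stop,
then motif, then no-stop, then frame 0, ties to the lowest frame.  Motif
matching is exact over the six motifs, leftmost hit first (the motif is
searched anywhere in the read, and its position reported, rather than
demanding a fixed aligned position).  The catalytic-cysteine check aligns
the read to the anchor and inspects the residue in anchor column 477;
alignment identity < 25% is reported as `unalignable`.  Family
classification is best-hit identity (coverage-aware, "shorter"
denominator) against a labelled panel at a 0.40 floor — above the ~0.30
twilight zone, below within-family identity; ties resolve
MasD > NmsA > BssA > Pfl.  A trailing stop codon (the read ending at a
gene boundary) is not counted as an internal stop.

## OTU clustering

Accepted proteins are projected onto the anchor's region columns; reads
covering < 80% of the region are dropped with a ledger entry.  Distances
are computed column-wise on these fixed anchor columns (the convention of
alignment-based OTU tools): both-residue columns are match/mismatch,
internal gap columns mismatch, columns outside either sequence's span are
excluded; a per-pair global-alignment mode (`pairwise="global"`) is
available.  Sequences are dereplicated first (O(u²) scaling);
multiplicities re-expand into the OTU table.

Clustering is agglomerative with a threshold stop: merge while the
minimal inter-cluster linkage distance is ≤ the threshold.  Ties break on
the lexicographically smallest pair of cluster representatives, making the
partition independent of input order.  Default thresholds 0.04 / 0.14 /
0.28 correspond to the calibrated 96 / 86 / 72 % identities.

**Default linkage is nearest-neighbour (single).**  The alternatives are
exposed (`furthest`, `average`) and obey the expected ordering of OTU
counts, but with sequencing errors and no denoising stage, complete and
average linkage shatter the cloud of error-bearing reads around each true
sequence into spurious OTUs (measured: 2–2.5× inflation at a 0.5%/base
substitution rate), while single linkage chains those reads back to their
parent and recovers the simulated richness within ±10%.  Single linkage
can in principle chain distinct OTUs through intermediates; at the
calibrated 4% species threshold with OTUs ≥ 10% diverged this does not
occur.  Absolute OTU counts from any particular linkage are therefore
treated as convention-dependent, not as reproduction targets.

## Diversity statistics

Definitions follow the survey-table conventions: `SSO_abs` = OTU with
exactly one read in the whole dataset (observed at this site);
`SSO_rel` = one read here, more elsewhere; Good's coverage
`C = [1 − n/N]·100` with `n = SSO_abs + SSO_rel`, rounded to integer
percent; inverse Simpson defaults to the plug-in `1/Σp²` (bounded by
[1, S]; the small-sample form `Σn(n−1)/(N(N−1))` is a config switch and
undefined for single-read sites); rarefaction uses the closed-form
hypergeometric expectation evaluated with log-gamma; subsampling is a
single seeded multivariate-hypergeometric draw per site at the smallest
per-site total by default.  Occupancy classes: cosmopolitan at ≥ 10 of 12
sites (parameterized), locally restricted at exactly 1 site, intermediate
otherwise — note "locally restricted" in the occupancy sense is a
different statistic from the read-count singleton SSO_abs; both are
computed and named separately.

## Community comparison

Bray–Curtis dissimilarities feed three views: NMDS (non-metric SMACOF
minimizing Kruskal stress-1, best of 20 seeded random starts, coordinates
centered; rotation/reflection are indeterminate), Ward hierarchical
clustering in the Ward.D2 convention (variance-minimizing update applied
to the dissimilarities as Euclidean distances; merge heights satisfy
h² = 2·ΔESS and are non-decreasing), and a Fruchterman–Reingold layout of
the bipartite site–OTU presence graph (seeded; sites sharing many OTUs
end near each other through their shared OTU nodes).  Shared-OTU
percentage defaults to the Jaccard denominator (intersection/union) with
an intersection/min-richness alternative; neither is treated as exactly
reproducing any published sharing figure, whose denominator is not
pinned down.

## Validation strategy and scales

Every stage is tested against an independent oracle: translation against
a hand-written codon table; homopolymer runs and column-wise identities
against brute force (1,000 fuzz cases each); agglomerative clustering
against a list-based re-implementation and against scipy; Ward against
direct ESS minimization on embeddable points; rarefaction against 10⁴
Monte-Carlo draws (3 SE); subsampled richness against the rarefaction
expectation over 10³ seeds; the regression against a closed-form fit.
Ground-truth recovery uses a clean run (6 sites × 100 reads, 30 OTUs:
100% survival and exact recovery of the sampled OTUs) and three
error-bearing replicates (75 reads/site, i.e. ~15 reads/OTU at 0.5%/base
substitutions: mean recovery within ±10%; single replicates fluctuate by
a few spurious singletons from multi-error reads — the protein-OTU
inflation phenomenon the strict QC exists to limit).  With finite
sampling a rare lognormal OTU may legitimately go unsequenced, so exact
recovery is asserted against the OTUs present in the truth table.

What passing these tests does *not* show: performance on real 454 data
(no flowgram noise model, qualities uncoupled from errors), robustness to
frameshift-corrupted reads (no frameshift correction — such reads are
rejected, not repaired), or the absolute OTU counts of any particular
field dataset (clustering-method-dependent).

## Known limitations

* The bundled anchor and family panel are synthetic stand-ins; analyses
  of real reads require a real panel FASTA.
* The chimera screen is a scorer, not a full detector; it assumes parents
  are present and ≥ 2× more abundant.
* No denoising/preclustering stage; error tolerance comes from the
  linkage choice instead.
* Strain-pair simulation attenuates the regression slope slightly at high
  divergence (homoplasy); mapped thresholds are unaffected within ±1
  point under default ranges.
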