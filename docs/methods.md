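# Methods

This note records the models implemented, the defaults and why, what the
simulator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Barcode space and error correction

The prototype bead architecture is four split-pool rounds of 96 six-bp
sub-barcodes followed by a 12-nt UMI (read-1 minimum 36 bases). Whitelists
are represented implicitly as per-round sets: membership and correction for
a product space never require the 96⁴ ≈ 8.5 × 10⁷ strings, and for a full
product the whole-barcode condition "Hamming distance ≤ 1" is exactly "all
segments exact except at most one at distance 1" — the per-segment matcher
is therefore not an approximation, and the test suite asserts its
equivalence to a brute-force scan on a materialized 10⁴-barcode space,
including ambiguous neighborhoods.

Matching tolerance is capped at 1 mismatch; ambiguous Hamming-1 matches
(possible only when user-supplied rounds are closer than distance 3) are
discarded rather than arbitrarily resolved. `N` in a barcode mismatches
every base, so a single `N` behaves as one correctable error; an `N` in the
UMI discards the read (`bad_umi`), since a wildcarded UMI would alias
molecules. Linkers between segments are supported (matched exactly) but the
default layout has none.

The real 96-sequence plates are proprietary, so `generate_subbarcode_sets`
builds per-round codes with minimum pairwise Hamming distance 3 — the
smallest spacing that makes single-error correction unambiguous within a
round. A randomized maximal greedy packing over all 4⁶ hexamers yields
88–96 codewords per shuffle; bounded restarts (vectorized, deterministic
under the seed) reach 96, and an explicit error is raised if the bound is
exhausted. A purely deterministic construction was rejected: the best
linear code at these parameters ([6,3,3] over GF(4)) holds only 64 words.

## Read processing

Reads are streamed in O(1) memory from paired FASTQ (gzip-transparent,
via pysam). Kept reads are written as an intermediate FASTQ of read-2
records whose header comment carries `CB:Z:<barcode> UR:Z:<umi>` (SAM-tag
style), plus an optional TSV sidecar; base qualities are ignored for
matching, which is a pure Hamming criterion. Accounting is exact:
`total_reads = exact + corrected + ambiguous + unmatched + too_short +
bad_umi`, and reads with a linker mismatch fold into `unmatched`.

## Quantification

The mapping stage of a production run is an external pseudo-aligner. The
built-in `SubstringIndex` exists so the full pipeline runs on synthetic
data: a read maps to a feature iff the read or its reverse complement is an
exact substring of that feature's transcripts and of no other feature's
(k-mer-seeded, k = 31 by default); multi-feature hits are discarded.
`import_assignments` adapts any external per-read gene table into the same
counting path.

UMI counts are distinct UMIs per (barcode, feature). A UMI observed on
several features within one barcode is credited to the feature with most
supporting reads; ties drop the UMI. No fuzzy (Hamming-1) UMI merging is
performed — the choice keeps counting order-invariant and exactly
conservative, at the cost of slightly inflated counts under UMI sequencing
errors. Matrices are barcodes × typed features (gene / CRISPR / antibody in
one matrix, splittable on demand) and round-trip exactly through
MatrixMarket + barcodes.tsv + features.tsv with a manifest documenting
orientation.

## Downsampling and normalization

UMI downsampling is uniform without replacement across a cell's UMI mass
(multivariate hypergeometric), so a cell above the target lands exactly on
it; read downsampling is binomial thinning of read multiplicities before
UMI collapse. Both are seeded. Log-normalization is
ln(1 + 10⁴ · x / total) per cell; pseudobulk TPM is counts/total × 10⁶ with
no gene-length term, because UMIs are molecule end-counts and a length term
would distort them.

## Cell calling

The barcode-rank knee is the steepest negative slope of log(total) against
log(rank) after a 5-rank moving average, searched between rank bounds
(default 10 to n−10); the returned threshold is the smoothed curve value at
the knee, which at an abrupt plateau transition sits strictly between the
plateaus. If no slope passes −0.3 (e.g. a flat curve) the caller falls back
to the 99th-percentile total with a warning.

The ambient profile is the summed counts of all barcodes at or below the
lower threshold, normalized (optional pseudocount, default 0 — a gene
unseen in the ambient pool has probability 0, and a candidate carrying it
gets the minimum attainable p-value and a flag). The test statistic is the
full multinomial log-pmf at the barcode's own total; for each distinct
total, one ensemble of R multinomial draws is simulated and shared by every
barcode at that total — identical in distribution to independent ensembles
and the dominant runtime saving. p = (#{LL ≤ obs} + 1)/(R + 1) is the
standard add-one Monte-Carlo estimator, bounded in [1/(R+1), 1]; note that
R bounds attainable significance, so calling at α = 0.001 after BH requires
R ≳ 2,000 (the default). BH adjustment is delegated to statsmodels.
`force_n` mode bypasses the test: top n barcodes by total, ties broken
lexicographically for determinism.

## Barnyard analysis

Purity, contamination (1 − purity, summarized per species as median, mean
and max, since the headline "below 3%" statistic could be any of them), and
doublet inference are computed over called cells only. The inferred total
doublet rate divides the observed mixed fraction by the cross-species
observability 2p(1−p); higher-order multiplets are ignored, which is
adequate at the λ ≈ 0.1 loading regimes modeled. The species-label
threshold (default purity > 0.85) is strict at the boundary and reported in
the output. One known bias: a cross-species doublet dominated by one large
cell can exceed the purity threshold and be species-labeled, deflating the
inferred rate slightly; the simulator's recovery tests bound this effect
within binomial error at the modeled size distribution.

The Poisson expectation (1 − e^−λ − λe^−λ)/(1 − e^−λ) evaluates to 0.0492
at λ = 0.1 (verified against direct Poisson-pmf evaluation).

## Guide assignment

With r = top guide count / Σ(other guide counts): zero total → none;
r ≥ 10 (including Σ(others) = 0, r = +∞) → single; r < 10 → multiple. The
"single vs multiple" boundary is read as the base-10 log of the dominance
ratio falling below 1 — the only reading under which the three labels
partition all cells, which the exhaustive 3-guide oracle test asserts over
every count vector with entries ≤ 20. The ratio is configurable.

## Hashtag processing

Tag counting matches the read-2 prefix (default length 15, the length of
the published TotalSeqA hash sequences; configurable for 16-bp trims)
against the tag whitelist at Hamming ≤ 1, discarding ambiguous hits, then
UMI-deduplicates. The whitelist's pairwise distances are checked against
2 × tolerance and a warning is raised when correction could be ambiguous.

Demultiplexing CLR-transforms counts per hash across cells (pseudocount 1).
The per-hash positivity threshold is the empirical `positive_quantile`
(default 0.99) of that hash's *background* cells. Background is defined as
cells outside the hash's positive cluster (deterministic 1-D two-means
split, initialized at the 10th/90th percentiles) whose best hash is some
other hash. Excluding the positive cluster matters: genuine inter-hash
doublets otherwise sit inside the background and drag its upper quantile
above the singlet signal level, collapsing the calls; with the exclusion,
injected 5% doublets are recovered within binomial error. Cells above 0, 1,
or ≥ 2 thresholds are negative, singlet, or doublet.

## Capacity calculator

Droplet count D = aqueous volume / droplet volume; per-cell collision
combines Poisson co-encapsulation, 1 − (1 − 1/D)^(n−1), with birthday-style
barcode reuse over B = 96⁴, 1 − (1 − 1/B)^(n−1), as independent events. The
droplet volume is the single free parameter, defaulted to 619 pL (a ~106-µm
droplet — an 80-µm bead plus aqueous shell), the value at which 35 µL at a
6% budget holds ≈ 3,500 cells. Under the same defaults the 2-mL and 10-mL
tubes hold 192,594 and 839,857 cells: barcode reuse consumes a growing
share of the collision budget at high n, so capacity density falls ~16%
from 35 µL to 10 mL (and is volume-independent to < 10% once the reuse term
is removed — both properties are asserted in the tests). Inversion is exact
monotone bisection, with the round-trip property
rate(n) ≤ target < rate(n+1).

## Simulator

`simulate_experiment` draws, from one seed: droplet occupancies
(zero-truncated Poisson(λ), or an explicit doublet rate), per-cell species
(independent at the configured proportions — giving the 2p(1−p)
cross-species observability the inference assumes), per-species expression
as Dirichlet-multinomial around a species base profile (concentration 5,
enough cell-to-cell variation to be realistic while keeping species
signatures distinct), cell totals log-normal (median 300 UMIs, σ = 0.35),
ambient contamination as a binomial fraction (default 2%) of each cell's
UMIs drawn from the pooled species-mixture profile, a sea of ambient-only
barcodes (default 2,000 at ~15 UMIs — an order of magnitude below cells, as
in a real rank plot), one dominant guide per infected cell (80% infected,
~20 guide UMIs), and hash counts (~50 UMIs on the assigned hash, 2%
relative background on the rest). Transcripts are unique random 200-mers
verified to share no read-length k-mer across features (forward or reverse
complement), so the toy aligner is exact on simulated reads. Read 1 is
barcode + UMI with per-base substitution errors; UMIs are drawn
collision-free within a barcode so that, at zero error, the pipeline's
matrix equals the truth table *exactly* — an identity the suite asserts.

Default problem sizes (500 cells, 100 genes/species, 2,000 ambient
barcodes, 1 read/UMI, R = 2,000 calling iterations) keep a full end-to-end
run around half a minute while leaving every statistic testable against
binomial error bars.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: realistic transcript length/positional coverage,
PCR family-size structure beyond a reads-per-UMI count, quality scores,
indels or barcode-synthesis truncations, chimeric reads, per-cell ambient
variation, and expression correlation structure between genes. Results on
real FASTQ additionally depend on the external aligner fed through
`import_assignments`.

## Degenerate inputs and tie-breaking

Zero-total cells: QC mito fraction 0 with a flag; log-normalization leaves
them zero; species label "unclassified". Constant pseudobulk vectors raise
(correlation undefined). Flat rank curves take the quantile fallback.
`force_n` ties break lexicographically. Monte-Carlo LL comparisons use ≤ on
bit-identical arithmetic paths for observed and simulated statistics, so
ties resolve consistently.
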