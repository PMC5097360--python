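# Methods

## Scope and data model

The package analyses single-end ChIP-nexus / ChIP-exo data after alignment.
Read mapping itself is out of scope: the tool consumes SAM/BAM from an
external aligner and trusts that multi-mappers were already discarded (an
optional MAPQ floor is available). Every statistic is computed from *hits* —
the 5′-end position and strand of a mapped read — stored per chromosome as
position → count tables (`T_f`, `T_r`). Coordinates are 1-based and fully
closed internally; BED output converts to 0-based half-open at the writer.

The 5′ end of a forward alignment is its leftmost aligned reference base, of
a reverse alignment its rightmost. Soft-clipped bases are not extrapolated
through: the exonuclease-stop evidence is the aligned terminus.

## Preprocessing

Raw reads begin with a random barcode (default 5 nt) followed by a fixed
barcode. Both are protocol constants of the library kit, not of the method,
so the fixed-barcode sequence must be supplied explicitly. The random
barcode is moved into the read ID as a `TL:<barcode>` token (space
separated) so aligners carry it into the BAM query name; reads whose fixed
barcode differs from the expected sequence by more than one nucleotide are
discarded. An `N` inside the fixed barcode counts as a mismatch
(conservative); an `N` inside the random barcode is carried verbatim.

Adapter clipping removes, from the leftmost qualifying position, any exact
match of an adapter prefix extending through the read's 3′ end (minimum
overlap 3 nt, configurable). Reads that begin with adapter, or that fall
below the minimum length after clipping, are discarded. Mismatch-tolerant
adapter alignment and quality trimming are deliberate non-goals; the
clipper is exact, deterministic and verified against a brute-force
every-overlap oracle.

## Duplicate removal and duplication levels

PCR duplicates are reads with identical 5′ position, strand **and** random
barcode (IMIB); exactly one read per (chrom, pos, strand, barcode) is kept.
Which copy is kept is irrelevant for every downstream statistic; the BAM
writer keeps the first in file order so output bytes are reproducible.
Strands are never merged when grouping. Reads without a barcode abort the
run by default (or are kept as distinct molecules with a warning).

Duplication levels are read-weighted: an IM read contributes at the size of
its position group, an IMIB read at the size of its barcode subgroup, and
each retained IMUB read at the number of distinct barcodes at its position
(the post-dedup 5′-end depth). Overall levels are the summed proportions at
levels ≥ 2. The plot bins levels 1–9 individually with an open-ended ≥10
bin (configurable ceiling) and writes its data table alongside as TSV.
Whether position-weighted rather than read-weighted IMUB levels are ever
preferable is an open presentation question; the read-weighted definition is
the one consistent with using mean per-position IMUB depth as an enrichment
QC. Barcode-error correction (merging barcodes within Hamming distance 1)
and optical-duplicate detection are not performed.

## Protected-region width

The qfrag-length distribution `Q_t(δ)` counts ordered forward/reverse hit
pairs at each distance δ = 2..Δ, respecting multiplicities (reads, not
unique positions). Δ defaults to 110. The pseudo-control swaps every hit's
strand and shifts it one read length toward its new 5′ direction; hits
shifted outside the chromosome are dropped and counted, not reflected
(negligible at genome scale). The transform is an involution, and maps a
data pair at distance δ to a control pair at distance `2(rl−1) − δ` — the
reflection identity that makes the phantom distance `rl − 1` its fixed
point. Artifact patterns are therefore invariant under the transform and
cancel exactly in `D = Q_t − Q_p`, while genuine sub-read-length footprints
are destroyed in the control and survive in `D`.

The width estimate is the smallest δ maximising `D` (smallest-δ
tie-breaking: deterministic and biased toward the sharper footprint). When
`D` is identically zero the estimate degenerates to δ = 2 and is flagged.
`rl` defaults to the modal mapped read length and can be overridden.
Chromosome filtering before the signature is optional and off by default;
the signature is robust to it because artifact-rich chromosomes cancel in
the difference anyway.

## Peak calling

qfrags are formed from hit pairs with `q_min ≤ δ ≤ q_max`, where
`q_min = width − x`, `q_max = width + x` and x defaults to 5. A qfrag
covers the **closed** interval between the two 5′ ends, making the idealized
single-site depth profile symmetric about the cross-link position. Depth is
accumulated with a difference array, O(hits × window), and verified against
all-pairs interval stacking.

Summits are free-standing local maxima: covered positions with no higher
depth within a radius of `q_min`. A run of adjacent equal-depth qualifying
positions (a plateau — the generic shape at a clean site, where the depth is
constant between the innermost forward and reverse cluster edges) yields one
summit: the depth-weighted centroid of the profile over the run extended by
`q_min` on each side, clamped into the run. The centroid, rather than a
plateau endpoint or midpoint, is used because a single stray hit pairing
with one of the site's 5′ clusters erodes one plateau edge and would shift
an endpoint/midpoint summit by several bp, while the centroid stays anchored
at the underlying binding position; clamping keeps the free-standing
property verbatim (any position of the maximal run satisfies it).

Every summit in a covered region is tested. `k` counts 5′ ends of both
strands, with multiplicity, in the closed window `[s − q_max, s + q_max]`;
the null expectation is `λ = 2·q_max·(|T_f| + |T_r|)/l`, computed per
chromosome (a genome-pooled λ would let small, dense chromosomes inflate
sparse ones). The window spans `2·q_max + 1` positions while λ uses the
factor `2·q_max`; the formulas are kept exactly as printed — the ~2%
conservative offset is irrelevant at any realistic λ. p-values are the
Poisson upper tail `P(X ≥ k)` (scipy survival function; `p(0) = 1`),
BH-corrected across all tested summits genome-wide (statsmodels step-up,
cross-checked against a direct step-up oracle). Ranking is by p-value, ties
by larger k then coordinate; the list is truncated to `top_n` (default
200 000) after an optional q-value cutoff. Writers emit summit BED
(score = −log10 q), narrowPeak with the summit extended ±2 bp, and a full
TSV. ChIP-exo mode runs the identical caller with barcode deduplication
skipped upstream.

## Synthetic data

The simulator generates what the method assumes, with all randomness from a
single seed:

* **Sites.** Placed proportionally to chromosome length on an even grid
  with random offsets (minimum gap 200 bp, so neighbouring peaks never
  interact). Each of the `molecules_per_site` molecules picks a strand
  (fair coin) and a 5′ end at `s − ⌈w/2⌉` (forward) or `s + ⌊w/2⌋`
  (reverse) plus rounded Gaussian jitter, making the forward–reverse 5′
  distance exactly the planted width w.
* **Barcodes and PCR.** Uniform random barcodes of 5 nt; each molecule gets
  `1 + Poisson(pcr_duplication_mean)` copies. Barcode collisions are
  possible by design (4⁵ = 1024 barcodes) and their expected count is
  computable by a birthday argument — tests bound the residual IMIB level
  accordingly.
* **Background.** Uniform on both strands at `background_rate` hits/bp per
  strand, single copies, fresh barcodes.
* **Phantom loci.** Matched forward/reverse clusters exactly `rl − 1` apart
  with distinct barcodes — the repeat-driven artifact geometry behind the
  phantom peak.

Defaults are the standard study conditions: 1 Mb genome in two chromosomes,
200 sites × 50 molecules, w = 18, jitter SD 1 bp, rl = 42,
`pcr_duplication_mean = 1.0` (overall IM duplication ≈ 50%, within the range
reported for real ChIP-nexus libraries) and `background_rate = 0.01`,
a realistic post-dedup genome-wide density (several million usable reads
over a ~120 Mb genome). `emit_fastq` renders molecules over a seed-derived
random reference (written as 60-column FASTA), appending adapter when the
insert is shorter than the read length; `write_alignments` renders the
post-alignment state directly so dedup and peak calling can be exercised
without an aligner. Not modelled: sequencing errors, indels, base-quality
variation, mappability structure, and fragment-length variability between
molecules. Passing tests therefore demonstrate correctness of the
algorithms under the assumed generative model, not robustness to alignment
artifacts beyond the explicit phantom pattern.

## Numerical and degenerate-input choices

* Empty inputs flow through: empty FASTQ → zero stats, empty BAM → empty
  hit set, all-zero depth → no summits, no tests.
* Poisson tails come from the survival function (log-space stable);
  BH never exceeds 1 and is restored to input order.
* All output writers sort deterministically; identical seeds and inputs
  give byte-identical FASTQ, BAM, TSV and peak files.
* Problem sizes in tests and the acceptance script are the study
  conditions above (~30 000 deduplicated reads per dataset), which keep the
  whole suite in the tens of seconds while leaving every statistical margin
  wide (width recovery is exact, recall ≈ 99%, background significant rate
  ≈ 0.1%).

## Known limitations

* No input/control-library normalisation: the null is uniform coverage, as
  in the method itself; locally biased backgrounds will inflate summit
  counts.
* The fixed-barcode sequence and random-barcode length of any real library
  must come from the wet-lab protocol; the preprocessor refuses to guess.
* Dense real genomes make the per-chromosome depth arrays the memory
  bottleneck (8 bytes/bp); fine up to mammalian chromosomes, but the
  implementation favours clarity over streaming.
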