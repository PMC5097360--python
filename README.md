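# qnexus

Preprocessing, duplicate removal, binding-footprint estimation and peak
calling for **ChIP-nexus** and **ChIP-exo** experiments.

ChIP-nexus reads start with a random barcode (a UMI) followed by a fixed
barcode, and their 5′ ends mark the positions where λ-exonuclease digestion
stopped at a cross-linked protein. This yields base-pair-resolution binding
footprints — but also two analysis problems that generic ChIP-seq tools do
not handle:

1. independent molecules pile up at the same exonuclease-stop nucleotide, so
   PCR duplicates can only be recognised through the random barcode, and
2. fragment-size estimators are biased by the "phantom peak" at one read
   length, caused by repeat-driven paired 5′-end pile-ups.

## Method

All computation operates on *hits* — 5′-end positions of uniquely mapped
reads, `h = (pos, strand)` with `strand ∈ {f, r}`, collected per chromosome
into multisets `T_f` and `T_r`.

**Duplicate removal and duplication statistics.** Reads mapping to the same
(position, strand) are *identically mapped* (IM); those additionally sharing
the random barcode (IMIB) are PCR duplicates and all but one are discarded;
the retained reads have unique barcodes (IMUB). The package reports, per
class, the proportion of reads at each duplication level and the overall
duplication level (share of reads with 5′-end depth > 1).

**Protected-region width.** A *qfrag* is the interval between an ordered pair
of hits, forward upstream of reverse; its length distribution

    Q_t(δ) = |{(h_i, h_j) : h_i ∈ T_f, h_j ∈ T_r, h_j − h_i = δ}|,  δ = 2..Δ

peaks at the width of the exonuclease-protected region. To cancel the
phantom peak, a *pseudo-control* is built by swapping every hit's strand and
shifting it one read length `rl` toward its new 5′ end
(`pos → pos + rl − 1` for new strand r, `pos → pos − rl + 1` for f). This
transform maps a pair at distance δ to a pair at distance `2(rl−1) − δ`, so
artifact pairs at the fixed point `δ = rl − 1` survive unchanged and cancel
in the signature `D(δ) = Q_t(δ) − Q_p(δ)`; the width estimate is
`ℓ = argmax_δ D(δ)`.

**Peak calling.** Hit pairs with `q_min ≤ δ ≤ q_max` (default `ℓ ∓ 5`) form
qfrags; the qfrag depth profile is scanned for free-standing local maxima
(*summits*: no higher depth within a radius of `q_min`). Each summit is
scored by `k`, the 5′-end count within `±q_max`, and tested against a
uniform Poisson null with `λ = 2·q_max·(|T_f|+|T_r|)/l` per chromosome;
p-values `P(X ≥ k)` are Benjamini–Hochberg corrected across all tested
summits, ranked, and written as BED / narrowPeak / TSV. For ChIP-exo the
same caller runs with barcode deduplication skipped.

A ground-truthed simulator (`qnexus.synthetic_data`) generates barcoded
reads with planted binding sites, PCR duplication, uniform background and
phantom artifacts, so the whole pipeline is testable without external data.

## Worked example

```python
from qnexus import (SimConfig, simulate_hits, deduplicate,
                    estimate_protected_width, call_peaks, PeakCallParams)

cfg = SimConfig(seed=1)                  # 200 sites, width 18, 50 molecules/site
hits, truth = simulate_hits(cfg)         # pre-dedup barcoded hit set
dedup, n_removed = deduplicate(hits)     # one read per (pos, strand, barcode)
print(hits.total, "->", dedup.total, "reads;", n_removed, "PCR duplicates removed")

sig = estimate_protected_width(dedup)
print("protected-region width:", sig.estimate)

result = call_peaks(dedup, PeakCallParams(width=sig.estimate))
print(len([s for s in result.summits if s.q_value < 0.01]), "significant summits")
```

prints

```
40186 -> 30017 reads; 10169 PCR duplicates removed
protected-region width: 18
207 significant summits
```

The width estimate equals the planted footprint width (18 bp), the removed
reads are the simulated PCR copies, and the significant summits recover
199/200 planted sites within ±1 bp (a handful of near-site background
coincidences account for the extras). The same pipeline runs from the shell
via `qnexus preprocess | dedup | characteristics | callpeaks | simulate`.

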