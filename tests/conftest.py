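"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive each quantity from its definition
(all-pairs enumeration, interval stacking, step-up sorting) without touching
the implementation's data paths, so agreement is meaningful.
"""

from collections import Counter

import numpy as np
import pytest

from qnexus import HitSet


def make_hitset(chrom_lengths, fwd=(), rev=(), read_length=None, barcoded=False):
    """Build a HitSet from (chrom, pos[, count]) tuples per strand."""
    hs = HitSet(chrom_lengths, read_length=read_length, track_barcodes=barcoded)
    for strand, entries in (("f", fwd), ("r", rev)):
        for entry in entries:
            chrom, pos, *rest = entry
            count = rest[0] if rest else 1
            barcode = rest[1] if len(rest) > 1 else None
            hs.add(chrom, pos, strand, count=count, barcode=barcode)
    return hs


def random_hitset(rng, n_hits=200, chrom_len=2000, lo=None, hi=None, read_length=None):
    """A random single-chromosome HitSet with multiplicities."""
    lo = 1 if lo is None else lo
    hi = chrom_len if hi is None else hi
    hs = HitSet({"c": chrom_len}, read_length=read_length)
    for _ in range(n_hits):
        pos = int(rng.integers(lo, hi + 1))
        strand = "f" if rng.random() < 0.5 else "r"
        hs.add("c", pos, strand, count=int(rng.integers(1, 4)))
    return hs


# -- oracles ---------------------------------------------------------------


def oracle_qfrag_lengths(hits, delta_max):
    """O(n^2) all-pairs qfrag-length counts."""
    counts = Counter()
    for chrom in hits.chroms:
        for pf, cf in hits.counts(chrom, "f").items():
            for pr, cr in hits.counts(chrom, "r").items():
                delta = pr - pf
                if 2 <= delta <= delta_max:
                    counts[delta] += cf * cr
    return np.array([counts.get(d, 0) for d in range(2, delta_max + 1)], dtype=np.int64)


def oracle_qfrag_coverage(hits, chrom, q_min, q_max):
    """All-pairs closed-interval stacking for one chromosome."""
    l = hits.chrom_lengths[chrom]
    depth = np.zeros(l + 1, dtype=np.int64)
    for pf, cf in hits.counts(chrom, "f").items():
        for pr, cr in hits.counts(chrom, "r").items():
            if q_min <= pr - pf <= q_max and pr <= l:
                depth[pf : pr + 1] += cf * cr
    return depth


def oracle_free_standing(depth, q_min):
    """All positions satisfying the free-standing definition verbatim."""
    positions = []
    l = len(depth) - 1
    for s in range(1, l + 1):
        if depth[s] < 1:
            continue
        lo, hi = max(1, s - q_min), min(l, s + q_min)
        if all(depth[s] >= depth[t] for t in range(lo, hi + 1)):
            positions.append(s)
    return positions


def oracle_bh(p_values):
    """Step-up Benjamini-Hochberg by direct definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def oracle_clip(seq, adapter, min_overlap):
    """Try every suffix/prefix overlap; leftmost qualifying match wins."""
    for i in range(len(seq)):
        overlap = min(len(seq) - i, len(adapter))
        if overlap >= min_overlap and seq[i : i + overlap] == adapter[:overlap]:
            return seq[:i]
    return seq


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
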