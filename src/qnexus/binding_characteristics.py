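"""Protected-region width estimation from the qfrag-length distribution.

A *qfrag* is the genomic interval between an ordered pair of hits
``(h_i, h_j)`` with ``h_i`` on the forward and ``h_j`` on the reverse
strand; its length is ``delta = h_j.pos - h_i.pos``.  Around a genuine
binding site the lambda exonuclease stops on either side of the cross-linked
protein, so forward and reverse 5'-end clusters sit one protected-region
width apart and the qfrag-length distribution

    Q_t(delta) = |{(h_i, h_j) : h_i in T_f, h_j in T_r, h_j - h_i = delta}|

peaks at that width.  Repeat-driven mapping artifacts, however, produce
paired pile-ups exactly one read length apart (the "phantom peak" familiar
from cross-correlation analysis), which can dominate Q_t.

The pseudo-control removes that bias: swap each hit's strand and shift it
one read length toward its new 5' direction,

    pos -> pos + rl - 1  (new strand r),    pos -> pos - rl + 1  (new strand f).

This transform maps a data pair at distance delta to a control pair at
distance 2*(rl-1) - delta, so the phantom distance rl-1 is its fixed point:
artifact signal survives unchanged in the control while genuine sub-read-
length footprints are destroyed.  The difference D = Q_t - Q_p is therefore
an unbiased signature, and the protected-region width is estimated as

    width = argmax_delta  Q_t(delta) - Q_p(delta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .mapped_reads import FORWARD, REVERSE, HitSet

logger = logging.getLogger("qnexus")

DEFAULT_DELTA_MAX = 110


@dataclass
class QfragLengthDistribution:
    """Counts Q(delta) for delta = 2..delta_max."""

    delta_max: int
    counts: np.ndarray  # counts[i] is Q(2 + i), length delta_max - 1
    source: str  # "data" or "pseudo_control"

    def __getitem__(self, delta: int) -> int:
        if not 2 <= delta <= self.delta_max:
            raise IndexError(f"delta {delta} outside [2, {self.delta_max}]")
        return int(self.counts[delta - 2])

    @property
    def deltas(self) -> np.ndarray:
        return np.arange(2, self.delta_max + 1)

    @property
    def argmax(self) -> int:
        """Smallest delta attaining the maximal count."""
        return int(self.deltas[int(np.argmax(self.counts))])


@dataclass
class WidthSignature:
    """The signature D = Q_t - Q_p and the width estimate derived from it."""

    q_t: QfragLengthDistribution
    q_p: QfragLengthDistribution
    read_length: int
    estimate: int
    degenerate: bool = False

    @property
    def difference(self) -> np.ndarray:
        return self.q_t.counts.astype(np.int64) - self.q_p.counts.astype(np.int64)

    def to_tsv(self, path: Union[str, Path]) -> None:
        d = self.difference
        with open(path, "w") as fh:
            fh.write(f"#read_length\t{self.read_length}\n")
            fh.write(f"#estimate\t{self.estimate}\n")
            fh.write(f"#degenerate\t{int(self.degenerate)}\n")
            fh.write("delta\tq_t\tq_p\td\n")
            for i, delta in enumerate(self.q_t.deltas):
                fh.write(f"{delta}\t{self.q_t.counts[i]}\t{self.q_p.counts[i]}\t{d[i]}\n")


def qfrag_length_distribution(
    hits: HitSet,
    delta_max: int = DEFAULT_DELTA_MAX,
    source: str = "data",
) -> QfragLengthDistribution:
    """Count qfrags of each length delta in [2, delta_max], genome-wide.

    Pair counting respects read multiplicities: a forward position with
    count f and a reverse position with count r at distance delta contribute
    f*r qfrags to Q(delta).
    """
    if delta_max < 2:
        raise ValueError("delta_max must be >= 2")
    counts = np.zeros(delta_max - 1, dtype=np.int64)
    for chrom in hits.chroms:
        fwd = hits.counts(chrom, FORWARD)
        rev = hits.counts(chrom, REVERSE)
        if not fwd or not rev:
            continue
        rev_get = rev.get
        for pos, f_count in fwd.items():
            for i in range(delta_max - 1):
                r_count = rev_get(pos + 2 + i)
                if r_count:
                    counts[i] += f_count * r_count
    return QfragLengthDistribution(delta_max=delta_max, counts=counts, source=source)


def pseudo_control(hits: HitSet, read_length: Optional[int] = None) -> HitSet:
    """Strand-swap and read-length-shift transform of a hit set.

    Every hit's strand is inverted, then the position is shifted one read
    length toward the new 5' direction: new strand r -> pos + rl - 1, new
    strand f -> pos - rl + 1.  Hits whose transformed position leaves the
    chromosome are dropped (counted and logged).  Applied twice the
    transform is the identity (absent boundary clamping).
    """
    rl = read_length if read_length is not None else hits.read_length
    if rl is None:
        raise ValueError("read length required (not recorded on the HitSet)")
    if rl < 2:
        raise ValueError("read length must be >= 2")
    out = HitSet(hits.chrom_lengths, read_length=rl, track_barcodes=False)
    n_clamped = 0
    for chrom in hits.chroms:
        l = hits.chrom_lengths[chrom]
        for pos, cnt in hits.counts(chrom, FORWARD).items():
            new_pos = pos + rl - 1  # f -> r, shift toward the new 5' end
            if 1 <= new_pos <= l:
                out.add(chrom, new_pos, REVERSE, count=cnt)
            else:
                n_clamped += cnt
        for pos, cnt in hits.counts(chrom, REVERSE).items():
            new_pos = pos - rl + 1  # r -> f
            if 1 <= new_pos <= l:
                out.add(chrom, new_pos, FORWARD, count=cnt)
            else:
                n_clamped += cnt
    if n_clamped:
        logger.info("pseudo_control: dropped %d hits shifted outside the chromosome", n_clamped)
    return out


def estimate_protected_width(
    hits: HitSet,
    delta_max: int = DEFAULT_DELTA_MAX,
    read_length: Optional[int] = None,
) -> WidthSignature:
    """Estimate the protected-region width from the qfrag signature.

    Computes Q_t on the data, Q_p on its pseudo-control, and returns the
    smallest delta maximising D = Q_t - Q_p.  When D is identically zero the
    estimate degenerates to delta = 2 and is flagged.
    """
    rl = read_length if read_length is not None else hits.read_length
    if rl is None:
        raise ValueError("read length required (not recorded on the HitSet)")
    if all(
        not hits.counts(c, FORWARD) or not hits.counts(c, REVERSE) for c in hits.chroms
    ):
        raise ValueError("no qfrags: no chromosome has hits on both strands")
    q_t = qfrag_length_distribution(hits, delta_max=delta_max, source="data")
    q_p = qfrag_length_distribution(
        pseudo_control(hits, rl), delta_max=delta_max, source="pseudo_control"
    )
    diff = q_t.counts - q_p.counts
    best = int(np.argmax(diff))
    estimate = int(q_t.deltas[best])
    degenerate = bool(np.all(diff == diff[best]) and diff[best] == 0)
    if degenerate:
        logger.warning("estimate_protected_width: signature identically zero (degenerate)")
    return WidthSignature(
        q_t=q_t, q_p=q_p, read_length=rl, estimate=estimate, degenerate=degenerate
    )
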