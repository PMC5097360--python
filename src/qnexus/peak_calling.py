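"""qfrag-coverage peak calling with Poisson significance testing.

Binding positions are flanked by 5'-end clusters on the forward and reverse
strand, one protected-region width apart.  The caller exploits this
geometry directly: every forward/reverse hit pair at a distance within
``[q_min, q_max] = [width - x, width + x]`` forms a qfrag covering the
closed interval between the two 5' ends, and the qfrag depth profile
selectively emphasises regions flanked by such paired clusters.  Candidate
binding positions (*summits*) are free-standing local maxima of the qfrag
depth: no position within a radius of ``q_min`` has higher depth.

Each summit is scored by ``k``, the number of 5' ends (both strands, with
multiplicity) within ``[s - q_max, s + q_max]``, and tested against a
uniform-background Poisson null with per-chromosome expectation

    lambda = 2 * q_max * (|T_f| + |T_r|) / l.

P-values ``P(X >= k)`` are Benjamini-Hochberg corrected across all tested
summits genome-wide ("all regions covered by at least one qfrag are
tested"); the final list is sorted by p-value and truncated to ``top_n``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .binding_characteristics import DEFAULT_DELTA_MAX, estimate_protected_width
from .mapped_reads import FORWARD, REVERSE, HitSet

logger = logging.getLogger("qnexus")


@dataclass
class PeakCallParams:
    """Parameters of the qfrag peak caller.

    ``width`` is the protected-region width (estimated from the data when
    None); ``deviation`` is the tolerated deviation x around it, giving the
    qfrag window ``[width - x, width + x]``.
    """

    width: Optional[int] = None
    deviation: int = 5
    top_n: int = 200_000
    summit_extension: int = 2
    q_value_cutoff: Optional[float] = None

    @property
    def q_min(self) -> int:
        if self.width is None:
            raise ValueError("width not set")
        return self.width - self.deviation

    @property
    def q_max(self) -> int:
        if self.width is None:
            raise ValueError("width not set")
        return self.width + self.deviation

    def validate(self) -> None:
        if self.width is None:
            raise ValueError("width not set")
        if not 2 <= self.q_min <= self.q_max:
            raise ValueError(
                f"need 2 <= q_min <= q_max, got q_min={self.q_min}, q_max={self.q_max}"
            )


@dataclass
class Summit:
    """A candidate binding position with its test statistics."""

    chrom: str
    pos: int  # 1-based
    qfrag_depth: int
    k: int
    lam: float
    p_value: float
    q_value: float = math.nan


def qfrag_coverage(hits: HitSet, q_min: int, q_max: int) -> Dict[str, np.ndarray]:
    """Per-chromosome qfrag depth profiles.

    Every forward position p (count f) and reverse position p + delta
    (count r) with delta in [q_min, q_max] adds f*r to the depth of each
    position of the closed interval [p, p + delta].  Returned arrays are
    indexed by 1-based position (index 0 unused); accumulation uses a
    difference array, O(hits * window).
    """
    if q_min < 2 or q_min > q_max:
        raise ValueError("need 2 <= q_min <= q_max")
    profiles: Dict[str, np.ndarray] = {}
    for chrom in hits.chroms:
        l = hits.chrom_lengths[chrom]
        diff = np.zeros(l + 2, dtype=np.int64)
        fwd = hits.counts(chrom, FORWARD)
        rev = hits.counts(chrom, REVERSE)
        if fwd and rev:
            rev_get = rev.get
            for pos, f_count in fwd.items():
                for delta in range(q_min, q_max + 1):
                    end = pos + delta
                    if end > l:
                        break
                    r_count = rev_get(end)
                    if r_count:
                        w = f_count * r_count
                        diff[pos] += w
                        diff[end + 1] -= w
        profiles[chrom] = np.cumsum(diff[:-1])
    return profiles


def find_summits(depth: np.ndarray, q_min: int) -> List[int]:
    """Free-standing local maxima of a qfrag depth profile.

    A summit is a covered position (depth >= 1) with no higher depth within
    a radius of ``q_min``.  A run of adjacent qualifying positions of equal
    depth (a plateau) yields one summit: the depth-weighted centroid of the
    profile over the run extended by ``q_min`` on each side, clamped into
    the run.  On a symmetric peak this is the plateau centre; when stray
    pairings erode one plateau edge the centroid stays anchored at the
    underlying binding position, unlike the raw plateau midpoint.  Clamping
    keeps every summit inside the maximal-depth run, so the free-standing
    property holds verbatim.  ``depth`` is indexed by 1-based position,
    index 0 unused.
    """
    if len(depth) < 2:
        return []
    body = depth[1:]
    window_max = maximum_filter1d(body, size=2 * q_min + 1, mode="constant", cval=0)
    qualifying = np.flatnonzero((body >= 1) & (body == window_max)) + 1
    if qualifying.size == 0:
        return []
    summits: List[int] = []
    run_start = 0
    for i in range(1, qualifying.size + 1):
        end_of_run = (
            i == qualifying.size
            or qualifying[i] != qualifying[i - 1] + 1
            or depth[qualifying[i]] != depth[qualifying[run_start]]
        )
        if end_of_run:
            lo, hi = int(qualifying[run_start]), int(qualifying[i - 1])
            w_lo = max(1, lo - q_min)
            w_hi = min(len(depth) - 1, hi + q_min)
            window = depth[w_lo : w_hi + 1].astype(np.float64)
            centroid = float(np.arange(w_lo, w_hi + 1) @ window) / float(window.sum())
            summit = int(math.floor(centroid + 0.5))
            summits.append(min(max(summit, lo), hi))
            run_start = i
    return summits


def summit_lambda(n_hits: int, chrom_length: int, q_max: int) -> float:
    """Expected 5'-end count in a 2*q_max window under a uniform null."""
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    return 2.0 * q_max * n_hits / chrom_length


def poisson_pvalue(k: int, lam: float) -> float:
    """Upper-tail Poisson probability P(X >= k), computed stably."""
    if k < 0 or lam < 0:
        raise ValueError("k and lambda must be non-negative")
    if k == 0:
        return 1.0
    return float(poisson.sf(k - 1, lam))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PeakCallResult:
    summits: List[Summit]
    params: PeakCallParams
    n_tested: int
    width_estimated: bool = False


def call_peaks(hits: HitSet, params: Optional[PeakCallParams] = None) -> PeakCallResult:
    """Run the full caller: coverage, summits, Poisson test, BH, ranking.

    ``hits`` should be the deduplicated (IMUB) hit set for ChIP-nexus, or
    the raw hit set for ChIP-exo (where barcode deduplication is skipped).
    When ``params.width`` is None the protected-region width is estimated
    internally from the qfrag signature.
    """
    params = params or PeakCallParams()
    width_estimated = False
    if params.width is None:
        sig = estimate_protected_width(hits, delta_max=DEFAULT_DELTA_MAX)
        params.width = sig.estimate
        width_estimated = True
        logger.info("call_peaks: estimated protected-region width %d", params.width)
    params.validate()

    profiles = qfrag_coverage(hits, params.q_min, params.q_max)
    summits: List[Summit] = []
    for chrom in hits.chroms:
        depth = profiles[chrom]
        positions = find_summits(depth, params.q_min)
        if not positions:
            continue
        l = hits.chrom_lengths[chrom]
        n_hits = hits.strand_total(chrom, FORWARD) + hits.strand_total(chrom, REVERSE)
        lam = summit_lambda(n_hits, l, params.q_max)
        # prefix sums of combined 5'-end counts for O(1) window queries
        ends = np.zeros(l + 1, dtype=np.int64)
        for strand in (FORWARD, REVERSE):
            for pos, cnt in hits.counts(chrom, strand).items():
                ends[pos] += cnt
        cum = np.concatenate(([0], np.cumsum(ends[1:])))  # cum[p] = ends in [1, p]
        for s in positions:
            lo = max(1, s - params.q_max)
            hi = min(l, s + params.q_max)
            k = int(cum[hi] - cum[lo - 1])
            summits.append(
                Summit(
                    chrom=chrom,
                    pos=s,
                    qfrag_depth=int(depth[s]),
                    k=k,
                    lam=lam,
                    p_value=poisson_pvalue(k, lam),
                )
            )
    n_tested = len(summits)
    if summits:
        q_values = bh_adjust([s.p_value for s in summits])
        for s, q in zip(summits, q_values):
            s.q_value = float(q)
    summits.sort(key=lambda s: (s.p_value, -s.k, s.chrom, s.pos))
    if params.q_value_cutoff is not None:
        summits = [s for s in summits if s.q_value <= params.q_value_cutoff]
    summits = summits[: params.top_n]
    logger.info("call_peaks: %d summits tested, %d reported", n_tested, len(summits))
    return PeakCallResult(
        summits=summits, params=params, n_tested=n_tested, width_estimated=width_estimated
    )


# -- writers ---------------------------------------------------------------


def _neg_log10(x: float) -> float:
    return -math.log10(max(x, 1e-300))


def write_summit_bed(result: PeakCallResult, path: Union[str, Path]) -> None:
    """Summit positions as BED (0-based half-open), score = -log10 q."""
    with open(path, "w") as fh:
        for i, s in enumerate(result.summits, start=1):
            fh.write(
                f"{s.chrom}\t{s.pos - 1}\t{s.pos}\tpeak_{i}\t{_neg_log10(s.q_value):.5f}\n"
            )


def write_narrowpeak(
    result: PeakCallResult,
    path: Union[str, Path],
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Summits extended by ``summit_extension`` bp each side, ENCODE narrowPeak."""
    ext = result.params.summit_extension
    with open(path, "w") as fh:
        for i, s in enumerate(result.summits, start=1):
            start = max(0, s.pos - 1 - ext)
            end = s.pos + ext
            if chrom_lengths is not None:
                end = min(end, chrom_lengths[s.chrom])
            score = min(1000, int(round(10 * _neg_log10(s.q_value))))
            fh.write(
                f"{s.chrom}\t{start}\t{end}\tpeak_{i}\t{score}\t.\t"
                f"{s.k}\t{_neg_log10(s.p_value):.5f}\t{_neg_log10(s.q_value):.5f}\t"
                f"{s.pos - 1 - start}\n"
            )


def write_summit_tsv(result: PeakCallResult, path: Union[str, Path]) -> None:
    """All summit fields as TSV, one row per reported summit."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tqfrag_depth\tk\tlambda\tp_value\tq_value\n")
        for s in result.summits:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.qfrag_depth}\t{s.k}\t{s.lam:.10g}\t"
                f"{s.p_value:.10g}\t{s.q_value:.10g}\n"
            )
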