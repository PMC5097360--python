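"""Selective PCR-duplicate removal and barcode-aware duplication statistics.

Three read classes are distinguished among reads whose 5' end maps to the
same genomic position and strand:

* **IM** — identically mapped reads (barcode ignored);
* **IMIB** — identically mapped reads with an identical random barcode,
  the presumed PCR duplicates;
* **IMUB** — identically mapped reads with unique barcodes, i.e. the reads
  that remain after keeping one read per (position, strand, barcode).

Exonuclease digestion piles up independent molecules at the same stop
nucleotide, so IM pile-ups alone cannot separate PCR duplication from
genuine signal — the random barcode can.  :func:`deduplicate` keeps exactly
one read per (chrom, pos, strand, barcode); :func:`duplication_profile`
computes, per class, the proportion of reads at each duplication level and
the overall duplication level (the share of reads with 5'-end depth > 1).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import pysam

from .mapped_reads import HitSet, five_prime_position

logger = logging.getLogger("qnexus")

CLASSES = ("IM", "IMIB", "IMUB")


@dataclass
class DuplicationProfile:
    """Per-level read proportions and overall levels for IM/IMIB/IMUB."""

    levels: Dict[str, Dict[int, float]]
    overall: Dict[str, float]
    n_reads: Dict[str, int]
    empty: bool = False

    def binned(self, ceiling: int = 10) -> Dict[str, Dict[str, float]]:
        """Histogram with levels 1..ceiling-1 individual, '>=ceiling' open."""
        out: Dict[str, Dict[str, float]] = {}
        for cls in CLASSES:
            bins = {str(lv): 0.0 for lv in range(1, ceiling)}
            bins[f">={ceiling}"] = 0.0
            for lv, prop in self.levels[cls].items():
                key = str(lv) if lv < ceiling else f">={ceiling}"
                bins[key] += prop
            out[cls] = bins
        return out

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("class\tlevel\tproportion\n")
            for cls in CLASSES:
                for lv in sorted(self.levels[cls]):
                    fh.write(f"{cls}\t{lv}\t{self.levels[cls][lv]:.10g}\n")
            for cls in CLASSES:
                fh.write(f"{cls}\toverall\t{self.overall[cls]:.10g}\n")


def deduplicate(
    hits: HitSet, on_missing_barcode: str = "abort"
) -> Tuple[HitSet, int]:
    """Keep one read per (chrom, pos, strand, barcode); return (IMUB set, n removed).

    Reads without a barcode either abort the run (default) or are treated as
    distinct molecules (``on_missing_barcode="distinct"``), with a warning.
    """
    if not hits.has_barcodes:
        raise ValueError("deduplication requires barcode-tracked hits")
    if on_missing_barcode not in ("abort", "distinct"):
        raise ValueError("on_missing_barcode must be 'abort' or 'distinct'")
    out = HitSet(hits.chrom_lengths, read_length=hits.read_length, track_barcodes=True)
    n_in = 0
    n_retained = 0
    n_missing = 0
    for chrom, pos, strand, barcodes in hits.iter_groups():
        for barcode, cnt in barcodes.items():
            n_in += cnt
            if barcode is None:
                if on_missing_barcode == "abort":
                    raise ValueError(
                        f"read without barcode at ({chrom}, {pos}, {strand}); "
                        "rerun with on_missing_barcode='distinct' to keep such reads"
                    )
                n_missing += cnt
                out.add(chrom, pos, strand, count=cnt, barcode=None)
                n_retained += cnt
            else:
                out.add(chrom, pos, strand, count=1, barcode=barcode)
                n_retained += 1
    if n_missing:
        logger.warning("deduplicate: %d reads without barcode treated as distinct", n_missing)
    return out, n_in - n_retained


def duplication_profile(hits: HitSet) -> DuplicationProfile:
    """Duplication-level histograms for the three read classes.

    Every read contributes at the level of its group: an IM read at the size
    of its (chrom, pos, strand) group, an IMIB read at the size of its
    barcode subgroup, and each retained (IMUB) read at the number of
    distinct barcodes at its position.  Proportions are per class, of that
    class's reads; the overall level is the summed proportion at levels >= 2.
    """
    if not hits.has_barcodes:
        raise ValueError("duplication profiling requires barcode-tracked hits")
    im_hist: Counter = Counter()
    imib_hist: Counter = Counter()
    imub_hist: Counter = Counter()
    for _chrom, _pos, _strand, barcodes in hits.iter_groups():
        group_size = sum(barcodes.values())
        im_hist[group_size] += group_size
        for cnt in barcodes.values():
            imib_hist[cnt] += cnt
        n_distinct = len(barcodes)
        imub_hist[n_distinct] += n_distinct
    hists = {"IM": im_hist, "IMIB": imib_hist, "IMUB": imub_hist}
    levels: Dict[str, Dict[int, float]] = {}
    overall: Dict[str, float] = {}
    n_reads: Dict[str, int] = {}
    empty = sum(im_hist.values()) == 0
    for cls, hist in hists.items():
        total = sum(hist.values())
        n_reads[cls] = total
        if total == 0:
            levels[cls] = {}
            overall[cls] = 0.0
        else:
            levels[cls] = {lv: cnt / total for lv, cnt in sorted(hist.items())}
            overall[cls] = sum(p for lv, p in levels[cls].items() if lv >= 2)
    if empty:
        logger.warning("duplication_profile: no reads; overall levels reported as 0")
    return DuplicationProfile(levels=levels, overall=overall, n_reads=n_reads, empty=empty)


def duplication_plot(
    profile: DuplicationProfile,
    path: Union[str, Path],
    ceiling: int = 10,
    title: Optional[str] = None,
) -> Path:
    """Plot proportion vs duplication level for IM, IMIB and IMUB.

    The level axis shows 1..ceiling-1 and an open-ended final bin.  The
    plotted table is written alongside as TSV (same stem, ``.tsv`` suffix)
    for regression testing.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    binned = profile.binned(ceiling=ceiling)
    bins = [str(lv) for lv in range(1, ceiling)] + [f">={ceiling}"]
    colors = {"IM": "crimson", "IMIB": "steelblue", "IMUB": "black"}
    fig, ax = plt.subplots(figsize=(6, 4))
    for cls in CLASSES:
        ax.plot(
            bins,
            [binned[cls][b] for b in bins],
            marker="o",
            color=colors[cls],
            label=f"{cls} (overall {100 * profile.overall[cls]:.1f}%)",
        )
    ax.set_xlabel("duplication level (5'-end depth)")
    ax.set_ylabel("proportion of reads")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)

    tsv = path.with_suffix(".tsv")
    with open(tsv, "w") as fh:
        fh.write("class\tbin\tproportion\n")
        for cls in CLASSES:
            for b in bins:
                fh.write(f"{cls}\t{b}\t{binned[cls][b]:.10g}\n")
    return path


def write_deduplicated_alignments(
    in_path: Union[str, Path],
    out_path: Union[str, Path],
    on_missing_barcode: str = "abort",
) -> Tuple[int, int]:
    """Stream a SAM/BAM file, keeping the first read per (5' pos, strand, barcode).

    Which duplicate is kept does not matter for any downstream statistic;
    "first in file order" makes the output deterministic for
    coordinate-sorted input.  Returns ``(n_retained, n_removed)``.
    """
    seen = set()
    n_retained = 0
    n_removed = 0
    with pysam.AlignmentFile(str(in_path), check_sq=False) as bam:
        mode = "wb" if str(out_path).endswith(".bam") else "w"
        with pysam.AlignmentFile(str(out_path), mode, header=bam.header) as out:
            for aln in bam.fetch(until_eof=True):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                hit = five_prime_position(aln)
                if hit.barcode is None:
                    if on_missing_barcode == "abort":
                        raise ValueError(
                            f"alignment {aln.query_name!r} carries no TL: barcode"
                        )
                    out.write(aln)
                    n_retained += 1
                    continue
                key = (hit.chrom, hit.pos, hit.strand, hit.barcode)
                if key in seen:
                    n_removed += 1
                    continue
                seen.add(key)
                out.write(aln)
                n_retained += 1
    return n_retained, n_removed
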