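"""Reduction of mapped single-end alignments to strand-aware 5' end hits.

All downstream statistics operate on *hits*: the 5'-end position and strand
of a uniquely mapped read, ``h = (pos, strand)`` with ``pos`` 1-based in
``{1, ..., l}`` and ``strand`` in ``{f, r}``.  :class:`HitSet` stores the
per-chromosome multisets ``T_f`` and ``T_r`` as position -> count tables and
optionally, per position, the multiset of random barcodes recovered from the
``TL:`` token in the query name — the input to duplicate removal.

Coordinates are 1-based fully-closed everywhere inside the package; BED
output converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, Optional, Sequence, Tuple, Union

import pysam

logger = logging.getLogger("qnexus")

FORWARD = "f"
REVERSE = "r"
_STRANDS = (FORWARD, REVERSE)

_BARCODE_RE = re.compile(r"TL:([ACGTN]+)")


@dataclass(frozen=True)
class Hit:
    """A 5'-end mapping event."""

    chrom: str
    pos: int  # 1-based
    strand: str  # 'f' or 'r'
    barcode: Optional[str] = None


class HitSet:
    """Per-chromosome, strand-separated multisets of 5'-end hits.

    Parameters
    ----------
    chrom_lengths
        Mapping of chromosome name to length in bp; positions are validated
        against it.
    read_length
        The (modal) mapped read length ``rl`` used by the pseudo-control.
    track_barcodes
        When true, per-position barcode multisets are kept so that duplicate
        removal and duplication profiling are possible.
    """

    def __init__(
        self,
        chrom_lengths: Union[Dict[str, int], Iterable[Tuple[str, int]]],
        read_length: Optional[int] = None,
        track_barcodes: bool = False,
    ) -> None:
        self.chrom_lengths: Dict[str, int] = dict(chrom_lengths)
        for name, length in self.chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.read_length = read_length
        self._counts: Dict[Tuple[str, str], Counter] = defaultdict(Counter)
        self._barcodes: Optional[Dict[Tuple[str, str], Dict[int, Counter]]] = (
            defaultdict(lambda: defaultdict(Counter)) if track_barcodes else None
        )

    # -- construction -----------------------------------------------------

    def add(
        self,
        chrom: str,
        pos: int,
        strand: str,
        count: int = 1,
        barcode: Optional[str] = None,
    ) -> None:
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 1 <= pos <= self.chrom_lengths[chrom]:
            raise ValueError(f"position {pos} outside [1, {self.chrom_lengths[chrom]}] on {chrom}")
        if strand not in _STRANDS:
            raise ValueError(f"strand must be 'f' or 'r', got {strand!r}")
        if count < 1:
            raise ValueError("count must be >= 1")
        self._counts[(chrom, strand)][pos] += count
        if self._barcodes is not None:
            self._barcodes[(chrom, strand)][pos][barcode] += count

    # -- accessors --------------------------------------------------------

    @property
    def has_barcodes(self) -> bool:
        return self._barcodes is not None

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(sorted(self.chrom_lengths))

    def counts(self, chrom: str, strand: str) -> Counter:
        """Position -> read count table for one chromosome strand."""
        return self._counts.get((chrom, strand), Counter())

    def barcode_table(self, chrom: str, strand: str) -> Dict[int, Counter]:
        if self._barcodes is None:
            raise ValueError("this HitSet does not track barcodes")
        return self._barcodes.get((chrom, strand), {})

    def strand_total(self, chrom: str, strand: str) -> int:
        return sum(self._counts.get((chrom, strand), Counter()).values())

    @property
    def n_forward(self) -> int:
        return sum(self.strand_total(c, FORWARD) for c in self.chrom_lengths)

    @property
    def n_reverse(self) -> int:
        return sum(self.strand_total(c, REVERSE) for c in self.chrom_lengths)

    @property
    def total(self) -> int:
        return self.n_forward + self.n_reverse

    def iter_groups(self) -> Iterator[Tuple[str, int, str, Counter]]:
        """Yield ``(chrom, pos, strand, barcode_counter)`` position groups."""
        if self._barcodes is None:
            raise ValueError("this HitSet does not track barcodes")
        for chrom in self.chroms:
            for strand in _STRANDS:
                table = self._barcodes.get((chrom, strand), {})
                for pos in sorted(table):
                    yield chrom, pos, strand, table[pos]

    # -- transforms -------------------------------------------------------

    def filter_chroms(
        self,
        include: Optional[Sequence[str]] = None,
        exclude: Optional[Sequence[str]] = None,
    ) -> "HitSet":
        """Restrict to a chromosome subset (include takes precedence)."""
        keep = set(self.chrom_lengths)
        if include is not None:
            keep &= set(include)
        if exclude is not None:
            keep -= set(exclude)
        out = HitSet(
            {c: l for c, l in self.chrom_lengths.items() if c in keep},
            read_length=self.read_length,
            track_barcodes=self.has_barcodes,
        )
        for (chrom, strand), table in self._counts.items():
            if chrom not in keep:
                continue
            if self._barcodes is not None:
                for pos, bcs in self._barcodes[(chrom, strand)].items():
                    for bc, cnt in bcs.items():
                        out.add(chrom, pos, strand, count=cnt, barcode=bc)
            else:
                for pos, cnt in table.items():
                    out.add(chrom, pos, strand, count=cnt)
        return out

    # -- serialisation ----------------------------------------------------

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write a deterministic hit table (with barcodes when tracked)."""
        with open(path, "w") as fh:
            for chrom in self.chroms:
                fh.write(f"#chrom\t{chrom}\t{self.chrom_lengths[chrom]}\n")
            if self.read_length is not None:
                fh.write(f"#read_length\t{self.read_length}\n")
            fh.write("chrom\tpos\tstrand\tbarcode\tcount\n")
            for chrom in self.chroms:
                for strand in _STRANDS:
                    if self._barcodes is not None:
                        table = self._barcodes.get((chrom, strand), {})
                        for pos in sorted(table):
                            for bc in sorted(table[pos], key=lambda b: (b is None, b)):
                                cnt = table[pos][bc]
                                fh.write(
                                    f"{chrom}\t{pos}\t{strand}\t{bc or '.'}\t{cnt}\n"
                                )
                    else:
                        counts = self._counts.get((chrom, strand), Counter())
                        for pos in sorted(counts):
                            fh.write(f"{chrom}\t{pos}\t{strand}\t.\t{counts[pos]}\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "HitSet":
        chrom_lengths: Dict[str, int] = {}
        read_length: Optional[int] = None
        rows = []
        track_barcodes = False
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#chrom\t"):
                    _, name, length = line.split("\t")
                    chrom_lengths[name] = int(length)
                elif line.startswith("#read_length\t"):
                    read_length = int(line.split("\t")[1])
                elif line.startswith("chrom\t") or not line:
                    continue
                else:
                    chrom, pos, strand, bc, cnt = line.split("\t")
                    barcode = None if bc == "." else bc
                    if barcode is not None:
                        track_barcodes = True
                    rows.append((chrom, int(pos), strand, barcode, int(cnt)))
        out = cls(chrom_lengths, read_length=read_length, track_barcodes=track_barcodes)
        for chrom, pos, strand, barcode, cnt in rows:
            out.add(chrom, pos, strand, count=cnt, barcode=barcode)
        return out


def barcode_from_query_name(query_name: str) -> Optional[str]:
    """Recover the random barcode from a ``TL:`` token in the query name."""
    m = _BARCODE_RE.search(query_name)
    return m.group(1) if m else None


def five_prime_position(alignment: pysam.AlignedSegment) -> Hit:
    """Reduce a mapped alignment to its 5'-end hit.

    The 5' end of a forward alignment is its leftmost aligned reference
    base, of a reverse alignment its rightmost; soft-clipped bases are not
    extrapolated through, since the exonuclease-stop evidence is the aligned
    terminus.
    """
    if alignment.is_unmapped:
        raise ValueError("alignment is unmapped")
    if alignment.is_reverse:
        pos = alignment.reference_end  # 0-based exclusive == 1-based inclusive
        strand = REVERSE
    else:
        pos = alignment.reference_start + 1
        strand = FORWARD
    return Hit(
        chrom=alignment.reference_name,
        pos=pos,
        strand=strand,
        barcode=barcode_from_query_name(alignment.query_name or ""),
    )


def load_hits(
    path: Union[str, Path],
    include_chroms: Optional[Sequence[str]] = None,
    exclude_chroms: Optional[Sequence[str]] = None,
    min_mapq: int = 0,
    read_length: Optional[int] = None,
    track_barcodes: bool = True,
) -> HitSet:
    """Load a SAM/BAM file into a :class:`HitSet`.

    Only mapped, primary, non-supplementary alignments are used; uniqueness
    of mapping is trusted to the upstream aligner (an optional MAPQ floor is
    available via ``min_mapq``).  ``read_length`` overrides the modal mapped
    read length otherwise taken from the alignments.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        if bam.header.nreferences == 0:
            raise ValueError(f"{path}: no reference sequences in header")
        chrom_lengths = dict(zip(bam.references, bam.lengths))
        keep = set(chrom_lengths)
        if include_chroms is not None:
            keep &= set(include_chroms)
        if exclude_chroms is not None:
            keep -= set(exclude_chroms)
        hits = HitSet(
            {c: l for c, l in chrom_lengths.items() if c in keep},
            track_barcodes=track_barcodes,
        )
        length_counts: Counter = Counter()
        n_skipped = 0
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                n_skipped += 1
                continue
            if aln.mapping_quality < min_mapq:
                n_skipped += 1
                continue
            if aln.reference_name not in keep:
                n_skipped += 1
                continue
            hit = five_prime_position(aln)
            hits.add(hit.chrom, hit.pos, hit.strand, barcode=hit.barcode)
            if aln.query_length:
                length_counts[aln.query_length] += 1
    if read_length is not None:
        hits.read_length = read_length
    elif length_counts:
        # modal read length; ties broken toward the longer read
        hits.read_length = max(length_counts, key=lambda k: (length_counts[k], k))
    if n_skipped:
        logger.info("load_hits: skipped %d alignments (unmapped/secondary/filtered)", n_skipped)
    return hits
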