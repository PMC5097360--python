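"""Barcode extraction and adapter clipping for raw ChIP-nexus reads.

ChIP-nexus libraries carry a leading random barcode (a UMI) followed by a
fixed barcode at the 5' end of every read.  Before alignment the random
barcode must be moved out of the sequence and into the read ID (as a
``TL:<barcode>`` token) so that the duplicate-removal step can recover it
from the aligned reads; the fixed barcode acts as a library sanity filter
(at most one mismatch is tolerated).  Because lambda-exonuclease digestion
produces many inserts shorter than the read length, reads frequently run
into the sequencing adapter, which is clipped from the 3' end.

The three entry points mirror the stages of the preprocessing workflow:

* :func:`parse_barcode` -- split off random + fixed barcode, tag the ID.
* :func:`clip_adapter` -- remove a 3' adapter overlap, drop adapter-only reads.
* :func:`preprocess` -- stream a FASTQ file through both stages.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Optional, Tuple, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger("qnexus")

ID_TAG_PREFIX = "TL:"
_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class BarcodeConfig:
    """Geometry of the barcoded read prefix and the 3' adapter.

    The random-barcode length and the fixed-barcode sequence are protocol
    constants of the library preparation, not of the method, so the fixed
    barcode has no default and must be supplied by the user.
    """

    fixed_barcode: str
    adapter: str
    random_len: int = 5
    max_fixed_mismatch: int = 1
    min_len_after_clip: int = 1
    min_adapter_overlap: int = 3
    id_tag_prefix: str = ID_TAG_PREFIX

    def __post_init__(self) -> None:
        if self.random_len < 1:
            raise ValueError("random_len must be >= 1")
        if not self.fixed_barcode or set(self.fixed_barcode) - set("ACGT"):
            raise ValueError("fixed_barcode must be a non-empty string over {A,C,G,T}")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.min_len_after_clip < 1:
            raise ValueError("min_len_after_clip must be >= 1")


@dataclass(frozen=True)
class ReadRecord:
    """A single FASTQ read (ID without the leading '@')."""

    id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )


@dataclass
class PreprocessStats:
    """Per-reason read accounting for one preprocessing run."""

    n_input: int = 0
    n_discarded_fixed_barcode: int = 0
    n_discarded_all_adapter: int = 0
    n_discarded_too_short: int = 0
    n_discarded_bad_sequence: int = 0
    n_output: int = 0

    @property
    def n_discarded(self) -> int:
        return (
            self.n_discarded_fixed_barcode
            + self.n_discarded_all_adapter
            + self.n_discarded_too_short
            + self.n_discarded_bad_sequence
        )

    def check(self) -> None:
        if self.n_input != self.n_output + self.n_discarded:
            raise AssertionError(f"read accounting violated: {self}")

    def to_tsv(self, path: Union[str, Path]) -> None:
        rows = [
            ("n_input", self.n_input),
            ("n_discarded_fixed_barcode", self.n_discarded_fixed_barcode),
            ("n_discarded_all_adapter", self.n_discarded_all_adapter),
            ("n_discarded_too_short", self.n_discarded_too_short),
            ("n_discarded_bad_sequence", self.n_discarded_bad_sequence),
            ("n_output", self.n_output),
        ]
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for k, v in rows:
                fh.write(f"{k}\t{v}\n")


def _hamming(a: str, b: str) -> int:
    # N never matches: conservative for the fixed-barcode filter.
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def parse_barcode(
    read: ReadRecord, cfg: BarcodeConfig
) -> Tuple[Optional[ReadRecord], Optional[str]]:
    """Move the random barcode into the read ID and strip both barcodes.

    Returns ``(record, None)`` on acceptance, where the record's ID gained a
    ``TL:<barcode>`` token (space separated) and sequence/qualities lost the
    ``random_len + len(fixed_barcode)`` prefix, or ``(None, reason)`` with
    reason in ``{"too_short", "bad_sequence", "fixed_barcode"}``.
    """
    seq = read.sequence.upper()
    if set(seq) - _VALID_BASES:
        return None, "bad_sequence"
    prefix = cfg.random_len + len(cfg.fixed_barcode)
    if len(seq) < prefix + cfg.min_len_after_clip:
        return None, "too_short"
    random_bc = seq[: cfg.random_len]
    observed_fixed = seq[cfg.random_len : prefix]
    if _hamming(observed_fixed, cfg.fixed_barcode) > cfg.max_fixed_mismatch:
        return None, "fixed_barcode"
    tagged = ReadRecord(
        id=f"{read.id} {cfg.id_tag_prefix}{random_bc}",
        sequence=seq[prefix:],
        qualities=read.qualities[prefix:],
    )
    return tagged, None


def _leftmost_adapter_start(seq: str, adapter: str, min_overlap: int) -> Optional[int]:
    """Leftmost position where a prefix of ``adapter`` matches through the
    read's 3' end (exact match, overlap >= min_overlap); None if absent."""
    n = len(seq)
    for i in range(n - min_overlap + 1):
        m = min(n - i, len(adapter))
        if seq[i : i + m] == adapter[:m]:
            return i
    return None


def clip_adapter(
    read: ReadRecord, cfg: BarcodeConfig
) -> Tuple[Optional[ReadRecord], Optional[str]]:
    """Clip a 3' adapter overlap; reject adapter-only or over-clipped reads.

    Everything from the leftmost qualifying adapter match to the read end is
    removed.  Reads that begin with adapter are rejected ``"all_adapter"``;
    reads whose clipped length falls below ``min_len_after_clip`` are
    rejected ``"too_short"``.
    """
    start = _leftmost_adapter_start(read.sequence, cfg.adapter, cfg.min_adapter_overlap)
    if start is None:
        return read, None
    if start == 0:
        return None, "all_adapter"
    if start < cfg.min_len_after_clip:
        return None, "too_short"
    return ReadRecord(read.id, read.sequence[:start], read.qualities[:start]), None


def _open_maybe_gzip(path: Union[str, Path], mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")  # type: ignore[return-value]
    return open(path, mode)


def _iter_fastq(handle: IO[str], path: Union[str, Path]) -> Iterator[ReadRecord]:
    it = FastqGeneralIterator(handle)
    index = 0
    while True:
        try:
            title, seq, qual = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record #{index} in {path}: {exc}") from exc
        yield ReadRecord(title, seq, qual)
        index += 1


def preprocess(
    fastq_in: Union[str, Path],
    fastq_out: Union[str, Path],
    cfg: BarcodeConfig,
) -> PreprocessStats:
    """Stream a FASTQ file through barcode extraction and adapter clipping.

    Surviving reads keep their input order.  Input and output may be plain
    or gzip-compressed (by ``.gz`` suffix).
    """
    stats = PreprocessStats()
    with _open_maybe_gzip(fastq_in, "r") as fin, _open_maybe_gzip(fastq_out, "w") as fout:
        for read in _iter_fastq(fin, fastq_in):
            stats.n_input += 1
            tagged, reason = parse_barcode(read, cfg)
            if tagged is None:
                if reason == "fixed_barcode":
                    stats.n_discarded_fixed_barcode += 1
                elif reason == "too_short":
                    stats.n_discarded_too_short += 1
                else:
                    stats.n_discarded_bad_sequence += 1
                continue
            clipped, reason = clip_adapter(tagged, cfg)
            if clipped is None:
                if reason == "all_adapter":
                    stats.n_discarded_all_adapter += 1
                else:
                    stats.n_discarded_too_short += 1
                continue
            fout.write(f"@{clipped.id}\n{clipped.sequence}\n+\n{clipped.qualities}\n")
            stats.n_output += 1
    stats.check()
    logger.info(
        "preprocess: %d in, %d out (%d fixed-barcode, %d all-adapter, %d too-short, %d bad)",
        stats.n_input,
        stats.n_output,
        stats.n_discarded_fixed_barcode,
        stats.n_discarded_all_adapter,
        stats.n_discarded_too_short,
        stats.n_discarded_bad_sequence,
    )
    return stats
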