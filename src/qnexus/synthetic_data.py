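"""Ground-truthed ChIP-nexus read simulation.

The generator emulates the statistical structure the method assumes, so
every pipeline stage is testable without downloading real data:

* *sites* — at each binding position s, molecules place their 5' end at
  ``s - ceil(w/2)`` (forward) or ``s + floor(w/2)`` (reverse) plus rounded
  Gaussian jitter, so the forward-reverse 5'-end distance is exactly the
  protected-region width w;
* *barcodes and PCR* — each molecule draws a uniform random barcode and
  ``1 + Poisson(pcr_duplication_mean)`` PCR copies;
* *background* — uniform hits on both strands at a fixed per-bp rate, one
  copy each, fresh barcodes;
* *phantom loci* — repeat-like artifacts: matched forward/reverse 5'-end
  clusters exactly ``rl - 1`` apart with distinct barcodes, the pattern that
  produces the phantom peak at one read length in fragment-size estimators.

:func:`emit_fastq` renders molecules as raw barcoded reads over a
seed-derived random reference (written as FASTA), appending adapter when
the insert is shorter than the read length; :func:`write_alignments`
renders the corresponding post-alignment SAM/BAM so deduplication and peak
calling can be exercised without running an aligner.  All randomness flows
from ``SimConfig.seed``; equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pysam

from .mapped_reads import FORWARD, REVERSE, HitSet

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; the defaults are the standard study conditions."""

    seed: int = 0
    genome: Tuple[Tuple[str, int], ...] = (("chrS1", 800_000), ("chrS2", 200_000))
    n_sites: int = 200
    protected_width: int = 18  # plays the role of the estimated width
    jitter_sd: float = 1.0
    molecules_per_site: int = 50
    pcr_duplication_mean: float = 1.0
    background_rate: float = 0.01  # hits per bp per strand
    read_length: int = 42
    fragment_length: int = 60  # insert length of each molecule (cosmetic)
    barcode_len: int = 5
    fixed_barcode: str = "CTGA"
    adapter: str = "AGATCGGAAGAGCACACGTCTGGA"
    n_phantom_loci: int = 0
    phantom_molecules: int = 30  # per strand per locus
    min_site_gap: int = 200

    def __post_init__(self) -> None:
        if self.protected_width < 2:
            raise ValueError("protected_width must be >= 2")
        if self.background_rate < 0 or self.pcr_duplication_mean < 0 or self.jitter_sd < 0:
            raise ValueError("rates must be >= 0")
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")


@dataclass(frozen=True)
class MoleculeRecord:
    """One sequenced molecule of the ground truth (all its PCR copies)."""

    read_id: str
    chrom: str
    pos: int  # 5'-end position
    strand: str
    barcode: str
    copies: int
    insert_len: int
    origin: str  # "site:<i>", "background", or "phantom:<j>"


@dataclass
class GroundTruth:
    sites: List[Tuple[str, int]]
    phantom_loci: List[Tuple[str, int]]
    molecules: List[MoleculeRecord]

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for chrom, pos in self.sites:
                fh.write(f"#site\t{chrom}\t{pos}\n")
            for chrom, pos in self.phantom_loci:
                fh.write(f"#phantom\t{chrom}\t{pos}\n")
            fh.write("read_id\tchrom\tpos\tstrand\tbarcode\tcopies\tinsert_len\torigin\n")
            for m in self.molecules:
                fh.write(
                    f"{m.read_id}\t{m.chrom}\t{m.pos}\t{m.strand}\t{m.barcode}\t"
                    f"{m.copies}\t{m.insert_len}\t{m.origin}\n"
                )


def _random_barcode(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _place_sites(cfg: SimConfig, rng: np.random.Generator, n: int) -> List[Tuple[str, int]]:
    """Distribute n sites over the genome, proportional to chromosome length,
    with a minimum pairwise gap so neighbouring peaks never interact."""
    total = sum(l for _, l in cfg.genome)
    margin = cfg.protected_width + 4 * max(1, int(math.ceil(cfg.jitter_sd))) + 50
    alloc: List[int] = []
    assigned = 0
    for i, (_, l) in enumerate(cfg.genome):
        if i == len(cfg.genome) - 1:
            alloc.append(n - assigned)
        else:
            a = int(round(n * l / total))
            alloc.append(a)
            assigned += a
    sites: List[Tuple[str, int]] = []
    for (chrom, l), n_chrom in zip(cfg.genome, alloc):
        if n_chrom == 0:
            continue
        usable = l - 2 * margin
        spacing = usable // n_chrom
        if spacing < cfg.min_site_gap:
            raise ValueError(
                f"cannot place {n_chrom} sites with gap >= {cfg.min_site_gap} on "
                f"{chrom} (length {l})"
            )
        slack = spacing - cfg.min_site_gap
        for i in range(n_chrom):
            offset = int(rng.integers(0, slack + 1)) if slack > 0 else 0
            sites.append((chrom, margin + i * spacing + offset))
    return sites


def simulate_hits(cfg: SimConfig) -> Tuple[HitSet, GroundTruth]:
    """Generate a barcoded hit set plus its ground truth.

    Returns the *pre-deduplication* hit set: each molecule contributes its
    PCR copies at its (position, strand) with its barcode.
    """
    rng = np.random.default_rng(cfg.seed)
    hits = HitSet(dict(cfg.genome), read_length=cfg.read_length, track_barcodes=True)
    molecules: List[MoleculeRecord] = []
    half_up = -(-cfg.protected_width // 2)  # ceil(w/2)
    half_down = cfg.protected_width // 2

    sites = _place_sites(cfg, rng, cfg.n_sites) if cfg.n_sites > 0 else []
    mol_idx = 0
    for site_i, (chrom, s) in enumerate(sites):
        l = dict(cfg.genome)[chrom]
        for _ in range(cfg.molecules_per_site):
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            jitter = int(round(rng.normal(0.0, cfg.jitter_sd))) if cfg.jitter_sd > 0 else 0
            pos = (s - half_up + jitter) if strand == FORWARD else (s + half_down + jitter)
            pos = min(max(pos, 1), l)
            barcode = _random_barcode(rng, cfg.barcode_len)
            copies = 1 + int(rng.poisson(cfg.pcr_duplication_mean))
            molecules.append(
                MoleculeRecord(
                    read_id=f"mol{mol_idx}",
                    chrom=chrom,
                    pos=pos,
                    strand=strand,
                    barcode=barcode,
                    copies=copies,
                    insert_len=cfg.fragment_length,
                    origin=f"site:{site_i}",
                )
            )
            mol_idx += 1

    # uniform background, one copy per molecule
    if cfg.background_rate > 0:
        for chrom, l in cfg.genome:
            for strand in (FORWARD, REVERSE):
                n_bg = int(rng.poisson(cfg.background_rate * l))
                positions = rng.integers(1, l + 1, size=n_bg)
                for pos in positions:
                    molecules.append(
                        MoleculeRecord(
                            read_id=f"mol{mol_idx}",
                            chrom=chrom,
                            pos=int(pos),
                            strand=strand,
                            barcode=_random_barcode(rng, cfg.barcode_len),
                            copies=1,
                            insert_len=cfg.fragment_length,
                            origin="background",
                        )
                    )
                    mol_idx += 1

    # repeat-driven artifacts: paired clusters exactly rl - 1 apart
    phantom_loci: List[Tuple[str, int]] = []
    if cfg.n_phantom_loci > 0:
        phantom_cfg = replace(cfg, protected_width=max(cfg.read_length, 2))
        phantom_loci = _place_sites(phantom_cfg, rng, cfg.n_phantom_loci)
        for locus_i, (chrom, q) in enumerate(phantom_loci):
            for strand, pos in ((FORWARD, q), (REVERSE, q + cfg.read_length - 1)):
                for _ in range(cfg.phantom_molecules):
                    molecules.append(
                        MoleculeRecord(
                            read_id=f"mol{mol_idx}",
                            chrom=chrom,
                            pos=pos,
                            strand=strand,
                            barcode=_random_barcode(rng, cfg.barcode_len),
                            copies=1,
                            insert_len=cfg.fragment_length,
                            origin=f"phantom:{locus_i}",
                        )
                    )
                    mol_idx += 1

    for m in molecules:
        hits.add(m.chrom, m.pos, m.strand, count=m.copies, barcode=m.barcode)
    truth = GroundTruth(sites=sites, phantom_loci=phantom_loci, molecules=molecules)
    return hits, truth


# -- rendering to sequence formats ----------------------------------------


def make_reference(cfg: SimConfig) -> Dict[str, str]:
    """Seed-derived random reference sequences, one per chromosome."""
    rng = np.random.default_rng([cfg.seed, 900913])
    return {
        chrom: rng.choice(_BASES, size=l).tobytes().decode()
        for chrom, l in cfg.genome
    }


def write_reference_fasta(reference: Dict[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _molecule_insert(reference: Dict[str, str], m: MoleculeRecord) -> str:
    """Insert sequence in read orientation (5'->3' from the hit position)."""
    ref = reference[m.chrom]
    if m.strand == FORWARD:
        start = m.pos - 1
        return ref[start : start + m.insert_len]
    end = m.pos  # 1-based inclusive -> slice end
    start = max(0, end - m.insert_len)
    seg = ref[start:end]
    return seg.translate(_COMPLEMENT)[::-1]


def emit_fastq(
    truth: GroundTruth,
    cfg: SimConfig,
    fastq_path: Union[str, Path],
    fasta_path: Optional[Union[str, Path]] = None,
    reference: Optional[Dict[str, str]] = None,
) -> None:
    """Render the ground truth as raw barcoded FASTQ reads.

    Each read is ``random barcode + fixed barcode + insert``, filled up to
    the read length with adapter when the insert is shorter than
    ``read_length`` (the exonuclease-digested short-insert case).
    """
    if reference is None:
        reference = make_reference(cfg)
    if fasta_path is not None:
        write_reference_fasta(reference, fasta_path)
    adapter_fill = (cfg.adapter * (cfg.read_length // len(cfg.adapter) + 2))
    with open(fastq_path, "w") as fh:
        for m in truth.molecules:
            insert = _molecule_insert(reference, m)
            core = insert[: cfg.read_length]
            if len(core) < cfg.read_length:
                core = core + adapter_fill[: cfg.read_length - len(core)]
            seq = m.barcode + cfg.fixed_barcode + core
            qual = "I" * len(seq)
            for c in range(m.copies):
                fh.write(f"@{m.read_id}.{c}\n{seq}\n+\n{qual}\n")


def write_alignments(
    truth: GroundTruth,
    cfg: SimConfig,
    path: Union[str, Path],
) -> None:
    """Render the ground truth as a coordinate-sorted SAM/BAM file.

    Emulates the post-alignment state: adapter already clipped, the random
    barcode carried in the query name as a ``TL:`` token, one alignment per
    PCR copy.  Output format follows the file suffix (.bam -> BAM).
    """
    reference = make_reference(cfg)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": chrom, "LN": l} for chrom, l in cfg.genome],
        }
    )
    chrom_index = {chrom: i for i, (chrom, _) in enumerate(cfg.genome)}
    rows = []
    for m in truth.molecules:
        insert = _molecule_insert(reference, m)
        alen = min(len(insert), cfg.read_length)
        if m.strand == FORWARD:
            ref_start0 = m.pos - 1
            flag = 0
            seq = insert[:alen]
        else:
            ref_start0 = m.pos - alen
            flag = 16
            # SAM stores the reference-forward sequence
            seq = reference[m.chrom][ref_start0 : ref_start0 + alen]
        for c in range(m.copies):
            rows.append((chrom_index[m.chrom], ref_start0, flag, m, c, alen, seq))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3].read_id, r[4]))
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for tid, ref_start0, flag, m, c, alen, seq in rows:
            a = pysam.AlignedSegment(header=header)
            a.query_name = f"{m.read_id}.{c} TL:{m.barcode}"
            a.flag = flag
            a.reference_id = tid
            a.reference_start = ref_start0
            a.mapping_quality = 42
            a.cigartuples = [(0, alen)]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * alen)
            out.write(a)
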