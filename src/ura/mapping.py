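"""Read assignment: internal exact mapper, SAM import, downsampling, window counts.

The estimator only consumes reads whose best mapping is to a unique
location in the representative set. At desk scale this package ships an
exact-match mapper that is self-consistent with the build stage (the build
enumerates exact substrings, so exact lookup reproduces precisely the
unique/multi classification the index encodes). Alignments produced by an
external mismatch-tolerant aligner can be imported from SAM instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._util import canonical
from .reference import ReferenceDB, _MULTI

logger = logging.getLogger(__name__)

UNIQUE = "unique"
MULTI = "multi"
UNMAPPED = "unmapped"


@dataclass
class ReadAssignment:
    read_id: str
    status: str  # unique | multi | unmapped
    genome_id: str | None = None
    position: int | None = None
    strand: str | None = None  # '+' read equals the reference substring, '-' its revcomp


@dataclass
class WindowCounts:
    """Per-genome window hit vectors plus the number of assigned reads."""

    counts: dict[str, np.ndarray]
    total_assigned: int


def build_exact_index(db: ReferenceDB) -> dict[str, tuple[int, int]]:
    """Canonical read-length substring -> (genome index, position) lookup.

    Substrings occurring at more than one location map to a multi sentinel.
    Cached on the database object; O(1) expected-time queries.
    """
    if db._lookup is None:
        from .reference import _occurrence_map

        db._lookup = _occurrence_map(list(db.genomes.values()), db.read_len)
    return db._lookup


def map_reads(
    reads: Iterable[tuple[str, str]], db: ReferenceDB
) -> list[ReadAssignment]:
    """Classify reads as unique / multi / unmapped by exact canonical lookup.

    ``reads`` yields (read_id, sequence). Reads of the wrong length or
    containing ``N`` are unmapped (read length is fixed upstream by the
    build; trimming is out of scope).
    """
    lookup = build_exact_index(db)
    genome_ids = list(db.genomes)
    read_len = db.read_len
    out: list[ReadAssignment] = []
    n_wrong_len = 0
    for read_id, seq in reads:
        if len(seq) != read_len or "N" in seq:
            if len(seq) != read_len:
                n_wrong_len += 1
            out.append(ReadAssignment(read_id, UNMAPPED))
            continue
        key = canonical(seq)
        hit = lookup.get(key)
        if hit is None:
            out.append(ReadAssignment(read_id, UNMAPPED))
        elif hit == _MULTI:
            out.append(ReadAssignment(read_id, MULTI))
        else:
            gi, pos = hit
            gid = genome_ids[gi]
            strand = "+" if seq == db.genomes[gid].sequence[pos : pos + read_len] else "-"
            out.append(ReadAssignment(read_id, UNIQUE, gid, pos, strand))
    if n_wrong_len:
        logger.warning("%d reads had length != %d and were left unmapped", n_wrong_len, read_len)
    return out


def import_sam_assignments(
    sam_path, db: ReferenceDB, min_score: int = -40
) -> list[ReadAssignment]:
    """Derive assignments from external-aligner SAM records.

    A read is *unique* iff exactly one of its non-supplementary alignments
    scores at least ``min_score`` (alignment-score ``AS`` tag); two or more
    passing alignments (including a co-optimal secondary) make it *multi*;
    none make it *unmapped*. Alignments without an AS tag are treated as
    passing (aligner chose to report them without a score).
    """
    import pysam

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        per_read: dict[str, list] = {}
        order: list[str] = []
        for rec in sam:
            if rec.query_name not in per_read:
                per_read[rec.query_name] = []
                order.append(rec.query_name)
            if rec.is_unmapped or rec.is_supplementary:
                continue
            if rec.reference_name not in db.genomes:
                raise ValueError(f"unknown reference name {rec.reference_name!r} in SAM")
            score = rec.get_tag("AS") if rec.has_tag("AS") else None
            if score is not None and score < min_score:
                continue
            per_read[rec.query_name].append(rec)
    out = []
    for read_id in order:
        passing = per_read[read_id]
        if not passing:
            out.append(ReadAssignment(read_id, UNMAPPED))
        elif len(passing) > 1:
            out.append(ReadAssignment(read_id, MULTI))
        else:
            rec = passing[0]
            out.append(
                ReadAssignment(
                    read_id,
                    UNIQUE,
                    rec.reference_name,
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                )
            )
    return out


def downsample_assignments(
    assignments: Sequence[ReadAssignment], depth: int, seed: int
) -> list[ReadAssignment]:
    """Uniformly subsample mapped reads (unique or multi) to a fixed depth.

    Unmapped reads are discarded first; when fewer than ``depth`` mapped
    reads exist, all are kept. Sampling is without replacement and
    deterministic given ``seed``. Fixing the mapped depth across samples
    removes sequencing-effort differences before abundance estimation.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    mapped = [a for a in assignments if a.status != UNMAPPED]
    if len(mapped) <= depth:
        return mapped
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(mapped), size=depth, replace=False)
    idx.sort()
    return [mapped[i] for i in idx]


def count_window_hits(
    assignments: Sequence[ReadAssignment], db: ReferenceDB
) -> WindowCounts:
    """Count uniquely-assigned reads per unique-count window.

    Each unique assignment whose start position is a member of a window
    increments that window; positions in the trailing remainder (unique but
    unwindowed) contribute nothing. A unique assignment at a position that
    is not a unique position of its genome signals a database/sample
    mismatch and raises.
    """
    pos_to_window: dict[str, dict[int, int]] = {}
    unique_sets: dict[str, set[int]] = {}
    for gid, wins in db.windows.items():
        m: dict[int, int] = {}
        for w in wins:
            for p in w.member_positions:
                m[p] = w.ordinal
        pos_to_window[gid] = m
        unique_sets[gid] = set(db.index.positions[gid])
    counts = {gid: np.zeros(len(wins), dtype=np.int64) for gid, wins in db.windows.items()}
    total = 0
    for a in assignments:
        if a.status != UNIQUE:
            continue
        total += 1
        ordinal = pos_to_window[a.genome_id].get(a.position)
        if ordinal is not None:
            counts[a.genome_id][ordinal] += 1
        elif a.position not in unique_sets[a.genome_id]:
            raise ValueError(
                f"assignment at {a.genome_id}:{a.position} is not a unique "
                "position of the database (db/sample mismatch?)"
            )
    return WindowCounts(counts=counts, total_assigned=total)


def write_assignments_tsv(assignments: Sequence[ReadAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\tgenome_id\tposition\tstrand\n")
        for a in assignments:
            fh.write(
                f"{a.read_id}\t{a.status}\t{a.genome_id or ''}"
                f"\t{'' if a.position is None else a.position}\t{a.strand or ''}\n"
            )


def read_fastx(path) -> Iterable[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTA or FASTQ, plain or gzipped."""
    import gzip as _gzip
    from pathlib import Path

    p = Path(path)
    opener = _gzip.open if p.suffix == ".gz" else open
    stem = p.name[:-3] if p.suffix == ".gz" else p.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    from Bio import SeqIO

    with opener(p, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()
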