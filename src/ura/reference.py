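"""Build stage: representative selection, uniqueness index and unique-count windows.

The reference database is the precomputed artifact of the method. Each
species-level genome bin (SGB) is represented by one genome. Every
read-length substring of every representative is enumerated (step of one
base) and a substring is *unique* when its strand-canonical form occurs at
exactly one (genome, position) across the whole representative set. The
unique start positions of each genome are then partitioned, in genomic
order, into non-overlapping windows holding exactly ``W`` unique positions
(default 100). Window counts of uniquely-mapping sample reads are the raw
signal of the abundance estimator: every window has identical unique
capacity, so equally-abundant genomes produce equal expected per-window
counts regardless of genome length or uniqueness fraction.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from ._util import canonical, reverse_complement

logger = logging.getLogger(__name__)

# sentinel occurrence marking a substring seen at more than one location
_MULTI = (-1, -1)


@dataclass
class Genome:
    """A representative genome sequence over the alphabet {A,C,G,T,N}."""

    genome_id: str
    sequence: str
    genus: str = ""
    species_label: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SGBMetadata:
    """Per-SGB record used for representative selection."""

    sgb_id: str
    genus: str
    n_assemblies: int
    known_species: bool = False


@dataclass
class UniquenessIndex:
    """Sorted unique start positions per genome, at a fixed read length."""

    read_len: int
    positions: dict[str, list[int]]

    @property
    def total_unique(self) -> dict[str, int]:
        return {g: len(p) for g, p in self.positions.items()}


@dataclass
class UniqueWindow:
    """A group of exactly W consecutive unique start positions of one genome.

    ``span`` is the half-open genomic interval
    [first position, last position + read_len).
    """

    genome_id: str
    ordinal: int
    member_positions: list[int]
    span: tuple[int, int]


@dataclass
class ReferenceDB:
    """The build-stage artifact: genomes, uniqueness index and windows."""

    genomes: dict[str, Genome]
    index: UniquenessIndex
    windows: dict[str, list[UniqueWindow]]
    window_unique_count: int
    # lazily built exact-substring lookup (see ura.mapping.build_exact_index)
    _lookup: dict | None = field(default=None, repr=False, compare=False)

    @property
    def read_len(self) -> int:
        return self.index.read_len

    def window_counts_shape(self) -> dict[str, int]:
        return {g: len(w) for g, w in self.windows.items()}


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------

def select_sgb_representatives(
    metadata: Sequence[SGBMetadata], min_assemblies: int = 5
) -> set[str]:
    """Keep SGBs whose genus is unique in the set, or with enough assemblies.

    Small SGBs that share a genus with another SGB are assumed to be
    erroneous splits of a nearby larger bin and are dropped unless backed by
    at least ``min_assemblies`` assemblies.
    """
    seen: set[str] = set()
    for rec in metadata:
        if not rec.genus:
            raise ValueError(f"empty genus for SGB {rec.sgb_id!r}")
        if rec.sgb_id in seen:
            raise ValueError(f"duplicate sgb_id {rec.sgb_id!r}")
        seen.add(rec.sgb_id)
    genus_counts: dict[str, int] = {}
    for rec in metadata:
        genus_counts[rec.genus] = genus_counts.get(rec.genus, 0) + 1
    return {
        rec.sgb_id
        for rec in metadata
        if genus_counts[rec.genus] == 1 or rec.n_assemblies >= min_assemblies
    }


# ---------------------------------------------------------------------------
# MinHash sketching / Mash distance
# ---------------------------------------------------------------------------

@dataclass
class SketchSignature:
    """Bottom-``sketch_size`` MinHash sketch of canonical k-mer hashes."""

    k: int
    sketch_size: int
    hashes: list[int]


def _hash_kmer(kmer: str) -> int:
    return int.from_bytes(
        hashlib.blake2b(kmer.encode(), digest_size=8).digest(), "big"
    )


def sketch_genome(genome: Genome, k: int = 21, sketch_size: int = 1000) -> SketchSignature:
    """MinHash-sketch a genome: keep the smallest canonical k-mer hashes.

    K-mers containing ``N`` are excluded; a k-mer and its reverse complement
    hash identically (canonical form), so a genome and its reverse
    complement sketch identically.
    """
    if sketch_size <= 0:
        raise ValueError("sketch_size must be positive")
    seq = genome.sequence.upper()
    if len(seq) < k:
        raise ValueError(f"genome {genome.genome_id!r} shorter than k={k}")
    hashes: set[int] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        hashes.add(_hash_kmer(canonical(kmer)))
    bottom = sorted(hashes)[:sketch_size]
    return SketchSignature(k=k, sketch_size=sketch_size, hashes=bottom)


def mash_distance(a: SketchSignature, b: SketchSignature) -> float:
    """Mash distance D = -(1/k) ln(2J/(1+J)) from the merged-sketch Jaccard.

    J is estimated from the bottom-s union of the two sketches, the standard
    MinHash construction. J=0 is capped at distance 1.0; identical sketches
    give 0.0 exactly.
    """
    import math

    if a.k != b.k:
        raise ValueError(f"k-mer sizes differ: {a.k} != {b.k}")
    s = min(a.sketch_size, b.sketch_size, max(len(a.hashes), len(b.hashes)))
    if s == 0:
        return 1.0
    merged = sorted(set(a.hashes) | set(b.hashes))[:s]
    shared = sum(1 for h in merged if h in set(a.hashes) and h in set(b.hashes))
    j = shared / len(merged)
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    return min(1.0, -math.log(2.0 * j / (1.0 + j)) / a.k)


def validate_reference_set(
    genomes: Sequence[Genome],
    threshold: float = 0.05,
    k: int = 21,
    sketch_size: int = 1000,
) -> list[tuple[str, str, float]]:
    """Flag representative pairs closer than ``threshold`` Mash distance.

    Representatives too close to one another share most of their sequence,
    leaving too few unique reads for either; a distance of 0.05 between
    pairs is sufficient separation. Sub-threshold pairs are returned (and
    logged as warnings) rather than raised: the build may legitimately
    proceed with reduced sensitivity for those genomes.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes to validate")
    sketches = {g.genome_id: sketch_genome(g, k=k, sketch_size=sketch_size) for g in genomes}
    flagged = []
    ids = [g.genome_id for g in genomes]
    for i in range(len(ids)):
        for jdx in range(i + 1, len(ids)):
            d = mash_distance(sketches[ids[i]], sketches[ids[jdx]])
            if d < threshold:
                flagged.append((ids[i], ids[jdx], d))
                logger.warning(
                    "representatives %s and %s are close (Mash %.4f < %.4f)",
                    ids[i], ids[jdx], d, threshold,
                )
    return flagged


# ---------------------------------------------------------------------------
# potential-read enumeration and the uniqueness index
# ---------------------------------------------------------------------------

def enumerate_potential_reads(
    genome: Genome, read_len: int
) -> Iterator[tuple[int, str]]:
    """Yield every read-length substring with a one-base step.

    Positions run 0 .. len-read_len inclusive; substrings containing ``N``
    are skipped but the coordinate system is unaffected.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    seq = genome.sequence
    if read_len > len(seq):
        raise ValueError(
            f"read_len {read_len} exceeds genome {genome.genome_id!r} length {len(seq)}"
        )
    for pos in range(len(seq) - read_len + 1):
        read = seq[pos : pos + read_len]
        if "N" in read:
            continue
        yield pos, read


def _occurrence_map(
    genomes: Sequence[Genome], read_len: int
) -> dict[str, tuple[int, int]]:
    """Canonical substring -> single (genome index, position), or the multi
    sentinel when seen at more than one location."""
    occ: dict[str, tuple[int, int]] = {}
    for gi, genome in enumerate(genomes):
        seq = genome.sequence
        rc = reverse_complement(seq)
        n = len(seq)
        for pos in range(n - read_len + 1):
            fwd = seq[pos : pos + read_len]
            if "N" in fwd:
                continue
            rev = rc[n - pos - read_len : n - pos]
            key = fwd if fwd <= rev else rev
            if occ.setdefault(key, (gi, pos)) != (gi, pos):
                occ[key] = _MULTI
    return occ


def build_uniqueness_index(
    genomes: Sequence[Genome], read_len: int
) -> UniquenessIndex:
    """Record, per genome, the start positions of globally unique reads.

    A potential read is unique iff its canonical form occurs at exactly one
    (genome, position) over the whole representative set — a read occurring
    twice within one genome is non-unique, mirroring what a strand-agnostic
    aligner reports as a uniquely-mapping read.
    """
    if not genomes:
        raise ValueError("empty genome set")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id in reference set")
    occ = _occurrence_map(genomes, read_len)
    return _index_from_occurrence(occ, genomes, read_len)


def _index_from_occurrence(
    occ: dict[str, tuple[int, int]], genomes: Sequence[Genome], read_len: int
) -> UniquenessIndex:
    positions: dict[str, list[int]] = {g.genome_id: [] for g in genomes}
    for (gi, pos) in occ.values():
        if gi >= 0:
            positions[genomes[gi].genome_id].append(pos)
    for plist in positions.values():
        plist.sort()
    return UniquenessIndex(read_len=read_len, positions=positions)


def build_unique_windows(
    index: UniquenessIndex, window_unique_count: int = 100
) -> dict[str, list[UniqueWindow]]:
    """Partition each genome's unique positions into groups of exactly W.

    Consecutive groups in genomic order; a trailing group with fewer than W
    positions is discarded so that every window has identical unique
    capacity (the per-window count comparability the estimator relies on).
    """
    if window_unique_count < 1:
        raise ValueError("window_unique_count must be >= 1")
    w = window_unique_count
    out: dict[str, list[UniqueWindow]] = {}
    for genome_id, plist in index.positions.items():
        windows = []
        for ordinal in range(len(plist) // w):
            members = plist[ordinal * w : (ordinal + 1) * w]
            windows.append(
                UniqueWindow(
                    genome_id=genome_id,
                    ordinal=ordinal,
                    member_positions=members,
                    span=(members[0], members[-1] + index.read_len),
                )
            )
        out[genome_id] = windows
    return out


def build_database(
    genomes: Sequence[Genome],
    read_len: int = 100,
    window_unique_count: int = 100,
    metadata: Sequence[SGBMetadata] | None = None,
    min_assemblies: int = 5,
    mash_check: bool = False,
    mash_threshold: float = 0.05,
) -> ReferenceDB:
    """Run the full build stage and return the reference database.

    When ``metadata`` is given, genomes are first filtered by the
    representative-selection rule (unique genus or >= min_assemblies).
    """
    genomes = list(genomes)
    if metadata is not None:
        kept = select_sgb_representatives(metadata, min_assemblies=min_assemblies)
        genomes = [g for g in genomes if g.genome_id in kept]
    if not genomes:
        raise ValueError("no genomes left to build a database from")
    if mash_check and len(genomes) >= 2:
        validate_reference_set(genomes, threshold=mash_threshold)
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id in reference set")
    occ = _occurrence_map(genomes, read_len)
    index = _index_from_occurrence(occ, genomes, read_len)
    windows = build_unique_windows(index, window_unique_count)
    return ReferenceDB(
        genomes={g.genome_id: g for g in genomes},
        index=index,
        windows=windows,
        window_unique_count=window_unique_count,
        _lookup=occ,  # doubles as the exact-mapper lookup
    )


# ---------------------------------------------------------------------------
# on-disk artifact
# ---------------------------------------------------------------------------

def save_database(db: ReferenceDB, out_dir: str | Path) -> None:
    """Write the DB directory: manifest.json, per-genome unique positions
    (gzipped text, one integer per line), windows.tsv and genomes.fasta."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "read_len": db.read_len,
        "window_unique_count": db.window_unique_count,
        "genomes": {
            gid: {
                "length": len(g.sequence),
                "sha1": hashlib.sha1(g.sequence.encode()).hexdigest(),
                "genus": g.genus,
                "species_label": g.species_label,
            }
            for gid, g in db.genomes.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    with open(out / "genomes.fasta", "w") as fh:
        for gid, g in db.genomes.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(g.sequence), 80):
                fh.write(g.sequence[i : i + 80] + "\n")
    pos_dir = out / "unique_positions"
    pos_dir.mkdir(exist_ok=True)
    for gid, plist in db.index.positions.items():
        with gzip.open(pos_dir / f"{gid}.txt.gz", "wt") as fh:
            fh.write("\n".join(map(str, plist)))
    with open(out / "windows.tsv", "w") as fh:
        fh.write("genome_id\tordinal\tstart\tend\tfirst_pos\tlast_pos\n")
        for gid, wins in db.windows.items():
            for w in wins:
                fh.write(
                    f"{gid}\t{w.ordinal}\t{w.span[0]}\t{w.span[1]}"
                    f"\t{w.member_positions[0]}\t{w.member_positions[-1]}\n"
                )


def load_database(db_dir: str | Path) -> ReferenceDB:
    """Load a DB directory written by :func:`save_database`."""
    from Bio import SeqIO

    db_dir = Path(db_dir)
    manifest = json.loads((db_dir / "manifest.json").read_text())
    genomes: dict[str, Genome] = {}
    for rec in SeqIO.parse(str(db_dir / "genomes.fasta"), "fasta"):
        meta = manifest["genomes"][rec.id]
        genomes[rec.id] = Genome(
            genome_id=rec.id,
            sequence=str(rec.seq).upper(),
            genus=meta.get("genus", ""),
            species_label=meta.get("species_label", ""),
        )
    positions: dict[str, list[int]] = {}
    for gid in genomes:
        with gzip.open(db_dir / "unique_positions" / f"{gid}.txt.gz", "rt") as fh:
            text = fh.read().strip()
        positions[gid] = [int(x) for x in text.split("\n")] if text else []
    index = UniquenessIndex(read_len=manifest["read_len"], positions=positions)
    windows = build_unique_windows(index, manifest["window_unique_count"])
    return ReferenceDB(
        genomes=genomes,
        index=index,
        windows=windows,
        window_unique_count=manifest["window_unique_count"],
    )


def read_genomes_fasta(path: str | Path, meta: dict[str, SGBMetadata] | None = None) -> list[Genome]:
    """Read representatives from a (multi-)FASTA file."""
    from Bio import SeqIO

    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genus = meta[rec.id].genus if meta and rec.id in meta else ""
        genomes.append(Genome(genome_id=rec.id, sequence=str(rec.seq).upper(), genus=genus))
    return genomes


def read_metadata_tsv(path: str | Path) -> list[SGBMetadata]:
    """Read the sgb_id/genus/n_assemblies/known_species metadata table."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"sgb_id": str, "genus": str})
    records = []
    for _, row in df.iterrows():
        records.append(
            SGBMetadata(
                sgb_id=str(row["sgb_id"]),
                genus=str(row["genus"]),
                n_assemblies=int(row["n_assemblies"]),
                known_species=bool(row.get("known_species", False)),
            )
        )
    return records
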