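"""Synthetic communities with known ground truth.

Generates representative genomes (optionally with shared segments that
defeat uniqueness), strain-level perturbations of them (deletions, copy
number variation, SNPs), error-free fixed-length reads under specified
copy-number abundances, and phenotype tables that are noisy linear
functions of log abundances. Every downstream module is testable against
these known truths without any external data.

Abundance semantics match the estimator's: "abundance" is genome copy
number, so a genome's expected read share is abundance x strain length,
normalized over the community.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import reverse_complement
from .reference import Genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SharedSegment:
    """Copy ``length`` bases from ``source`` into ``target`` (both genome ids)."""

    source: str
    target: str
    length: int
    count: int = 1


@dataclass
class CommunitySpec:
    """Recipe for a synthetic community with known truth.

    Defaults describe the standard benchmark community: 20 genomes of
    50 kb, flat-Dirichlet copy-number abundances, 2M error-free 100 bp
    reads.
    """

    n_genomes: int = 20
    genome_length: int = 50_000
    read_len: int = 100
    n_reads: int = 2_000_000
    shared_segments: list[SharedSegment] = field(default_factory=list)
    abundances: np.ndarray | None = None  # None -> Dirichlet(1) at sampling time
    seed: int = 0

    def genome_ids(self) -> list[str]:
        return [f"G{i:03d}" for i in range(self.n_genomes)]


@dataclass
class StrainPerturbation:
    """Differences between a sampled strain and its reference representative.

    ``deletion_fraction`` of the genome is removed in ``n_deletion_blocks``
    equal contiguous blocks at random locations; ``cnv_blocks`` are
    (start, length, multiplier) tandem repeats; ``snp_rate`` substitutes
    bases independently per bp.
    """

    deletion_fraction: float = 0.0
    n_deletion_blocks: int = 4
    cnv_blocks: list[tuple[int, int, int]] = field(default_factory=list)
    snp_rate: float = 0.0


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def generate_reference_genomes(spec: CommunitySpec, seed: int | None = None) -> list[Genome]:
    """I.i.d. uniform ACGT genomes, with the shared-segment plan applied.

    Shared segments are copied verbatim from source to target at random
    (seeded) locations, creating regions where read-length substrings occur
    in two genomes and are therefore non-unique.
    """
    if spec.n_genomes < 1:
        raise ValueError("need at least one genome")
    if spec.genome_length < spec.read_len:
        raise ValueError("genome_length must be >= read_len")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ids = spec.genome_ids()
    seqs = {gid: _random_sequence(rng, spec.genome_length) for gid in ids}
    for seg in spec.shared_segments:
        if seg.source not in seqs or seg.target not in seqs:
            raise ValueError(f"shared segment references unknown genome: {seg}")
        if seg.length > len(seqs[seg.source]) or seg.length > len(seqs[seg.target]):
            raise ValueError(f"shared segment longer than genome: {seg}")
        for _ in range(seg.count):
            src_start = int(rng.integers(0, len(seqs[seg.source]) - seg.length + 1))
            block = seqs[seg.source][src_start : src_start + seg.length]
            dst_start = int(rng.integers(0, len(seqs[seg.target]) - seg.length + 1))
            s = seqs[seg.target]
            seqs[seg.target] = s[:dst_start] + block + s[dst_start + seg.length :]
    return [Genome(genome_id=gid, sequence=seqs[gid], genus=f"genus_{gid}") for gid in ids]


def mutate_strain(genome: Genome, perturbation: StrainPerturbation, seed: int = 0) -> Genome:
    """Derive the strain actually present in a sample from its representative."""
    rng = np.random.default_rng(seed)
    seq = genome.sequence
    p = perturbation
    if not (0 <= p.deletion_fraction < 1):
        raise ValueError("deletion_fraction must be in [0, 1)")
    if p.snp_rate < 0:
        raise ValueError("snp_rate must be >= 0")

    intervals: list[tuple[int, int]] = []  # (start, end) half-open, to delete
    if p.deletion_fraction > 0:
        block = int(round(len(seq) * p.deletion_fraction / p.n_deletion_blocks))
        attempts = 0
        while len(intervals) < p.n_deletion_blocks:
            attempts += 1
            if attempts > 1000:
                raise ValueError("could not place non-overlapping deletion blocks")
            start = int(rng.integers(0, len(seq) - block + 1))
            cand = (start, start + block)
            if all(cand[1] <= s or cand[0] >= e for s, e in intervals):
                intervals.append(cand)
    for start, length, _mult in p.cnv_blocks:
        if start < 0 or start + length > len(seq):
            raise ValueError("CNV block outside genome bounds")
        cand = (start, start + length)
        if any(not (cand[1] <= s or cand[0] >= e) for s, e in intervals):
            raise ValueError("overlapping perturbation intervals")

    if p.snp_rate > 0:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hits = np.flatnonzero(rng.random(len(arr)) < p.snp_rate)
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
        seq = arr.tobytes().decode()

    # apply CNV (tandem repeats) and deletions right-to-left so earlier
    # coordinates stay valid
    edits: list[tuple[int, int, int]] = [(s, e, 0) for s, e in intervals]
    edits += [(s, s + l, m) for s, l, m in p.cnv_blocks]
    for s, e, mult in sorted(edits, reverse=True):
        seq = seq[:s] + seq[s:e] * mult + seq[e:]
    return Genome(
        genome_id=genome.genome_id,
        sequence=seq,
        genus=genome.genus,
        species_label=genome.species_label,
    )


def simulate_community_reads(
    strains: Sequence[Genome],
    abundances: Sequence[float],
    n_reads: int,
    read_len: int,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw error-free fixed-length reads from a community of strains.

    Read origins are multinomial with per-genome weight abundance x strain
    length; start positions and strands are uniform. Returns the reads and
    a per-genome truth table (origin counts and the true copy-number
    abundances renormalized over the community).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    abund = np.asarray(abundances, dtype=float)
    if abund.size != len(strains) or (abund < 0).any() or abund.sum() <= 0:
        raise ValueError("abundances must be non-negative, one per strain, sum > 0")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(s.sequence) for s in strains], dtype=float)
    weights = abund * lengths
    probs = weights / weights.sum()
    counts = rng.multinomial(n_reads, probs)
    reads: list[tuple[str, str]] = []
    rid = 0
    for strain, c in zip(strains, counts):
        if c == 0:
            continue
        seq = strain.sequence
        rc = reverse_complement(seq)
        L = len(seq)
        starts = rng.integers(0, L - read_len + 1, size=c)
        strands = rng.integers(0, 2, size=c)
        for pos, rev in zip(starts, strands):
            if rev:
                p = L - pos - read_len
                reads.append((f"r{rid}", rc[p : p + read_len]))
            else:
                reads.append((f"r{rid}", seq[pos : pos + read_len]))
            rid += 1
    truth = pd.DataFrame(
        {
            "genome_id": [s.genome_id for s in strains],
            "true_abundance": abund / abund.sum(),
            "n_reads": counts,
        }
    )
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Write reads as FASTQ with uniform max quality (error-free model)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def generate_phenotype_table(
    abundance_matrix: pd.DataFrame,
    effects: dict[str, dict[str, float]],
    noise_sd: float = 1.0,
    seed: int = 0,
    log_floor: float = 1e-5,
) -> pd.DataFrame:
    """Phenotypes as noisy linear functions of log10 relative abundances.

    ``effects`` maps phenotype name -> {species_id: weight}; a phenotype
    with all-zero weights is pure noise (a null phenotype). The realized
    signal fraction (variance of the linear part over total) is attached as
    ``frame.attrs['signal_fraction']``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    log_ra = np.log10(np.maximum(abundance_matrix.to_numpy(dtype=float), log_floor))
    cols = list(abundance_matrix.columns)
    out = {}
    signal_frac = {}
    for name, weights in effects.items():
        missing = set(weights) - set(cols)
        if missing:
            raise ValueError(f"effect species not in abundance matrix: {sorted(missing)}")
        w = np.array([weights.get(c, 0.0) for c in cols])
        signal = log_ra @ w
        noise = rng.normal(0.0, noise_sd, size=len(abundance_matrix))
        out[name] = signal + noise
        total_var = np.var(signal + noise)
        signal_frac[name] = float(np.var(signal) / total_var) if total_var > 0 else 0.0
    frame = pd.DataFrame(out, index=abundance_matrix.index)
    frame.attrs["signal_fraction"] = signal_frac
    return frame


def simulate_community(
    spec: CommunitySpec,
    perturbation: StrainPerturbation | None = None,
    seed: int | None = None,
):
    """Convenience pipeline: genomes -> strains -> reads -> truth.

    Returns (reference genomes, strains, reads, truth table). Abundances
    come from the spec, or Dirichlet(1) when unspecified.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    genomes = generate_reference_genomes(spec, seed=seed)
    abund = spec.abundances
    if abund is None:
        abund = rng.dirichlet(np.ones(spec.n_genomes))
    strains = genomes
    if perturbation is not None:
        strains = [
            mutate_strain(g, perturbation, seed=seed + 1 + i)
            for i, g in enumerate(genomes)
        ]
    live = [i for i in range(len(strains)) if abund[i] > 0]
    reads, truth = simulate_community_reads(
        [strains[i] for i in live],
        [abund[i] for i in live],
        n_reads=spec.n_reads,
        read_len=spec.read_len,
        seed=seed + 997,
    )
    full_truth = pd.DataFrame(
        {
            "genome_id": [g.genome_id for g in genomes],
            "true_abundance": np.asarray(abund, dtype=float) / np.sum(abund),
        }
    ).merge(truth[["genome_id", "n_reads"]], on="genome_id", how="left")
    full_truth["n_reads"] = full_truth["n_reads"].fillna(0).astype(int)
    return genomes, strains, reads, full_truth
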