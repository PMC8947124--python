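"""Presence calling, dense-mean coverage and relative-abundance normalization.

Per genome and sample, the window-hit vector is converted to a coverage
estimate in three steps:

1. *Enlargement*: consecutive windows are summed in groups of k, with k
   chosen so the typical summed count is about 20 reads — low-abundance
   genomes need longer windows before their counts are informative. If
   fewer than six enlarged windows remain the genome is called absent.
2. *Dense mean*: the mean of the densest 50% of the summed-count
   distribution — the shortest contiguous run of ceil(N/2) sorted values.
   This is robust both to hot regions (plasmids, copy-number gains,
   horizontal transfer that escaped the uniqueness filter) and to cold
   regions (segments of the representative deleted in the sample's strain).
3. *Presence*: the genome is present iff the dense run excludes zero; its
   coverage is the dense mean divided by k (reads per unique-count window).

Relative abundances are coverages normalized over the genomes called
present, so they are proportional to genome copy number, not read share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mapping import (
    WindowCounts,
    count_window_hits,
    downsample_assignments,
    map_reads,
)
from .reference import ReferenceDB

logger = logging.getLogger(__name__)

#: summed counts are meant to land within [2/3, 3/2] of the target
TARGET_BAND = (2.0 / 3.0, 3.0 / 2.0)


@dataclass
class CoverageCall:
    genome_id: str
    present: bool
    k: int = 0                    # enlargement factor (windows summed)
    n_enlarged: int = 0
    dense_mean_summed: float = 0.0  # reads per enlarged window
    coverage: float = 0.0           # reads per unique-count window
    in_target_band: bool | None = None


@dataclass
class AbundanceProfile:
    sample_id: str
    abundances: dict[str, float]
    calls: dict[str, CoverageCall] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not any(v > 0 for v in self.abundances.values())


def choose_enlargement_factor(
    counts: np.ndarray, target: float = 20.0
) -> tuple[int, int] | None:
    """Pick k so that k * (mean window count) is closest to ``target``.

    The mean is over all windows, zeros included (zero windows carry
    absence information; strain deletions are discounted later by the dense
    mean). Returns (k, number of enlarged windows), or None — the genome is
    absent — when the mean is zero or when at most five enlarged windows
    would remain.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count vector")
    if (counts < 0).any():
        raise ValueError("negative window counts")
    m = counts.mean()
    if m == 0:
        return None
    # |k*m - target| is minimized at one of the two integers around target/m
    k_lo = max(1, int(np.floor(target / m)))
    k = min((k_lo, k_lo + 1), key=lambda kk: (abs(kk * m - target), kk))
    n_enlarged = counts.size // k
    if n_enlarged <= 5:
        return None
    return k, n_enlarged


def sum_enlarged_windows(counts: np.ndarray, k: int) -> np.ndarray:
    """Sum consecutive groups of k windows; the trailing remainder is dropped."""
    counts = np.asarray(counts)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > counts.size:
        raise ValueError(f"k={k} exceeds window count {counts.size}")
    n = counts.size // k
    return counts[: n * k].reshape(n, k).sum(axis=1)


def dense_mean(
    values: np.ndarray, fraction: float = 0.5
) -> tuple[float, float, float]:
    """Mean of the densest ``fraction`` of a distribution.

    Sort ascending and take, among all contiguous runs of c =
    ceil(fraction*N) values, the one with the smallest (max - min); ties go
    to the run containing the lower median, then to the leftmost. Returns
    (mean, run minimum, run maximum). The run minimum doubles as the
    presence signal: a run that includes zero means the modal coverage
    state of the genome is "no reads".
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    s = np.sort(values)
    n = s.size
    c = int(np.ceil(fraction * n))
    ranges = s[c - 1 :] - s[: n - c + 1]
    best = ranges.min()
    starts = np.flatnonzero(ranges == best)
    if starts.size > 1:
        med_idx = (n - 1) // 2
        containing = starts[(starts <= med_idx) & (med_idx <= starts + c - 1)]
        start = int(containing[0]) if containing.size else int(starts[0])
    else:
        start = int(starts[0])
    run = s[start : start + c]
    return float(run.mean()), float(run[0]), float(run[-1])


def call_presence_and_coverage(
    counts: np.ndarray,
    target: float = 20.0,
    fraction: float = 0.5,
    genome_id: str = "",
) -> CoverageCall:
    """Full per-genome call: enlargement, dense mean, presence, coverage."""
    counts = np.asarray(counts)
    if counts.size == 0:
        return CoverageCall(genome_id=genome_id, present=False)
    choice = choose_enlargement_factor(counts, target=target)
    if choice is None:
        return CoverageCall(genome_id=genome_id, present=False)
    k, n_enlarged = choice
    summed = sum_enlarged_windows(counts, k)
    mean, run_min, _run_max = dense_mean(summed, fraction=fraction)
    present = run_min > 0
    band_lo, band_hi = TARGET_BAND[0] * target, TARGET_BAND[1] * target
    return CoverageCall(
        genome_id=genome_id,
        present=present,
        k=k,
        n_enlarged=n_enlarged,
        dense_mean_summed=mean if present else 0.0,
        coverage=mean / k if present else 0.0,
        in_target_band=band_lo <= k * counts.mean() <= band_hi,
    )


def normalize_relative_abundance(
    calls: list[CoverageCall], sample_id: str = "sample"
) -> AbundanceProfile:
    """Coverage of each present genome divided by the summed present coverage.

    Absent genomes get exactly 0. When nothing is present the profile is
    empty and a warning is logged.
    """
    if not calls:
        raise ValueError("no coverage calls")
    total = sum(c.coverage for c in calls if c.present)
    abundances: dict[str, float] = {}
    for c in calls:
        abundances[c.genome_id] = c.coverage / total if (c.present and total > 0) else 0.0
    if total == 0:
        logger.warning("sample %s: no genome called present; empty profile", sample_id)
    return AbundanceProfile(
        sample_id=sample_id,
        abundances=abundances,
        calls={c.genome_id: c for c in calls},
    )


def profile_from_counts(
    window_counts: WindowCounts,
    sample_id: str = "sample",
    target: float = 20.0,
    fraction: float = 0.5,
) -> AbundanceProfile:
    calls = []
    for gid, counts in window_counts.counts.items():
        calls.append(
            call_presence_and_coverage(counts, target=target, fraction=fraction, genome_id=gid)
        )
    return normalize_relative_abundance(calls, sample_id=sample_id)


def profile_sample(
    db: ReferenceDB,
    reads=None,
    sam_path=None,
    sample_id: str = "sample",
    depth: int = 8_000_000,
    seed: int = 0,
    target: float = 20.0,
    fraction: float = 0.5,
) -> AbundanceProfile:
    """End-to-end estimation: map -> downsample -> count -> call -> normalize.

    ``reads`` is an iterable of (read_id, sequence); alternatively
    ``sam_path`` imports external alignments. Deterministic given ``seed``.
    """
    if (reads is None) == (sam_path is None):
        raise ValueError("provide exactly one of reads or sam_path")
    if sam_path is not None:
        from .mapping import import_sam_assignments

        assignments = import_sam_assignments(sam_path, db)
    else:
        assignments = map_reads(reads, db)
    assignments = downsample_assignments(assignments, depth=depth, seed=seed)
    wc = count_window_hits(assignments, db)
    profile = profile_from_counts(wc, sample_id=sample_id, target=target, fraction=fraction)
    profile.provenance = {
        "depth": depth,
        "seed": seed,
        "target": target,
        "fraction": fraction,
        "read_len": db.read_len,
        "mapped_reads_used": len(assignments),
    }
    return profile


def profile_to_frame(profile: AbundanceProfile):
    """One row per genome: presence, enlargement, coverage and abundance."""
    import pandas as pd

    rows = []
    for gid, ra in profile.abundances.items():
        c = profile.calls.get(gid, CoverageCall(genome_id=gid, present=False))
        rows.append(
            {
                "sample_id": profile.sample_id,
                "genome_id": gid,
                "present": c.present,
                "k": c.k,
                "n_enlarged": c.n_enlarged,
                "dense_mean": c.dense_mean_summed,
                "coverage": c.coverage,
                "relative_abundance": ra,
            }
        )
    return pd.DataFrame(rows)
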