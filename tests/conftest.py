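"""Shared fixtures: small synthetic communities and independent oracles."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from ura import (
    CommunitySpec,
    SharedSegment,
    build_database,
    generate_reference_genomes,
    simulate_community_reads,
)


def brute_force_unique_positions(genomes, read_len):
    """Independent uniqueness oracle: count canonical substring occurrences
    with Biopython's reverse complement and a Counter, then keep positions
    whose substring was seen exactly once anywhere."""
    from Bio.Seq import Seq

    counter = Counter()
    keys = {}
    for g in genomes:
        for pos in range(len(g.sequence) - read_len + 1):
            sub = g.sequence[pos : pos + read_len]
            if "N" in sub:
                continue
            rc = str(Seq(sub).reverse_complement())
            key = min(sub, rc)
            counter[key] += 1
            keys[(g.genome_id, pos)] = key
    out = {g.genome_id: [] for g in genomes}
    for (gid, pos), key in keys.items():
        if counter[key] == 1:
            out[gid].append(pos)
    for v in out.values():
        v.sort()
    return out


def dense_mean_oracle(values, fraction=0.5):
    """Exhaustive search over all contiguous sorted runs, with the
    documented tie-break (lower-median containment, then leftmost)."""
    s = sorted(float(v) for v in values)
    n = len(s)
    c = math.ceil(fraction * n)
    runs = [(s[i + c - 1] - s[i], i) for i in range(n - c + 1)]
    best = min(r for r, _ in runs)
    starts = [i for r, i in runs if r == best]
    med_idx = (n - 1) // 2
    containing = [i for i in starts if i <= med_idx <= i + c - 1]
    start = containing[0] if containing else starts[0]
    run = s[start : start + c]
    return sum(run) / c, run[0], run[-1]


@pytest.fixture(scope="session")
def small_community():
    """Four 4 kb genomes, one shared 500 bp block, 60 bp reads."""
    spec = CommunitySpec(
        n_genomes=4,
        genome_length=4000,
        read_len=60,
        n_reads=40_000,
        shared_segments=[SharedSegment(source="G000", target="G001", length=500)],
        seed=11,
    )
    genomes = generate_reference_genomes(spec)
    return spec, genomes


@pytest.fixture(scope="session")
def small_db(small_community):
    spec, genomes = small_community
    return build_database(genomes, read_len=spec.read_len, window_unique_count=50)


@pytest.fixture(scope="session")
def small_sample(small_community):
    """Reads drawn from the small community at fixed abundances."""
    spec, genomes = small_community
    abundances = np.array([0.4, 0.3, 0.2, 0.1])
    reads, truth = simulate_community_reads(
        genomes, abundances, n_reads=spec.n_reads, read_len=spec.read_len, seed=23
    )
    return reads, truth
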