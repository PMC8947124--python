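"""Standard simulation benchmarks for the profiling pipeline.

These protocols define the package's reference evaluation conditions:

* *recovery*: a 20-genome community of 50 kb genomes, flat-Dirichlet
  copy-number abundances over 18 genomes with 2 held at zero, 2M
  error-free 100 bp reads; measures abundance recovery and the
  presence/absence confusion.
* *deletion robustness*: the same community with 20% of every strain
  deleted in blocks, testing that the dense mean discounts cold windows.
* *CNV robustness*: one strain carries a 10x tandem amplification covering
  5% of its genome; measures how much the hot region inflates its
  estimated coverage relative to equally-abundant neighbours.
* *atlas calibration*: null and planted-effect phenotypes over synthetic
  abundance matrices; measures the BH-FDR false-positive rate and the
  sign-recovery rate of real effects.

All functions are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import profile_sample
from .reference import ReferenceDB, build_database
from .simulate import (
    CommunitySpec,
    StrainPerturbation,
    generate_phenotype_table,
    generate_reference_genomes,
    mutate_strain,
    simulate_community_reads,
)


@dataclass
class RecoveryResult:
    pearson_r: float
    spearman_r: float
    n_true_present: int
    n_called_present_correct: int
    n_true_absent: int
    n_called_absent_correct: int
    truth: pd.DataFrame
    estimated: dict[str, float]


def _community_abundances(n_genomes: int, n_zero: int, rng: np.random.Generator) -> np.ndarray:
    """Flat-Dirichlet abundances with ``n_zero`` genomes held at exactly 0."""
    abund = np.zeros(n_genomes)
    live = rng.choice(n_genomes, size=n_genomes - n_zero, replace=False)
    abund[live] = rng.dirichlet(np.ones(n_genomes - n_zero))
    return abund


def build_benchmark_db(
    seed: int,
    n_genomes: int = 20,
    genome_length: int = 50_000,
    read_len: int = 100,
    window_unique_count: int = 100,
):
    spec = CommunitySpec(
        n_genomes=n_genomes, genome_length=genome_length, read_len=read_len, seed=seed
    )
    genomes = generate_reference_genomes(spec)
    db = build_database(genomes, read_len=read_len, window_unique_count=window_unique_count)
    return genomes, db


def _score_recovery(db: ReferenceDB, genomes, strains, abund, n_reads, read_len, seed):
    live = [i for i in range(len(strains)) if abund[i] > 0]
    reads, _ = simulate_community_reads(
        [strains[i] for i in live], [abund[i] for i in live],
        n_reads=n_reads, read_len=read_len, seed=seed,
    )
    prof = profile_sample(db, reads=reads, depth=n_reads, seed=seed + 1)
    true = abund / abund.sum()
    est = np.array([prof.abundances[g.genome_id] for g in genomes])
    present_true = true > 0
    called_present = np.array([prof.calls[g.genome_id].present for g in genomes])
    return RecoveryResult(
        pearson_r=float(np.corrcoef(true, est)[0, 1]),
        spearman_r=float(stats.spearmanr(true, est).statistic),
        n_true_present=int(present_true.sum()),
        n_called_present_correct=int((called_present & present_true).sum()),
        n_true_absent=int((~present_true).sum()),
        n_called_absent_correct=int((~called_present & ~present_true).sum()),
        truth=pd.DataFrame({"genome_id": [g.genome_id for g in genomes],
                            "true_abundance": true}),
        estimated=dict(prof.abundances),
    )


def recovery_experiment(
    seed: int,
    n_genomes: int = 20,
    genome_length: int = 50_000,
    read_len: int = 100,
    n_reads: int = 2_000_000,
    n_zero: int = 2,
    deletion_fraction: float = 0.0,
    db=None,
    genomes=None,
) -> RecoveryResult:
    """Abundance recovery on the standard community, optionally with
    strain-level deletions applied to every genome."""
    rng = np.random.default_rng(seed)
    if db is None:
        genomes, db = build_benchmark_db(
            seed, n_genomes=n_genomes, genome_length=genome_length, read_len=read_len
        )
    abund = _community_abundances(n_genomes, n_zero, rng)
    strains = genomes
    if deletion_fraction > 0:
        pert = StrainPerturbation(deletion_fraction=deletion_fraction)
        strains = [mutate_strain(g, pert, seed=seed + 11 + i) for i, g in enumerate(genomes)]
    return _score_recovery(db, genomes, strains, abund, n_reads, read_len, seed + 23)


def cnv_inflation_experiment(
    seeds,
    n_genomes: int = 4,
    genome_length: int = 20_000,
    read_len: int = 100,
    n_reads: int = 200_000,
    cnv_fraction: float = 0.05,
    cnv_multiplier: int = 10,
    build_seed: int = 101,
) -> list[float]:
    """Relative coverage inflation of one CNV-carrying genome, per seed.

    All genomes share equal true copy-number abundance; genome 0 carries a
    tandem amplification (``cnv_multiplier`` copies of a block covering
    ``cnv_fraction`` of its genome). Inflation is its coverage over the
    median coverage of the others, minus 1.
    """
    genomes, db = build_benchmark_db(
        build_seed, n_genomes=n_genomes, genome_length=genome_length, read_len=read_len
    )
    block_len = int(genome_length * cnv_fraction)
    inflations = []
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        start = int(rng.integers(0, genome_length - block_len))
        pert = StrainPerturbation(cnv_blocks=[(start, block_len, cnv_multiplier)])
        strains = [mutate_strain(genomes[0], pert, seed=int(seed))] + list(genomes[1:])
        reads, _ = simulate_community_reads(
            strains, np.full(n_genomes, 1.0 / n_genomes),
            n_reads=n_reads, read_len=read_len, seed=int(seed) + 7,
        )
        prof = profile_sample(db, reads=reads, depth=n_reads, seed=int(seed) + 13)
        cov = {g.genome_id: prof.calls[g.genome_id].coverage for g in genomes}
        others = np.median([cov[g.genome_id] for g in genomes[1:]])
        inflations.append(cov[genomes[0].genome_id] / others - 1.0)
    return inflations


def atlas_calibration_experiment(
    seed: int,
    n_null_seeds: int = 20,
    n_effect_seeds: int = 50,
    n_samples: int = 500,
    n_species: int = 40,
    effect_weight: float = 1.0,
    noise_sd: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """Null calibration and planted-effect recovery of the correlation atlas.

    Null phenotypes (zero weights) should leave about ``alpha`` of species
    below q < alpha; a single planted effect of ``effect_weight`` on
    log10-abundance should be re-detected with the correct sign. Also runs
    a two-species opposite-sign design and reports how often both signs
    are recovered.
    """
    from .atlas import log_transform, spearman_atlas

    root = np.random.default_rng(seed)

    def matrix(rng):
        raw = rng.dirichlet(np.ones(n_species), size=n_samples)
        return pd.DataFrame(raw, index=[f"s{i}" for i in range(n_samples)],
                            columns=[f"sp{i}" for i in range(n_species)])

    null_flags = []
    for i in range(n_null_seeds):
        sub = int(root.integers(2**31))
        mat = matrix(np.random.default_rng(sub))
        pheno = generate_phenotype_table(mat, {"null": {}}, noise_sd=noise_sd, seed=sub + 1)
        rec = spearman_atlas(log_transform(mat), pheno)
        null_flags.extend((rec["q_value"] < alpha).tolist())
    null_rate = float(np.mean(null_flags))

    sign_ok = 0
    both_signs_ok = 0
    for i in range(n_effect_seeds):
        sub = int(root.integers(2**31))
        mat = matrix(np.random.default_rng(sub))
        pheno = generate_phenotype_table(
            mat,
            {"single": {"sp0": effect_weight},
             "opposed": {"sp1": effect_weight, "sp2": -effect_weight}},
            noise_sd=noise_sd, seed=sub + 1,
        )
        rec = spearman_atlas(log_transform(mat), pheno).set_index(["phenotype", "species_id"])
        hit = rec.loc[("single", "sp0")]
        if hit["q_value"] < alpha and np.sign(hit["spearman_rho"]) == np.sign(effect_weight):
            sign_ok += 1
        up, dn = rec.loc[("opposed", "sp1")], rec.loc[("opposed", "sp2")]
        if up["spearman_rho"] > 0 > dn["spearman_rho"]:
            both_signs_ok += 1
    return {
        "null_positive_rate": null_rate,
        "n_null_tests": len(null_flags),
        "planted_sign_recovery_rate": sign_ok / n_effect_seeds,
        "opposed_signs_rate": both_signs_ok / n_effect_seeds,
        "n_effect_seeds": n_effect_seeds,
    }
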