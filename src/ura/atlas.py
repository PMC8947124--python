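"""Association statistics over abundance matrices.

Shannon alpha diversity and diversity-decile comparisons, running averages
along a phenotype, a species x phenotype correlation atlas (Spearman and
Pearson with Benjamini-Hochberg FDR within each phenotype family), KO
pseudo-abundances (copy-number-weighted sums of species abundances) and
module/pathway rank-sum enrichment.

Conventions: Shannon entropy is reported in bits (log base 2, configurable);
log abundances use a floor (default 1e-5) so absent species contribute a
finite value; FDR is Benjamini-Hochberg step-up; Mann-Whitney tests are
two-sided, exact for small groups and tie-corrected normal otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: switch to exact Mann-Whitney when both groups are at most this large
_EXACT_MAX_N = 20

ATLAS_COLUMNS = [
    "species_id", "phenotype", "n",
    "spearman_rho", "spearman_p", "pearson_r", "pearson_p", "q_value",
]


def shannon_diversity(row, base: float = 2.0) -> float:
    """Shannon index H = -sum p log p of one sample's abundances."""
    p = np.asarray(row, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance row")
    p = p / total
    p = p[p > 0]  # after normalization: entries may underflow to zero
    return float(-(p * (np.log(p) / np.log(base))).sum())


def alpha_diversity(matrix: pd.DataFrame, base: float = 2.0) -> pd.Series:
    """Per-sample Shannon diversity of a samples x species matrix."""
    return matrix.apply(lambda r: shannon_diversity(r.to_numpy(), base=base), axis=1).rename("shannon")


def log_transform(matrix: pd.DataFrame, floor: float = 1e-5) -> pd.DataFrame:
    """log10 abundances with a detection floor; floor recorded in attrs."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    out = np.log10(np.maximum(matrix.to_numpy(dtype=float), floor))
    res = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    res.attrs["log_floor"] = floor
    return res


def prevalence_filter(matrix: pd.DataFrame, min_fraction: float = 0.05) -> list:
    """Species detected (abundance > 0) in at least a fraction of samples."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    n = len(matrix)
    if n == 0:
        return []
    need = int(np.ceil(min_fraction * n))
    prev = (matrix > 0).sum(axis=0)
    return [s for s in matrix.columns if prev[s] >= need]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class AtlasRecord:
    species_id: str
    phenotype: str
    n: int
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    q_value: float


def spearman_atlas(
    log_matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    min_n: int = 3,
) -> pd.DataFrame:
    """Species x phenotype correlation atlas with per-phenotype BH-FDR.

    Spearman (average ranks on ties) and Pearson are computed on
    pairwise-complete observations per (species, phenotype). Species with
    zero variance over the complete samples get NaN statistics and are
    excluded from the FDR family. Returns a frame with ATLAS_COLUMNS;
    q_value applies to the Spearman p within each phenotype family.
    """
    common = log_matrix.index.intersection(phenotypes.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between matrix and phenotypes")
    X = log_matrix.loc[common]
    Y = phenotypes.loc[common]
    rows = []
    for pheno in Y.columns:
        y_all = Y[pheno].to_numpy(dtype=float)
        pheno_rows = []
        for sp in X.columns:
            x_all = X[sp].to_numpy(dtype=float)
            ok = ~(np.isnan(x_all) | np.isnan(y_all))
            x, y = x_all[ok], y_all[ok]
            n = int(ok.sum())
            if n < min_n or np.ptp(x) == 0 or np.ptp(y) == 0:
                pheno_rows.append((sp, pheno, n, np.nan, np.nan, np.nan, np.nan))
                continue
            rho, sp_p = stats.spearmanr(x, y)
            r, pe_p = stats.pearsonr(x, y)
            pheno_rows.append((sp, pheno, n, rho, sp_p, r, pe_p))
        ps = np.array([r[4] for r in pheno_rows], dtype=float)
        defined = ~np.isnan(ps)
        qs = np.full(ps.size, np.nan)
        if defined.any():
            qs[defined] = bh_fdr(ps[defined])
        for rec, q in zip(pheno_rows, qs):
            rows.append(rec + (q,))
    return pd.DataFrame(rows, columns=ATLAS_COLUMNS)


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # all values tied: no evidence either way
        return float(len(a) * len(b) / 2), 1.0
    method = "exact" if (len(a) <= _EXACT_MAX_N and len(b) <= _EXACT_MAX_N
                         and len(np.unique(pooled)) == len(a) + len(b)) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def decile_comparison(
    alpha: pd.Series, phenotypes: pd.DataFrame, n_bins: int = 10
) -> pd.DataFrame:
    """Compare phenotype values between the extreme alpha-diversity deciles.

    Samples are ranked by diversity (stable order breaks ties) and split
    into ``n_bins`` near-equal bins; per phenotype, a two-sided
    Mann-Whitney test contrasts the bottom and top bins, with BH-FDR
    across phenotypes.
    """
    common = alpha.index.intersection(phenotypes.index)
    if len(common) < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} samples")
    a = alpha.loc[common]
    order = np.argsort(a.to_numpy(), kind="stable")
    bins = np.array_split(order, n_bins)
    low, high = common[bins[0]], common[bins[-1]]
    rows = []
    for pheno in phenotypes.columns:
        lo = phenotypes.loc[low, pheno].dropna().to_numpy(dtype=float)
        hi = phenotypes.loc[high, pheno].dropna().to_numpy(dtype=float)
        u, p = _mannwhitney(lo, hi)
        rows.append({"phenotype": pheno, "n_low": len(lo), "n_high": len(hi),
                     "U": u, "p_value": p})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out


def running_average(
    phenotype: pd.Series, alpha: pd.Series, window: int, shift: int
) -> pd.DataFrame:
    """Windowed means of (phenotype, alpha) ordered by the phenotype.

    Samples are sorted by phenotype value; consecutive windows of size
    ``window`` advance by ``shift``; a final partial window is dropped.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if shift < 1:
        raise ValueError("shift must be >= 1")
    common = phenotype.index.intersection(alpha.index)
    x = phenotype.loc[common].to_numpy(dtype=float)
    y = alpha.loc[common].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if window > x.size:
        raise ValueError("window larger than sample count")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    rows = []
    for start in range(0, x.size - window + 1, shift):
        rows.append({"phenotype_mean": x[start : start + window].mean(),
                     "alpha_mean": y[start : start + window].mean()})
    return pd.DataFrame(rows)


def ko_pseudoabundance(
    abundance_matrix: pd.DataFrame,
    ko_table: pd.DataFrame,
    min_total_copies: int = 5,
    weight_by_copies: bool = True,
) -> pd.DataFrame:
    """Per-sample functional (KO) abundances from species abundances.

    ``ko_table`` is species x KO copy numbers. The default weights each
    species' abundance by its KO copy number; ``weight_by_copies=False``
    instead sums the abundances of the species carrying the KO at all
    (presence-sum variant). KOs with fewer than ``min_total_copies`` total
    copies across representatives are excluded: those seen in only a few
    genomes add nothing beyond single-species abundances.
    """
    shared = [s for s in abundance_matrix.columns if s in ko_table.index]
    if not shared:
        raise ValueError("no species shared between abundance matrix and KO table")
    copies = ko_table.loc[shared]
    keep = copies.columns[ko_table.sum(axis=0) >= min_total_copies]
    copies = copies[keep]
    weights = copies.to_numpy(dtype=float) if weight_by_copies else (
        copies.to_numpy(dtype=float) > 0
    ).astype(float)
    values = abundance_matrix[shared].to_numpy(dtype=float) @ weights
    return pd.DataFrame(values, index=abundance_matrix.index, columns=keep)


def ranksum_enrichment(
    ko_scores: pd.Series, membership: dict[str, list[str]]
) -> pd.DataFrame:
    """Rank-sum enrichment of KO sets (modules or pathways).

    ``ko_scores`` assigns each tested KO a signed association score (e.g.
    its Spearman rho with a phenotype); member KOs' scores are compared to
    all non-member scores with a two-sided Mann-Whitney test, BH-FDR
    across the tested sets. ``direction`` is +1 when member KOs rank above
    the background median, -1 below.
    """
    scores = ko_scores.dropna()
    rows = []
    for set_id, members in membership.items():
        inside = scores.index.intersection(members)
        outside = scores.index.difference(members)
        if len(inside) == 0 or len(outside) == 0:
            continue
        a = scores.loc[inside].to_numpy(dtype=float)
        b = scores.loc[outside].to_numpy(dtype=float)
        u, p = _mannwhitney(a, b)
        direction = 1 if np.median(a) > np.median(b) else -1
        rows.append({"set_id": set_id, "n_member": len(a), "n_background": len(b),
                     "U": u, "p_value": p, "direction": direction})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out
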