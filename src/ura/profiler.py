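"""Scikit-learn style estimator over the build + profile pipeline.

``URAProfiler`` is a transformer: ``fit`` builds the reference database
(uniqueness index and unique-count windows) from representative genomes;
``transform`` turns per-sample read sets into a samples x species
relative-abundance matrix. It composes with sklearn pipelines and
``clone``/``get_params``/``set_params`` as usual; the heavy lifting lives
in :mod:`ura.reference`, :mod:`ura.mapping` and :mod:`ura.estimation`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .estimation import AbundanceProfile, profile_sample
from .reference import Genome, SGBMetadata, build_database


class URAProfiler(BaseEstimator, TransformerMixin):
    """Estimate species relative abundances from uniquely-mapping reads.

    Parameters
    ----------
    read_len : int, default=100
        Fixed sample read length in bp; the build enumerates reference
        substrings of this length with a one-base step.
    window_unique_count : int, default=100
        Number of unique positions per window (W). Windows vary in genomic
        span but hold identical unique capacity.
    target_reads : float, default=20.0
        Desired mean read count per enlarged window; the enlargement
        factor k minimizes |k * mean - target_reads|.
    dense_fraction : float, default=0.5
        Fraction of the summed-count distribution the dense mean covers.
    depth : int, default=8_000_000
        Mapped-read downsampling depth per sample.
    seed : int, default=0
        Seed for the downsampling RNG (per-sample seeds derive from it).
    min_assemblies : int, default=5
        Representative-selection threshold when metadata is supplied.

    Attributes
    ----------
    db_ : ReferenceDB
        The fitted reference database.
    species_ : list of str
        Genome ids, in database order; columns of ``transform`` output.

    Examples
    --------
    >>> prof = URAProfiler(read_len=50, depth=10_000)
    >>> prof.fit(genomes)                     # doctest: +SKIP
    >>> ra = prof.transform({"s1": reads})    # doctest: +SKIP
    """

    def __init__(
        self,
        read_len: int = 100,
        window_unique_count: int = 100,
        target_reads: float = 20.0,
        dense_fraction: float = 0.5,
        depth: int = 8_000_000,
        seed: int = 0,
        min_assemblies: int = 5,
    ):
        self.read_len = read_len
        self.window_unique_count = window_unique_count
        self.target_reads = target_reads
        self.dense_fraction = dense_fraction
        self.depth = depth
        self.seed = seed
        self.min_assemblies = min_assemblies

    def fit(self, X: Sequence[Genome], y=None, metadata: Sequence[SGBMetadata] | None = None):
        """Build the reference database from representative genomes."""
        if not X:
            raise ValueError("need at least one genome")
        self.db_ = build_database(
            X,
            read_len=self.read_len,
            window_unique_count=self.window_unique_count,
            metadata=metadata,
            min_assemblies=self.min_assemblies,
        )
        self.species_ = list(self.db_.genomes)
        return self

    def profile(self, reads: Iterable[tuple[str, str]], sample_id: str = "sample",
                seed: int | None = None) -> AbundanceProfile:
        """Profile a single sample of (read_id, sequence) pairs."""
        check_is_fitted(self, "db_")
        return profile_sample(
            self.db_,
            reads=reads,
            sample_id=sample_id,
            depth=self.depth,
            seed=self.seed if seed is None else seed,
            target=self.target_reads,
            fraction=self.dense_fraction,
        )

    def transform(self, X) -> pd.DataFrame:
        """Profile many samples into a samples x species abundance matrix.

        ``X`` is a mapping of sample_id -> iterable of (read_id, sequence),
        or a plain iterable of read sets (ids are generated). Rows of the
        returned frame sum to 1 over the species called present (all-absent
        samples are all-zero rows).
        """
        check_is_fitted(self, "db_")
        if not hasattr(X, "items"):
            X = {f"sample{i}": reads for i, reads in enumerate(X)}
        rows = []
        for i, (sample_id, reads) in enumerate(X.items()):
            prof = self.profile(reads, sample_id=sample_id, seed=self.seed + i)
            rows.append(pd.Series(prof.abundances, name=sample_id))
        return pd.DataFrame(rows, columns=self.species_).fillna(0.0)

    def fit_transform(self, X, y=None, **fit_params):  # X here is genomes; not meaningful
        raise NotImplementedError(
            "fit consumes reference genomes while transform consumes read sets; "
            "call fit(genomes) then transform(samples)"
        )
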