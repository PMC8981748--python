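"""Rank-based binary gene-pair features (the 0-or-1 matrix).

For an ordered gene pair (A, B) and sample s, C(A, B, s) = 1 iff
expression[A, s] > expression[B, s], else 0 (ties score 0). Because C
depends only on the within-sample ordering, the feature space is invariant
to any monotone per-sample transform of expression — the property that makes
pair signatures portable across platforms and normalisations.

Pairs whose indicator is nearly constant across samples carry no
between-sample information; the stability filter retains pairs with a C=1
frequency inside a symmetric window (20-80% by default, inclusive).
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, DataError

logger = logging.getLogger("pairrisk")

__all__ = ["build_pair_matrix", "stability_filter", "pair_frequencies", "PairTransformer"]


def _canonical_pairs(genes: list[str]) -> list[tuple[str, str]]:
    return list(combinations(sorted(genes), 2))


def build_pair_matrix(expr_values: pd.DataFrame, gene_set) -> pd.DataFrame:
    """Binary pair x sample matrix over all unordered pairs of ``gene_set``.

    ``expr_values`` is genes-in-rows x samples on any scale (the transform is
    rank-based). Pairs are in canonical orientation (lexicographically
    smaller gene first), one row per unordered pair, indexed "A|B".
    """
    genes = sorted(set(gene_set))
    if len(genes) < 2:
        raise ConfigError(f"need at least 2 genes to build pairs, got {len(genes)}")
    missing = [g for g in genes if g not in expr_values.index]
    if missing:
        raise DataError(f"genes missing from expression matrix: {missing}")
    sub = expr_values.loc[genes].to_numpy()
    ia, ib = np.triu_indices(len(genes), k=1)
    values = (sub[ia] > sub[ib]).astype(np.int8)
    index = pd.Index([f"{genes[i]}|{genes[j]}" for i, j in zip(ia, ib)], name="pair")
    return pd.DataFrame(values, index=index, columns=expr_values.columns)


def pair_frequencies(pm: pd.DataFrame) -> pd.Series:
    """Per-pair fraction of samples with C = 1."""
    return pm.mean(axis=1).rename("freq")


def stability_filter(
    pm: pd.DataFrame, lo: float = 0.20, hi: float = 0.80
) -> tuple[pd.DataFrame, pd.Series]:
    """Retain pairs whose C=1 frequency lies in [lo, hi] (inclusive).

    Returns ``(filtered_matrix, frequencies_of_all_input_pairs)``. Because a
    pair's reverse orientation has frequency 1 - freq (absent ties), the
    symmetric window makes the retained unordered pairs independent of the
    orientation convention.
    """
    if pm.shape[0] == 0:
        raise DataError("empty pair matrix")
    if lo >= hi:
        raise ConfigError(f"stability window requires lo < hi, got [{lo}, {hi}]")
    freq = pair_frequencies(pm)
    keep = (freq >= lo) & (freq <= hi)
    logger.info("stability filter: retained %d / %d pairs", int(keep.sum()), len(keep))
    return pm.loc[keep], freq


class PairTransformer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer from expression space to pair space.

    fit(X) decides which pairs to keep — all unordered pairs of the selected
    genes whose C=1 frequency on the training samples falls inside the
    stability window — and transform(X) emits the binary indicators for those
    pairs. X is samples x genes (sklearn orientation).

    Parameters
    ----------
    genes : subset of columns to pair; None = all columns.
    lo, hi : stability window bounds, inclusive.
    filter_stability : disable to keep every pair.
    """

    def __init__(self, genes=None, lo: float = 0.20, hi: float = 0.80, filter_stability: bool = True):
        self.genes = genes
        self.lo = lo
        self.hi = hi
        self.filter_stability = filter_stability

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise DataError("PairTransformer requires a samples x genes DataFrame")
        genes = list(X.columns) if self.genes is None else list(self.genes)
        pm = build_pair_matrix(X.T, genes)
        if self.filter_stability:
            pm, freq = stability_filter(pm, self.lo, self.hi)
        else:
            freq = pair_frequencies(pm)
        self.genes_ = sorted(set(genes))
        self.pairs_ = [tuple(p.split("|")) for p in pm.index]
        self.frequencies_ = freq
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "pairs_"):
            raise DataError("PairTransformer is not fitted")
        pm = build_pair_matrix(X.T, self.genes_)
        keys = [f"{a}|{b}" for a, b in self.pairs_]
        return pm.loc[keys].T

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray([f"{a}|{b}" for a, b in self.pairs_], dtype=object)
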