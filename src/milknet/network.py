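"""Signed Pearson correlation network inference.

Three network flavours are built on the same primitive:

* species interaction network (SIN) — all unordered OTU pairs within one
  treatment group;
* diversity–metabolite network (DMN) — per-sample Hill numbers at each
  order q treated as feature vectors, correlated against metabolites;
* metabolite–OTU network (MON) — cross correlations between the two
  tables.

An edge is kept when the two-sided Pearson p-value is <= alpha (0.05 by
default, uncorrected — this is the study design being reproduced; a
Benjamini–Hochberg option is available for users who want error-rate
control). Edge sign is the sign of r. Correlations are computed on the
abundances as given; no compositional transformation is applied, which is
a known caveat of Pearson-based co-occurrence inference on relative data.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .diversity import DEFAULT_Q_GRID, profiles_from_table
from .io_tables import FeatureTable

__all__ = [
    "UndefinedCorrelation",
    "filter_low_total",
    "pearson_with_p",
    "build_network",
    "build_sin",
    "build_dmn",
    "build_mon",
    "SignedCorrelationNetwork",
]

logger = logging.getLogger(__name__)


class UndefinedCorrelation(ValueError):
    """Raised when Pearson correlation is undefined (a constant vector)."""


def filter_low_total(table: FeatureTable, min_total: float = 5) -> FeatureTable:
    """Drop features whose total abundance across the table's samples is
    below ``min_total`` (strictly: a total equal to ``min_total`` is kept).

    Applied per treatment group to suppress spuriously observed OTUs;
    feature order is preserved.
    """
    if table.feature_kind == "otu":
        vals = table.values
        if not np.allclose(vals, np.round(vals)):
            warnings.warn("OTU table contains non-integer counts", stacklevel=2)
    totals = table.feature_totals()
    keep = totals[totals >= min_total].index.tolist()
    if not keep:
        warnings.warn(
            f"all {table.shape[0]} features fall below min_total={min_total}", stacklevel=2
        )
        return FeatureTable(table.data.iloc[0:0], table.feature_kind)
    return table.subset_features(keep)


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with its two-sided p-value from the t transform
    ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of freedom.

    Raises :class:`UndefinedCorrelation` for a constant vector, which
    callers treat as "no edge".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired samples, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelation("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _corr_matrix(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and two-sided p between rows of A and rows of B.

    Rows must be non-constant; n >= 3. Vectorized equivalent of
    :func:`pearson_with_p` (cross-checked in the test suite).
    """
    n = A.shape[1]
    Az = (A - A.mean(axis=1, keepdims=True)) / A.std(axis=1, keepdims=True)
    Bz = (B - B.mean(axis=1, keepdims=True)) / B.std(axis=1, keepdims=True)
    r = Az @ Bz.T / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, np.minimum(p, 1.0)


def _node_kind(table: FeatureTable) -> str:
    return table.feature_kind


def build_network(
    table_a: FeatureTable,
    table_b: FeatureTable | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
    node_kind_a: str | None = None,
    node_kind_b: str | None = None,
) -> nx.Graph:
    """Build a signed correlation network.

    Same-table mode (``table_b is None``) tests every unordered feature
    pair within ``table_a`` and keeps all its features as nodes, even
    isolated ones. Cross mode tests only A-feature vs B-feature pairs and
    drops nodes that end up with no edge. The shared-sample intersection
    is used and must contain at least 3 samples.

    ``fdr=True`` applies Benjamini–Hochberg across all tested pairs before
    the ``alpha`` cut (off by default).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    cross = table_b is not None
    if cross:
        shared = [s for s in table_a.sample_ids if s in set(table_b.sample_ids)]
        if len(shared) < 3:
            raise ValueError(f"only {len(shared)} shared samples; need >= 3")
        ta = table_a.subset_samples(shared)
        tb = table_b.subset_samples(shared)
    else:
        ta = tb = table_a
        if len(ta.sample_ids) < 3:
            raise ValueError(f"only {len(ta.sample_ids)} samples; need >= 3")

    kind_a = node_kind_a or _node_kind(ta)
    kind_b = node_kind_b or _node_kind(tb)

    A, B = ta.values, tb.values
    ok_a = np.ptp(A, axis=1) > 0
    ok_b = ok_a if not cross else np.ptp(B, axis=1) > 0
    n_const = int((~ok_a).sum()) + (int((~ok_b).sum()) if cross else 0)
    if n_const:
        logger.info("skipping %d constant feature(s) with undefined correlation", n_const)

    ids_a = np.asarray(ta.feature_ids)
    ids_b = np.asarray(tb.feature_ids)
    r_mat, p_mat = _corr_matrix(A[ok_a], B[ok_b])

    if cross:
        pairs = [
            (ia, ib) for ia in range(r_mat.shape[0]) for ib in range(r_mat.shape[1])
        ]
    else:
        pairs = [
            (ia, ib) for ia in range(r_mat.shape[0]) for ib in range(ia + 1, r_mat.shape[1])
        ]
    pvals = np.array([p_mat[ia, ib] for ia, ib in pairs])
    if fdr and pvals.size:
        keep_mask = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        keep_mask = pvals <= alpha

    g = nx.Graph()
    tot_a = ta.feature_totals()
    tot_b = tb.feature_totals()
    if not cross:
        # isolated tested features remain nodes in within-table mode
        for fid in ta.feature_ids:
            g.add_node(fid, kind=kind_a, total_abundance=float(tot_a[fid]))

    names_a = ids_a[ok_a]
    names_b = ids_b[ok_b]
    for (ia, ib), keep in zip(pairs, keep_mask):
        if not keep:
            continue
        r = float(r_mat[ia, ib])
        if r == 0.0:
            continue
        a, b = str(names_a[ia]), str(names_b[ib])
        if a == b:
            continue
        if a not in g:
            g.add_node(a, kind=kind_a, total_abundance=float(tot_a[a]))
        if b not in g:
            g.add_node(b, kind=kind_b, total_abundance=float(tot_b[b]))
        g.add_edge(a, b, r=r, p=float(p_mat[ia, ib]), sign="pos" if r > 0 else "neg")
    return g


def build_sin(
    otu_table: FeatureTable,
    alpha: float = 0.05,
    min_total: float = 5,
    fdr: bool = False,
) -> nx.Graph:
    """Species interaction network for one treatment group: low-total OTUs
    removed, then all pairwise OTU correlations."""
    filtered = filter_low_total(otu_table, min_total=min_total)
    return build_network(filtered, alpha=alpha, fdr=fdr)


def diversity_feature_table(
    otu_table: FeatureTable, q_grid: Iterable[float] = DEFAULT_Q_GRID
) -> FeatureTable:
    """Per-sample Hill numbers recast as a feature table (orders x samples),
    with features labeled q0, q1, ... so they can enter cross-correlation."""
    prof = profiles_from_table(otu_table, q_grid)
    data = prof.T
    data.index = [f"q{q:g}" for q in data.index]
    return FeatureTable(data, feature_kind="metabolite")  # non-count kind


def build_dmn(
    otu_table: FeatureTable,
    metabolite_table: FeatureTable,
    q_grid: Iterable[float] = DEFAULT_Q_GRID,
    alpha: float = 0.05,
    fdr: bool = False,
) -> nx.Graph:
    """Diversity–metabolite network: each order q becomes one node
    (q0...q4 by default) correlated against every metabolite."""
    div = diversity_feature_table(otu_table, q_grid)
    return build_network(
        div,
        metabolite_table,
        alpha=alpha,
        fdr=fdr,
        node_kind_a="diversity_order",
        node_kind_b="metabolite",
    )


def build_mon(
    metabolite_table: FeatureTable,
    otu_table: FeatureTable,
    alpha: float = 0.05,
    min_total: float = 0,
    fdr: bool = False,
) -> nx.Graph:
    """Metabolite–OTU network: cross correlations between the two tables."""
    otus = filter_low_total(otu_table, min_total=min_total) if min_total else otu_table
    return build_network(metabolite_table, otus, alpha=alpha, fdr=fdr)


class SignedCorrelationNetwork(BaseEstimator):
    """Estimate a signed Pearson correlation graph from abundance data.

    scikit-learn-style estimator: ``X`` is (n_samples, n_features); pass
    ``Y`` to :meth:`fit` for cross-table (bipartite) mode. Feature names
    are taken from DataFrame columns when available.

    Parameters
    ----------
    alpha : float, default 0.05
        Two-sided p-value threshold for keeping an edge (``p <= alpha``).
    fdr : bool, default False
        Apply Benjamini–Hochberg across tested pairs before thresholding.
    min_total : float, default 0
        Drop features whose column total is below this before testing
        (the within-group spurious-read filter; 5 is the conventional
        choice for OTU count tables).

    Attributes
    ----------
    network_ : networkx.Graph
        The inferred signed network; edges carry ``r``, ``p``, ``sign``.
    n_features_in_ : int
        Features in ``X`` after the low-total filter.
    """

    def __init__(self, alpha: float = 0.05, fdr: bool = False, min_total: float = 0):
        self.alpha = alpha
        self.fdr = fdr
        self.min_total = min_total

    def _as_table(self, X, prefix: str, kind: str) -> FeatureTable:
        if isinstance(X, FeatureTable):
            return X
        if isinstance(X, pd.DataFrame):
            return FeatureTable(X.T, feature_kind=kind)
        X = np.asarray(X, dtype=float)
        df = pd.DataFrame(
            X.T,
            index=[f"{prefix}{i}" for i in range(X.shape[1])],
            columns=[f"s{j}" for j in range(X.shape[0])],
        )
        return FeatureTable(df, feature_kind=kind)

    def fit(self, X, Y=None):
        ta = self._as_table(X, "f", "otu")
        if self.min_total:
            ta = filter_low_total(ta, min_total=self.min_total)
        if Y is None:
            self.network_ = build_network(ta, alpha=self.alpha, fdr=self.fdr)
        else:
            tb = self._as_table(Y, "g", "metabolite")
            self.network_ = build_network(ta, tb, alpha=self.alpha, fdr=self.fdr)
        self.n_features_in_ = ta.shape[0]
        return self

    def fit_network(self, X, Y=None) -> nx.Graph:
        return self.fit(X, Y).network_
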