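"""Hill-number diversity profiles and between-group comparisons.

The Hill number of order ``q`` for a community with relative abundances
``p_1..p_S`` is

    qD = (sum_i p_i ** q) ** (1 / (1 - q))          for q != 1
    1D = exp(-sum_i p_i * ln(p_i))                  in the q -> 1 limit

in units of "species equivalents": a community with qD = x is as diverse,
at order q, as one with x equally abundant species. q tunes the weight on
abundant species — q=0 is richness, q=1 the exponential of Shannon entropy
(natural log), q=2 the inverse Simpson concentration. The curve of qD over
a grid of orders (the diversity profile) summarizes the whole species
abundance distribution, which is why it replaces any single index here.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io_tables import FeatureTable, GroupAssignment

__all__ = [
    "DEFAULT_Q_GRID",
    "hill_number",
    "profile",
    "profiles_from_table",
    "group_mean_profile",
    "compare_groups_t",
    "pairwise_group_tests",
    "HillDiversity",
]

DEFAULT_Q_GRID: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)

#: orders closer to 1 than this are routed to the Shannon-limit formula
_Q1_TOL = 1e-9


def hill_number(p: Sequence[float] | np.ndarray, q: float) -> float:
    """Effective number of species at diversity order ``q``.

    ``p`` must be strictly positive relative abundances summing to one
    (zeros removed by the caller); normalization is the caller's job so
    that a malformed vector cannot silently change the answer.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty abundance vector")
    if not np.isfinite(q):
        raise ValueError("q must be finite")
    if q < 0:
        raise ValueError("q must be non-negative")
    if (p <= 0).any():
        raise ValueError("abundances must be strictly positive (drop zeros first)")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"abundances must sum to 1 (got {p.sum()!r}); normalize first")
    if abs(q - 1.0) <= _Q1_TOL:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def profile(
    counts: Sequence[float] | np.ndarray,
    q_grid: Iterable[float] = DEFAULT_Q_GRID,
) -> dict[float, float]:
    """Diversity profile of one sample: order q -> effective species number.

    Counts are converted to relative abundances; zero-count features are
    dropped (they carry no abundance mass and richness counts only features
    actually present).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or (counts < 0).any():
        raise ValueError("counts must be a non-empty non-negative vector")
    nonzero = counts[counts > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero sample has no diversity profile")
    p = nonzero / nonzero.sum()
    return {float(q): hill_number(p, float(q)) for q in q_grid}


def profiles_from_table(
    table: FeatureTable, q_grid: Iterable[float] = DEFAULT_Q_GRID
) -> pd.DataFrame:
    """Per-sample diversity profiles (samples x orders) from a count table."""
    q_grid = [float(q) for q in q_grid]
    rows = {sid: profile(table.data[sid].to_numpy(), q_grid) for sid in table.sample_ids}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df.loc[table.sample_ids, q_grid]


def group_mean_profile(
    profiles: pd.DataFrame,
    groups: GroupAssignment,
    exclude_samples: Iterable[str] = (),
) -> pd.DataFrame:
    """Arithmetic mean profile per group (groups x orders).

    ``exclude_samples`` drops named samples before averaging, e.g. the
    day-0 baseline of a longitudinal series; no exclusion is applied by
    default.
    """
    exclude = set(exclude_samples)
    out: dict[str, pd.Series] = {}
    for group, members in groups.groups().items():
        members = [m for m in members if m in profiles.index and m not in exclude]
        if not members:
            raise ValueError(f"group {group!r} has no samples with computed profiles")
        out[group] = profiles.loc[members].mean(axis=0)
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "group"
    return df


def compare_groups_t(
    profiles: pd.DataFrame,
    groups: GroupAssignment,
    group_a: str,
    group_b: str,
    q: float,
    exclude_samples: Iterable[str] = (),
) -> tuple[float, float, float, float]:
    """Two-sided pooled-variance Student's t-test on per-sample qD values.

    Returns ``(mean_a, mean_b, t, p)``.
    """
    exclude = set(exclude_samples)
    q = float(q)
    if q not in profiles.columns:
        raise KeyError(f"order {q} not in computed profiles")

    def _vals(group: str) -> np.ndarray:
        members = [m for m in groups.samples_in(group) if m in profiles.index and m not in exclude]
        if len(members) < 2:
            raise ValueError(f"group {group!r} needs >= 2 samples for a t-test")
        return profiles.loc[members, q].to_numpy()

    a, b = _vals(group_a), _vals(group_b)
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        # identical degenerate groups: no evidence of difference
        return float(a.mean()), float(b.mean()), 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(a.mean()), float(b.mean()), float(t), float(p)


def pairwise_group_tests(
    profiles: pd.DataFrame,
    groups: GroupAssignment,
    exclude_samples: Iterable[str] = (),
) -> pd.DataFrame:
    """All pairwise group t-tests at every computed order, long format."""
    labels = sorted(groups.groups())
    rows = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            for q in profiles.columns:
                ma, mb, t, p = compare_groups_t(
                    profiles, groups, ga, gb, q, exclude_samples=exclude_samples
                )
                rows.append(
                    {"group_a": ga, "group_b": gb, "q": q, "mean_a": ma, "mean_b": mb,
                     "t": t, "p": p}
                )
    return pd.DataFrame(rows)


class HillDiversity(TransformerMixin, BaseEstimator):
    """Transform a counts matrix into per-sample Hill-number profiles.

    Follows the scikit-learn convention: ``X`` is (n_samples, n_features)
    — note this is the transpose of the features-as-rows
    :class:`~milknet.io_tables.FeatureTable` layout, which
    :func:`profiles_from_table` handles for you.

    Parameters
    ----------
    q_grid : sequence of float, default (0, 1, 2, 3, 4)
        Diversity orders at which to evaluate each sample's profile.

    Attributes
    ----------
    n_features_in_ : int
        Number of features seen during :meth:`fit`.
    q_grid_ : tuple of float
        Validated grid of orders.
    """

    def __init__(self, q_grid: Sequence[float] = DEFAULT_Q_GRID):
        self.q_grid = q_grid

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        grid = tuple(float(q) for q in self.q_grid)
        if any(q < 0 or not math.isfinite(q) for q in grid):
            raise ValueError("q_grid must contain finite non-negative orders")
        self.q_grid_ = grid
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "q_grid_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; HillDiversity was fitted with "
                f"{self.n_features_in_}"
            )
        out = np.empty((X.shape[0], len(self.q_grid_)))
        for i, row in enumerate(X):
            prof = profile(row, self.q_grid_)
            out[i] = [prof[q] for q in self.q_grid_]
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "q_grid_")
        return np.asarray([f"q{q:g}" for q in self.q_grid_], dtype=object)
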