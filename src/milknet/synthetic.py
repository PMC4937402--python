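"""Synthetic OTU/metabolite data with planted correlation structure.

The generator emulates the statistical shape of a small milk-microbiome
study: a handful of samples per treatment group (8-9), several dozen OTUs
with a heavy-tailed (Zipf-like) abundance distribution whose steepness is
set by a ``dominance`` parameter, planted positive and negative pairwise
OTU correlations driven by shared latent factors on the log scale, Poisson
count noise, and metabolites coupled (positively or negatively) to the
per-sample first-order Hill number. Everything is driven by one integer
seed through a single RNG stream, so a scenario is bit-reproducible.

The count model is deliberately aligned with the downstream inference:
plain Pearson correlation on abundances, no compositional closure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import profiles_from_table
from .io_tables import FeatureTable, GroupAssignment

__all__ = [
    "PlantedEdge",
    "DiversityEffect",
    "SyntheticTruth",
    "generate_otu_table",
    "generate_metabolite_table",
    "milk_study_preset",
    "DEFAULT_METABOLITE_EFFECTS",
    "edge_recovery",
]


@dataclass(frozen=True)
class PlantedEdge:
    feature_a: str
    feature_b: str
    sign: str  # "pos" | "neg"
    target_r: float  # target |Pearson r| on the count scale


@dataclass(frozen=True)
class DiversityEffect:
    metabolite: str
    sign: str  # "pos" | "neg"
    effect: float  # slope on the standardized Hill-number scale


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside generated tables."""

    planted_otu_edges: list[PlantedEdge] = field(default_factory=list)
    diversity_metabolite_effects: list[DiversityEffect] = field(default_factory=list)
    group_diversity_levels: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def edge_set(self, min_target_r: float = 0.0) -> set[frozenset]:
        return {
            frozenset((e.feature_a, e.feature_b))
            for e in self.planted_otu_edges
            if e.target_r >= min_target_r
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


#: nine metabolites coupled to diversity, 4 positive / 5 negative, mirroring
#: the milk metabolome panel this generator emulates
DEFAULT_METABOLITE_EFFECTS: tuple[DiversityEffect, ...] = (
    DiversityEffect("DHA", "pos", 3.0),
    DiversityEffect("Inositol", "pos", 3.0),
    DiversityEffect("Threitol", "pos", 3.0),
    DiversityEffect("PUFA", "pos", 3.0),
    DiversityEffect("Butanal", "neg", 3.0),
    DiversityEffect("Xlmonopalmitin", "neg", 3.0),
    DiversityEffect("Decanoic_acid", "neg", 3.0),
    DiversityEffect("Arabinose", "neg", 3.0),
    DiversityEffect("Myristic_acid", "neg", 3.0),
)


#: idiosyncratic log-noise used for negatively coupled pairs; a convex
#: (exponential) link bounds how negative the level correlation can get, so
#: negative pairs are generated with deliberately small marginal log-variance
_NEG_NOISE_SD = 0.08


def _pair_correlation(a2: float, sign: float, s2: float, mean_counts: float) -> float:
    """Count-scale Pearson correlation of a planted pair.

    Two features with log-mean baseline log(m), shared-factor loadings
    +-a and idiosyncratic log-noise variance s2 - a2, observed through
    Poisson counting, have

        r = (exp(sign * a^2) - 1) / ((exp(s^2) - 1) + exp(-s^2 / 2) / m)

    where s^2 = a^2 + noise^2 is the total log-variance. The additive
    ``exp(-s^2/2)/m`` term is the Poisson counting noise.
    """
    denom = math.expm1(s2) + math.exp(-s2 / 2) / mean_counts
    return math.expm1(sign * a2) / denom


def _loading_for_target(
    target_r: float, sign: str, noise_sd: float, mean_counts: float
) -> tuple[float, float]:
    """Shared-factor loading (and noise sd actually used) whose implied
    count-scale |Pearson| equals ``target_r``, accounting for both the
    log-normal level transform and Poisson counting noise.

    Positive targets are solved directly (|r| is increasing in the
    loading). Negative targets are bounded above by the Frechet-type limit
    of the exponential link, so they use the smaller :data:`_NEG_NOISE_SD`
    and an infeasible target raises ``ValueError``.
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    from scipy.optimize import brentq, minimize_scalar

    sgn = 1.0 if sign == "pos" else -1.0
    sd = noise_sd if sign == "pos" else min(noise_sd, _NEG_NOISE_SD)
    if sign == "pos":
        # r is capped at exp(-sd^2) as the loading grows; shrink the pair's
        # idiosyncratic noise until the target is attainable
        while math.exp(-sd**2) <= target_r * 1.005:
            sd *= 0.7
    s2_noise = sd**2

    def f(a2: float) -> float:
        return abs(_pair_correlation(a2, sgn, a2 + s2_noise, mean_counts)) - target_r

    if sign == "pos":
        a2 = brentq(f, 1e-9, 50.0)
    else:
        peak = minimize_scalar(
            lambda x: -abs(_pair_correlation(x, sgn, x + s2_noise, mean_counts)),
            bounds=(1e-9, 5.0), method="bounded",
        )
        if f(peak.x) < 0:
            raise ValueError(
                f"negative target |r|={target_r} is not attainable under the "
                f"log-normal Poisson count model (max about {target_r + f(peak.x):.3f}); "
                "lower the target or raise the sequencing depth"
            )
        a2 = brentq(f, 1e-9, peak.x)
    return math.sqrt(a2), sd


def generate_otu_table(
    n_samples: int,
    n_otus: int,
    planted_edges: Sequence[tuple[str, float]] = (),
    dominance: float = 1.0,
    seed: int | np.random.Generator = 0,
    depth: float = 50_000.0,
    noise_sd: float = 0.3,
    prefix: str = "OTU",
    sample_prefix: str = "S",
) -> tuple[FeatureTable, SyntheticTruth]:
    """Generate an OTU count table with planted pairwise correlations.

    Each OTU's per-sample log-mean is ``log(depth * w_i)`` plus latent
    structure, where the baseline weights ``w_i`` follow a Zipf law with
    exponent ``dominance`` (larger -> steeper abundance decay -> Hill
    numbers that fall faster with q). Each planted pair occupies two
    dedicated high-abundance features sharing a standard-normal factor,
    with equal-magnitude loadings (opposite in sign for a negative pair)
    calibrated so the count-scale |r| approximates the requested target.
    Counts are Poisson around the exponentiated latent mean — no
    compositional closure is imposed.

    ``planted_edges`` is a sequence of ``(sign, target_abs_r)`` tuples.
    """
    if n_samples < 3:
        raise ValueError("need n_samples >= 3")
    if 2 * len(planted_edges) > n_otus:
        raise ValueError(
            f"{len(planted_edges)} planted pairs need {2 * len(planted_edges)} dedicated "
            f"features but only {n_otus} are available"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = -1 if isinstance(seed, np.random.Generator) else int(seed)

    ranks = np.arange(1, n_otus + 1, dtype=float)
    w = ranks**-dominance
    w /= w.sum()
    log_mu = np.log(depth * w)[:, None] + np.zeros((n_otus, n_samples))

    edges: list[PlantedEdge] = []
    feature_noise = np.full(n_otus, noise_sd)
    for k, (sign, target_r) in enumerate(planted_edges):
        if sign not in ("pos", "neg"):
            raise ValueError(f"planted sign must be pos or neg, got {sign!r}")
        i, j = 2 * k, 2 * k + 1  # dedicated, high-baseline features
        pair_mean = depth * math.sqrt(w[i] * w[j])
        a, sd = _loading_for_target(float(target_r), sign, noise_sd, pair_mean)
        feature_noise[[i, j]] = sd
        f = rng.standard_normal(n_samples)
        log_mu[i] += a * f
        log_mu[j] += (a if sign == "pos" else -a) * f
        edges.append(PlantedEdge(f"{prefix}{i + 1}", f"{prefix}{j + 1}", sign, float(target_r)))

    log_mu += feature_noise[:, None] * rng.standard_normal((n_otus, n_samples))
    counts = rng.poisson(np.exp(log_mu))

    features = [f"{prefix}{i + 1}" for i in range(n_otus)]
    samples = [f"{sample_prefix}{j + 1}" for j in range(n_samples)]
    table = FeatureTable(
        pd.DataFrame(counts, index=features, columns=samples), feature_kind="otu"
    )
    truth = SyntheticTruth(planted_otu_edges=edges, seed=seed_val)
    return table, truth


def generate_metabolite_table(
    otu_table: FeatureTable,
    effects: Sequence[DiversityEffect] = DEFAULT_METABOLITE_EFFECTS,
    n_uncoupled: int = 3,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 1.0,
) -> FeatureTable:
    """Generate metabolite abundances coupled to per-sample diversity.

    Each coupled metabolite is ``sign * effect * z + noise`` where ``z`` is
    the standardized first-order Hill number (exp-Shannon) of the matching
    sample, shifted to be strictly positive (the shift leaves Pearson
    correlations untouched). Uncoupled metabolites are pure noise.
    """
    if otu_table.shape[0] == 0:
        raise ValueError("otu_table is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prof = profiles_from_table(otu_table, q_grid=(1.0,))
    z = prof[1.0].to_numpy()
    sd = z.std()
    z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)

    rows = {}
    for eff in effects:
        direction = 1.0 if eff.sign == "pos" else -1.0
        raw = direction * eff.effect * z + noise_sd * rng.standard_normal(z.size)
        rows[eff.metabolite] = raw - raw.min() + 1.0
    for k in range(n_uncoupled):
        raw = noise_sd * rng.standard_normal(z.size)
        rows[f"Metabolite_bg{k + 1}"] = raw - raw.min() + 1.0
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.columns = otu_table.sample_ids
    return FeatureTable(df, feature_kind="metabolite")


def _default_planted(sign_counts: tuple[int, int], rng: np.random.Generator):
    """(n_pos, n_neg) planted edges. Negative pairs come first so they take
    the highest-abundance ranks (their attainable |r| shrinks with counting
    noise) and get moderate targets; positive targets are strong."""
    n_pos, n_neg = sign_counts
    neg = [("neg", t) for t in rng.uniform(0.5, 0.65, size=n_neg)]
    pos = [("pos", t) for t in rng.uniform(0.75, 0.95, size=n_pos)]
    return neg + pos


def milk_study_preset(
    seed: int = 42,
    n_samples: tuple[int, int, int] = (8, 8, 9),
    n_otus: int = 70,
    dominance: dict[str, float] | None = None,
    planted: dict[str, tuple[int, int]] | None = None,
    depth: float = 1000.0,
) -> dict:
    """Generate the full small-cohort scenario: one OTU table covering the
    pre-chemotherapy / post-chemotherapy / healthy groups, a coupled
    metabolite table, group metadata, and ground truth per group.

    Group dominance levels are set so the healthy group keeps a flat,
    diverse abundance distribution while the patient groups are dominated
    by a few OTUs — the signature pattern of high healthy and depressed
    patient diversity at orders q >= 1. The modest sequencing depth keeps
    per-sample richness in the low-to-mid 50s and lets the rarest OTUs
    fall under the within-group total-reads filter, so per-group network
    node counts land in the 50-70 range typical of such cohorts. Planted
    edge mixes skew the pre-chemotherapy group toward positive
    associations; note that at 8-9 samples the uncorrected edge test also
    admits chance edges of both signs, exactly as it does in real studies
    of this size.

    Returns a dict with keys ``otu_table``, ``metabolite_table``,
    ``groups``, ``truth`` (group label -> :class:`SyntheticTruth`).
    """
    rng = np.random.default_rng(seed)
    dominance = dominance or {"pre": 1.6, "post": 1.5, "healthy": 1.1}
    planted = planted or {"pre": (12, 1), "post": (10, 4), "healthy": (10, 4)}
    labels = ("pre", "post", "healthy")
    if len(n_samples) != 3:
        raise ValueError("n_samples must give (pre, post, healthy) sizes")

    tables, truths, mapping = [], {}, {}
    prefixes = {"pre": "A", "post": "B", "healthy": "H"}
    for label, n in zip(labels, n_samples):
        spec = _default_planted(planted[label], rng)
        table, truth = generate_otu_table(
            n_samples=n,
            n_otus=n_otus,
            planted_edges=spec,
            dominance=dominance[label],
            seed=rng,
            depth=depth,
            sample_prefix=prefixes[label],
        )
        truth.group_diversity_levels = {label: dominance[label]}
        truth.seed = seed
        tables.append(table.data)
        truths[label] = truth
        mapping.update({s: label for s in table.sample_ids})

    otu_table = FeatureTable(pd.concat(tables, axis=1), feature_kind="otu")
    metabolite_table = generate_metabolite_table(otu_table, seed=rng)
    for truth in truths.values():
        truth.diversity_metabolite_effects = list(DEFAULT_METABOLITE_EFFECTS)
    return {
        "otu_table": otu_table,
        "metabolite_table": metabolite_table,
        "groups": GroupAssignment(mapping),
        "truth": truths,
    }


def edge_recovery(
    net, truth: SyntheticTruth, min_abs_r: float = 0.7, require_sign: bool = True
) -> tuple[float, float]:
    """Precision and recall of strong planted-edge recovery.

    Predicted strong edges are network edges with ``|r| >= min_abs_r``;
    the reference set is the planted pairs with target ``|r| >= min_abs_r``.
    ``require_sign`` additionally demands the recovered sign match the
    planted one. Returns ``(precision, recall)``; an empty prediction set
    has precision 1.0 by convention.
    """
    truth_edges = {
        frozenset((e.feature_a, e.feature_b)): e.sign
        for e in truth.planted_otu_edges
        if e.target_r >= min_abs_r
    }
    predicted = {
        frozenset((a, b)): attrs["sign"]
        for a, b, attrs in net.edges(data=True)
        if abs(attrs["r"]) >= min_abs_r
    }
    hits = sum(
        1
        for pair, sign in predicted.items()
        if pair in truth_edges and (not require_sign or truth_edges[pair] == sign)
    )
    precision = hits / len(predicted) if predicted else 1.0
    recall = hits / len(truth_edges) if truth_edges else 1.0
    return precision, recall
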