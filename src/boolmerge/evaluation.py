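"""Evaluation of merged models: attractor-pattern clustering, activation
frequencies versus observed expression, and phenotype scoring of mutation
profiles against clinical measurements.

The central quantity is the *activation frequency* of a gene: the fraction
of attractor states in which it is ON, optionally weighted by basin size.
It is compared with an observed per-gene expression frequency (Pearson by
default), and weighted sums of it over designated phenotype nodes give a
*network score* used as a proxy for a clinical outcome such as blast
percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from .errors import DegenerateVarianceError
from .dynamics import Attractor, MutationProfile, find_attractors, apply_perturbation
from .model import LogicalModel

__all__ = [
    "PatternMatrix",
    "pattern_matrix",
    "hamming_cluster",
    "ActivationProfile",
    "activation_frequency",
    "correlate",
    "PhenotypeScoreConfig",
    "network_score",
    "CohortRecord",
    "cohort_correlation",
]

Weighting = Literal["UNIFORM_STATES", "BASIN"]


@dataclass
class PatternMatrix:
    """Binary attractor-by-gene pattern table.

    ``values`` has one row per attractor and one column per gene in the
    union symbol set; cells are 0.0/1.0 or NaN where the gene is absent from
    the attractor's source model (the heatmap's grey). ``ties`` flags cells
    where a cyclic attractor's per-gene majority was an exact tie (recorded
    as 0).
    """

    values: pd.DataFrame
    ties: pd.DataFrame


def pattern_matrix(
    sets: Sequence[tuple[LogicalModel, Sequence[Attractor]]]
) -> PatternMatrix:
    """Build the pattern matrix from one or more models' attractor sets.

    Fixed points contribute their state; cyclic attractors contribute the
    per-gene majority value across their states, exact ties recorded as 0
    and flagged.
    """
    columns: list[str] = []
    for model, _ in sets:
        for s in model.symbols:
            if s not in columns:
                columns.append(s)
    rows, tie_rows, labels = [], [], []
    for model, attractors in sets:
        for a in attractors:
            arr = np.array(a.states, dtype=float)  # states x genes
            mean = arr.mean(axis=0)
            row = {}
            tie = {}
            for sym, m in zip(model.symbols, mean):
                if m > 0.5:
                    row[sym] = 1.0
                else:
                    row[sym] = 0.0
                tie[sym] = bool(len(a.states) > 1 and m == 0.5)
            rows.append([row.get(c, np.nan) for c in columns])
            tie_rows.append([tie.get(c, False) for c in columns])
            labels.append(a.label or f"{model.name}.{len(labels)}")
    values = pd.DataFrame(rows, index=labels, columns=columns)
    ties = pd.DataFrame(tie_rows, index=labels, columns=columns)
    return PatternMatrix(values=values, ties=ties)


def _masked_hamming(values: np.ndarray) -> np.ndarray:
    """Pairwise normalized Hamming distance, skipping NaN cells.

    Distance between two rows = differing cells / comparable cells, where a
    cell is comparable when neither row has NaN there. Raises if some pair
    shares no comparable position.
    """
    n = values.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(values[i]) & ~np.isnan(values[j])
            denom = int(both.sum())
            if denom == 0:
                raise ValueError(
                    f"rows {i} and {j} share no non-missing positions; "
                    "Hamming distance undefined"
                )
            diff = int((values[i][both] != values[j][both]).sum())
            dist[i, j] = dist[j, i] = diff / denom
    return dist


def hamming_cluster(
    matrix: PatternMatrix | pd.DataFrame,
    k: int | None = None,
    threshold: float | None = None,
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative average-linkage clustering of attractor patterns.

    Returns (cluster labels indexed like the matrix rows, scipy linkage
    matrix). Give either ``k`` (number of clusters) or ``threshold``
    (distance cut); with neither, every merge is returned via the linkage
    and labels use a 0.5 distance cut.
    """
    values = matrix.values if isinstance(matrix, PatternMatrix) else matrix
    if values.shape[0] < 2:
        raise ValueError("need at least two attractor patterns to cluster")
    dist = _masked_hamming(values.to_numpy(dtype=float))
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if k is not None:
        flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    else:
        flat = hierarchy.fcluster(linkage, t=0.5 if threshold is None else threshold,
                                  criterion="distance")
    labels = pd.Series(flat, index=values.index, name="cluster")
    return labels, linkage


@dataclass
class ActivationProfile:
    """Per-gene activation frequency in [0, 1], plus how it was weighted."""

    frequencies: pd.Series
    weighting: Weighting

    def __getitem__(self, symbol: str) -> float:
        return float(self.frequencies[symbol])


def activation_frequency(
    attractors: Sequence[Attractor],
    symbols: Sequence[str],
    weighting: Weighting = "UNIFORM_STATES",
) -> ActivationProfile:
    """Fraction of attractor states in which each gene is ON.

    UNIFORM_STATES pools all states of all attractors with equal weight;
    BASIN weights each attractor's per-gene mean by its basin fraction
    (renormalized over the given attractors).
    """
    if not attractors:
        raise ValueError("need at least one attractor")
    if weighting == "UNIFORM_STATES":
        pooled = np.concatenate([np.array(a.states, dtype=float) for a in attractors])
        freqs = pooled.mean(axis=0)
    elif weighting == "BASIN":
        weights = []
        means = []
        for a in attractors:
            if a.basin_fraction is None:
                raise ValueError(
                    f"attractor {a.label!r} lacks a basin fraction; "
                    "BASIN weighting unavailable"
                )
            weights.append(a.basin_fraction)
            means.append(np.array(a.states, dtype=float).mean(axis=0))
        w = np.array(weights, dtype=float)
        if w.sum() <= 0:
            raise ValueError("basin fractions sum to zero")
        freqs = (np.array(means) * (w / w.sum())[:, None]).sum(axis=0)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    series = pd.Series(freqs, index=list(symbols), name="activation_frequency")
    return ActivationProfile(frequencies=series, weighting=weighting)


def correlate(
    profile: ActivationProfile,
    observed: Mapping[str, float] | pd.Series,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, int, list[str]]:
    """Correlation between modeled activation frequency and observed
    expression frequency over the shared genes.

    Returns (r, number of genes used, genes excluded from either side).
    """
    observed = pd.Series(dict(observed)) if not isinstance(observed, pd.Series) else observed
    predicted = profile.frequencies
    common = [g for g in predicted.index if g in observed.index]
    excluded = sorted(set(predicted.index).symmetric_difference(observed.index))
    if len(common) < 3:
        raise ValueError(
            f"need at least 3 genes in common, got {len(common)}"
        )
    x = predicted[common].to_numpy(dtype=float)
    y = observed[common].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateVarianceError(
            "correlation undefined: constant predictions or observations"
        )
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), len(common), excluded


@dataclass(frozen=True)
class PhenotypeScoreConfig:
    """Signed weights over phenotype nodes; the network score is
    sum_k weight_k * activation_frequency(node_k)."""

    weights: tuple[tuple[str, float], ...]

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "PhenotypeScoreConfig":
        if not mapping:
            raise ValueError("phenotype score config needs at least one node")
        return cls(tuple(sorted((s, float(w)) for s, w in mapping.items())))

    def as_dict(self) -> dict[str, float]:
        return dict(self.weights)


def network_score(
    model: LogicalModel,
    profile: MutationProfile,
    config: PhenotypeScoreConfig,
    scheme: Literal["SYNC", "ASYNC"] = "SYNC",
    weighting: Weighting = "UNIFORM_STATES",
) -> float:
    """Phenotype network score of one mutation profile.

    Clamps the mutated genes, recomputes attractors, and evaluates the
    weighted sum of phenotype-node activation frequencies.
    """
    for node, _ in config.weights:
        if node not in model:
            raise KeyError(f"phenotype node {node!r} not in model")
    perturbed = apply_perturbation(model, profile)
    attractors = find_attractors(perturbed, scheme=scheme)
    freqs = activation_frequency(attractors, perturbed.symbols, weighting)
    return float(sum(w * freqs[node] for node, w in config.weights))


@dataclass(frozen=True)
class CohortRecord:
    """One patient: mutation profile plus a clinical measurement
    (e.g. blast percentage)."""

    patient_id: str
    profile: MutationProfile
    clinical_value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.clinical_value):
            raise ValueError(f"non-finite clinical value for {self.patient_id!r}")


def cohort_correlation(
    model: LogicalModel,
    cohort: Sequence[CohortRecord],
    config: PhenotypeScoreConfig,
    scheme: Literal["SYNC", "ASYNC"] = "SYNC",
    weighting: Weighting = "UNIFORM_STATES",
    method: Literal["pearson", "spearman"] = "pearson",
    weight_by_size: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Correlation between network scores and clinical values across
    mutation-profile groups.

    Patients with identical profiles are pooled; each group contributes its
    network score and its mean clinical value. ``weight_by_size`` weights
    groups by patient count in the correlation itself (Pearson only);
    otherwise group size is reported but not used.
    """
    groups: dict[tuple[tuple[str, int], ...], list[CohortRecord]] = {}
    for rec in cohort:
        groups.setdefault(rec.profile.clamps, []).append(rec)
    if len(groups) < 3:
        raise ValueError(
            f"need at least 3 distinct mutation profiles, got {len(groups)}"
        )
    rows = []
    for clamps, records in sorted(groups.items()):
        profile = MutationProfile(clamps)
        score = network_score(model, profile, config, scheme, weighting)
        rows.append({
            "profile": ";".join(f"{s}={b}" for s, b in clamps) or "wild-type",
            "n_patients": len(records),
            "score": score,
            "clinical_value": float(np.mean([r.clinical_value for r in records])),
        })
    table = pd.DataFrame(rows)
    x = table["score"].to_numpy()
    y = table["clinical_value"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateVarianceError("constant scores or clinical values across groups")
    if weight_by_size:
        w = table["n_patients"].to_numpy(dtype=float)
        r = _weighted_pearson(x, y, w)
    elif method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    else:
        r = float(stats.spearmanr(x, y).statistic)
    return r, table


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx, vy = np.sum(w * (x - mx) ** 2), np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        raise DegenerateVarianceError("zero weighted variance")
    return float(cov / np.sqrt(vx * vy))
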