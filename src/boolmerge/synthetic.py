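"""Seeded generators: random Boolean models, overlapping model pairs, and
noisy expression/cohort data.

Everything downstream of "finding models" can be exercised offline: the
generators produce the same ``.bnet``/SBML-qual/CSV artifacts the rest of
the tool consumes, and are pure functions of spec + seed (byte-identical
reruns). Rule trees are kept shallow (depth <= 3) so exhaustive influence
classification stays cheap, and no attempt is made to mimic the topology of
real regulatory networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import MutationProfile, find_attractors
from .evaluation import (
    CohortRecord,
    PhenotypeScoreConfig,
    activation_frequency,
    network_score,
)
from .expr import And, BoolExpr, Not, Or, Var
from .model import LogicalModel, NodeSpec

__all__ = [
    "SyntheticSpec",
    "random_model",
    "overlapping_pair",
    "synthetic_expression",
    "synthetic_cohort",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generators.

    n_nodes: nodes per model. max_in_degree: regulators per rule are drawn
    from 1..max_in_degree. overlap: number of symbols shared by a generated
    pair. p_neg: probability a literal is negated. sigma: noise s.d. on
    observed frequencies / clinical values. n_patients: cohort size.
    seed: mandatory; all randomness derives from it.
    """

    n_nodes: int = 10
    max_in_degree: int = 3
    overlap: int = 3
    p_neg: float = 0.3
    sigma: float = 0.05
    n_patients: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not (1 <= self.max_in_degree <= max(1, self.n_nodes - 1)):
            raise ValueError("max_in_degree must be in 1..n_nodes-1")
        if not (0 <= self.overlap <= self.n_nodes):
            raise ValueError("overlap must be in 0..n_nodes")
        if not (0.0 <= self.p_neg <= 1.0):
            raise ValueError("p_neg must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _random_rule(
    rng: np.random.Generator, regulators: list[str], p_neg: float
) -> BoolExpr:
    """Random shallow expression tree that uses every listed regulator."""
    literals: list[BoolExpr] = []
    for reg in regulators:
        lit: BoolExpr = Var(reg)
        if rng.random() < p_neg:
            lit = Not(lit)
        literals.append(lit)
    # combine literals pairwise with random connectives -> depth <= 3
    while len(literals) > 1:
        i = int(rng.integers(0, len(literals) - 1))
        a = literals.pop(i)
        b = literals.pop(i)
        op = And if rng.random() < 0.5 else Or
        literals.insert(i, op(a, b))
    return literals[0]


def _model_from_symbols(
    rng: np.random.Generator, name: str, symbols: list[str], spec: SyntheticSpec
) -> LogicalModel:
    nodes = []
    for sym in symbols:
        pool = [s for s in symbols if s != sym] or [sym]
        k = int(rng.integers(1, min(spec.max_in_degree, len(pool)) + 1))
        regs = sorted(rng.choice(pool, size=k, replace=False).tolist())
        nodes.append(NodeSpec(symbol=sym, rule=_random_rule(rng, regs, spec.p_neg)))
    return LogicalModel(name, nodes)


def random_model(spec: SyntheticSpec, name: str = "synthetic") -> LogicalModel:
    """One random model with n_nodes nodes named G1..Gn."""
    rng = np.random.default_rng(spec.seed)
    symbols = [f"G{i + 1}" for i in range(spec.n_nodes)]
    return _model_from_symbols(rng, name, symbols, spec)


def overlapping_pair(
    spec: SyntheticSpec,
) -> tuple[LogicalModel, LogicalModel, set[str]]:
    """Two models sharing exactly ``spec.overlap`` symbols.

    Shared symbols get independent rules in each model, so all three merge
    semantics differ nontrivially on the pair.
    """
    rng = np.random.default_rng(spec.seed)
    shared = [f"S{i + 1}" for i in range(spec.overlap)]
    n_excl = spec.n_nodes - spec.overlap
    a_symbols = shared + [f"A{i + 1}" for i in range(n_excl)]
    b_symbols = shared + [f"B{i + 1}" for i in range(n_excl)]
    model_a = _model_from_symbols(rng, "modelA", a_symbols, spec)
    model_b = _model_from_symbols(rng, "modelB", b_symbols, spec)
    return model_a, model_b, set(shared)


def synthetic_expression(
    model: LogicalModel, sigma: float, seed: int
) -> pd.Series:
    """Observed per-gene expression frequencies: the model's true activation
    frequency plus N(0, sigma) noise truncated to [0, 1]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    attractors = find_attractors(model, scheme="SYNC")
    truth = activation_frequency(attractors, model.symbols, "UNIFORM_STATES")
    noisy = truth.frequencies + rng.normal(0.0, sigma, size=len(model.symbols)) if sigma > 0 \
        else truth.frequencies.copy()
    observed = noisy.clip(0.0, 1.0)
    observed.name = "frequency"
    observed.index.name = "gene"
    return observed


def synthetic_cohort(
    model: LogicalModel,
    config: PhenotypeScoreConfig,
    n_patients: int,
    sigma: float,
    seed: int,
    clinical_offset: float = 20.0,
    clinical_scale: float = 60.0,
) -> tuple[list[CohortRecord], pd.Series]:
    """Synthetic patient cohort for phenotype-score recovery tests.

    Each patient carries 1-3 random clamps; the clinical value (a blast-
    percentage-like quantity) is an affine transform of the ground-truth
    network score plus N(0, sigma) noise. The first three patients get
    canonical distinct profiles (first phenotype node clamped to 1, to 0,
    and one random single clamp) so the cohort always contains >= 3 distinct
    profiles with non-degenerate scores.

    Returns (cohort records, ground-truth scores indexed by patient id).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    symbols = model.symbols
    phenotype = config.weights[0][0]

    profiles: list[MutationProfile] = []
    for i in range(n_patients):
        if i == 0:
            profile = MutationProfile.from_dict({phenotype: 1})
        elif i == 1:
            profile = MutationProfile.from_dict({phenotype: 0})
        elif i == 2:
            gene = str(rng.choice([s for s in symbols if s != phenotype] or symbols))
            profile = MutationProfile.from_dict({gene: int(rng.integers(0, 2))})
        else:
            n_clamps = int(rng.integers(1, 4))
            genes = rng.choice(symbols, size=min(n_clamps, len(symbols)), replace=False)
            profile = MutationProfile.from_dict(
                {str(g): int(rng.integers(0, 2)) for g in genes}
            )
        profiles.append(profile)

    records = []
    truth = {}
    score_cache: dict[tuple[tuple[str, int], ...], float] = {}
    for i, profile in enumerate(profiles):
        pid = f"P{i + 1:03d}"
        if profile.clamps not in score_cache:
            score_cache[profile.clamps] = network_score(model, profile, config)
        score = score_cache[profile.clamps]
        clinical = clinical_offset + clinical_scale * score
        if sigma > 0:
            clinical += rng.normal(0.0, sigma)
        records.append(CohortRecord(patient_id=pid, profile=profile,
                                    clinical_value=float(clinical)))
        truth[pid] = score
    return records, pd.Series(truth, name="true_score")


def cohort_to_frames(
    cohort: list[CohortRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy CSV-ready frames: (patient_id,gene,clamp) and (patient_id,clinical_value)."""
    mut_rows = []
    clin_rows = []
    for rec in cohort:
        for gene, clamp in rec.profile.clamps:
            mut_rows.append({"patient_id": rec.patient_id, "gene": gene, "clamp": clamp})
        clin_rows.append({"patient_id": rec.patient_id, "clinical_value": rec.clinical_value})
    return pd.DataFrame(mut_rows), pd.DataFrame(clin_rows)
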