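"""Desk-scale synthetic cohorts with the statistical structure of the
neuroblastoma study data.

The generator emulates a cohort of n patients carrying:

* two phi-correlated binary outcomes — the 5-year survival class and the
  vital status — drawn from an exact 2x2 joint distribution built from the
  two marginal prevalences and a target phi coefficient (defaults mirror
  the real cohort: 42/88 long-term survivors, 37/88 alive, phi = 0.85);
* a clinical table (age at diagnosis, INSS stage, MYCN status, gender,
  race, risk group) whose category probabilities depend on outcome, plus a
  survival time consistent with the survival label around the 5-year
  threshold;
* a gene-expression block (Gaussian features; planted informative features
  are class-shifted by ``delta``) and a DNA-methylation block (Beta
  features in [0, 1] with class-dependent means), each with planted
  shared-signal, task-specific, redundant near-duplicate, and null
  features.

Redundant features are a parent informative feature plus N(0, sigma) noise,
so at small sigma they are near-perfect MAC partners of their parent — the
structure the redundancy-removal step is meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import ClinicalTable, LabelPair, OmicsMatrix

__all__ = ["BlockCounts", "SynthConfig", "joint_from_phi", "generate"]


@dataclass(frozen=True)
class BlockCounts:
    """Planted feature composition of one omics block."""

    informative_shared: int = 4
    informative_task1: int = 4  # survival-specific
    informative_task2: int = 4  # vital-specific
    redundant_copies: int = 6
    nulls: int = 82

    @property
    def n_informative(self) -> int:
        return self.informative_shared + self.informative_task1 + self.informative_task2

    @property
    def total(self) -> int:
        return self.n_informative + self.redundant_copies + self.nulls


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition defaults for the synthetic cohort.

    The label marginals and inter-label correlation mirror the real cohort
    (a = 42/88 long-term, b = 37/88 alive, phi = 0.85) so the synthetic
    cohort is a drop-in stand-in at the same n = 88.
    """

    n_samples: int = 88
    p_survival_long: float = 42 / 88
    p_alive: float = 37 / 88
    phi: float = 0.85
    expression_counts: BlockCounts = field(default_factory=BlockCounts)
    methylation_counts: BlockCounts = field(
        default_factory=lambda: BlockCounts(nulls=132)
    )
    delta: float = 1.0  # class shift of informative expression features (SD units)
    sigma: float = 0.05  # noise SD added to redundant near-duplicates
    #: Beta means for methylation informative features by class (precision 10)
    beta_mean_class0: float = 0.35
    beta_mean_class1: float = 0.65
    beta_precision: float = 10.0
    threshold_years: float = 5.0
    seed: int = 0


def joint_from_phi(a: float, b: float, phi: float) -> np.ndarray:
    """2x2 joint P[(A, B)] with marginals P(A=1)=a, P(B=1)=b and phi coefficient.

    Returns the table [[P00, P01], [P10, P11]] built as
    P11 = a*b + c, P10 = a(1-b) - c, P01 = (1-a)b - c, P00 = (1-a)(1-b) + c
    with c = phi * sqrt(a*b*(1-a)*(1-b)). Raises if any cell would be
    negative, reporting the feasible phi bound for these marginals.
    """
    if not (0.0 < a < 1.0 and 0.0 < b < 1.0):
        raise ValueError("marginals must be in (0, 1)")
    c = phi * np.sqrt(a * b * (1 - a) * (1 - b))
    p11 = a * b + c
    p10 = a * (1 - b) - c
    p01 = (1 - a) * b - c
    p00 = (1 - a) * (1 - b) + c
    table = np.array([[p00, p01], [p10, p11]])
    if (table < -1e-12).any():
        lo, hi = phi_bounds(a, b)
        raise ValueError(
            f"phi = {phi} infeasible for marginals ({a:.4f}, {b:.4f}); "
            f"feasible range is [{lo:.4f}, {hi:.4f}]"
        )
    return np.clip(table, 0.0, 1.0)


def phi_bounds(a: float, b: float) -> tuple[float, float]:
    """Feasible phi range for a 2x2 table with marginals a and b."""
    denom = np.sqrt(a * b * (1 - a) * (1 - b))
    hi = min(a * (1 - b), (1 - a) * b) / denom
    lo = -min(a * b, (1 - a) * (1 - b)) / denom
    return float(lo), float(hi)


def sample_label_pair(
    n: int, a: float, b: float, phi: float, rng: np.random.Generator,
    threshold_years: float = 5.0,
) -> LabelPair:
    """Draw n i.i.d. (survival, vital) label pairs from the phi-joint."""
    table = joint_from_phi(a, b, phi)
    probs = table.ravel()  # order: (0,0), (0,1), (1,0), (1,1)
    draws = rng.choice(4, size=n, p=probs / probs.sum())
    survival = draws // 2
    vital = draws % 2
    return LabelPair(survival, vital, threshold_years)


def _expression_block(
    labels: LabelPair, counts: BlockCounts, delta: float, sigma: float,
    rng: np.random.Generator, prefix: str,
) -> tuple[OmicsMatrix, dict[str, list[str]]]:
    n = len(labels)
    s = labels.survival_label.astype(float)
    v = labels.vital_label.astype(float)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    roles: dict[str, list[str]] = {"informative": [], "redundant": [], "null": []}

    def add(name: str, col: np.ndarray, role: str) -> None:
        ids.append(name)
        cols.append(col)
        roles[role].append(name)

    for i in range(counts.informative_shared):
        add(f"{prefix}_shared_{i}", rng.normal(size=n) + delta * (s + v) / 2, "informative")
    for i in range(counts.informative_task1):
        add(f"{prefix}_surv_{i}", rng.normal(size=n) + delta * s, "informative")
    for i in range(counts.informative_task2):
        add(f"{prefix}_vital_{i}", rng.normal(size=n) + delta * v, "informative")
    parents = list(cols)  # informative features, in order
    for i in range(counts.redundant_copies):
        parent = parents[i % len(parents)]
        add(f"{prefix}_dup_{i}", parent + rng.normal(scale=sigma, size=n), "redundant")
    for i in range(counts.nulls):
        add(f"{prefix}_null_{i}", rng.normal(size=n), "null")
    m = OmicsMatrix(
        [f"S{j:04d}" for j in range(n)], ids, np.column_stack(cols), modality="expression"
    )
    return m, roles


def _methylation_block(
    labels: LabelPair, counts: BlockCounts, cfg: SynthConfig,
    rng: np.random.Generator, prefix: str,
) -> tuple[OmicsMatrix, dict[str, list[str]]]:
    n = len(labels)
    s = labels.survival_label.astype(float)
    v = labels.vital_label.astype(float)
    nu = cfg.beta_precision
    m0, m1 = cfg.beta_mean_class0, cfg.beta_mean_class1
    cols: list[np.ndarray] = []
    ids: list[str] = []
    roles: dict[str, list[str]] = {"informative": [], "redundant": [], "null": []}

    def beta_for(frac: np.ndarray) -> np.ndarray:
        # per-sample Beta draw with mean interpolated between the class means
        mean = m0 + (m1 - m0) * frac
        return rng.beta(mean * nu, (1 - mean) * nu)

    def add(name: str, col: np.ndarray, role: str) -> None:
        ids.append(name)
        cols.append(col)
        roles[role].append(name)

    for i in range(counts.informative_shared):
        add(f"{prefix}_shared_{i}", beta_for((s + v) / 2), "informative")
    for i in range(counts.informative_task1):
        add(f"{prefix}_surv_{i}", beta_for(s), "informative")
    for i in range(counts.informative_task2):
        add(f"{prefix}_vital_{i}", beta_for(v), "informative")
    parents = list(cols)
    for i in range(counts.redundant_copies):
        parent = parents[i % len(parents)]
        noisy = np.clip(parent + rng.normal(scale=cfg.sigma, size=n), 0.0, 1.0)
        add(f"{prefix}_dup_{i}", noisy, "redundant")
    for i in range(counts.nulls):
        add(f"{prefix}_null_{i}", rng.beta(0.5 * nu, 0.5 * nu, size=n), "null")
    m = OmicsMatrix(
        [f"S{j:04d}" for j in range(n)], ids, np.column_stack(cols), modality="methylation"
    )
    return m, roles


def _clinical_table(
    labels: LabelPair, cfg: SynthConfig, rng: np.random.Generator
) -> ClinicalTable:
    n = len(labels)
    s = labels.survival_label
    v = labels.vital_label
    poor = (s == 0) & (v == 0)

    # age at diagnosis: older children fare worse (lognormal, days)
    age_mean = np.where(poor, 7.2, 6.6)  # log-days: ~1340 vs ~735 days
    age_days = np.round(rng.lognormal(mean=age_mean, sigma=0.5)).astype(int)

    # INSS stage: poor outcomes concentrate in stage 4
    stage_probs_poor = {"1": 0.03, "2": 0.02, "3": 0.05, "4": 0.88, "4S": 0.02}
    stage_probs_good = {"1": 0.25, "2": 0.10, "3": 0.10, "4": 0.45, "4S": 0.10}
    stages = np.empty(n, dtype=object)
    for i in range(n):
        p = stage_probs_poor if poor[i] else stage_probs_good
        stages[i] = rng.choice(list(p.keys()), p=list(p.values()))

    mycn = np.where(
        rng.random(n) < np.where(poor, 0.45, 0.15), "amplified", "not amplified"
    )
    unknown_mask = rng.random(n) < 0.05
    mycn = np.where(unknown_mask, "unknown", mycn)

    gender = np.where(rng.random(n) < 51 / 88, "male", "female")
    race = rng.choice(
        ["White", "Black or African American", "Unknown",
         "Native Hawaiian or other Pacific Islander", "Asian"],
        size=n,
        p=[69 / 88, 9 / 88, 7 / 88, 2 / 88, 1 / 88],
    )
    risk = np.where(stages == "4", "high", np.where(rng.random(n) < 0.3, "high", "low"))

    thr = cfg.threshold_years
    surv_years = np.where(
        s == 1,
        thr + rng.exponential(scale=2.0, size=n),
        rng.uniform(0.2, thr, size=n),
    )
    surv_years = np.round(surv_years, 4)
    # rounding must not push a short-term time onto the threshold
    surv_years = np.where(s == 0, np.minimum(surv_years, thr - 1e-4), surv_years)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{j:04d}" for j in range(n)],
            "age_days": age_days,
            "inss_stage": stages.astype(str),
            "mycn_status": mycn,
            "survival_years": surv_years,
            "vital_status": np.where(v == 1, "alive", "dead"),
            "gender": gender,
            "race": race,
            "risk_group": risk,
        }
    )
    return ClinicalTable(df)


@dataclass
class SyntheticCohort:
    """Everything :func:`generate` produces, plus the planted ground truth."""

    clinical: ClinicalTable
    expression: OmicsMatrix
    methylation: OmicsMatrix
    labels: LabelPair
    expression_roles: dict[str, list[str]]
    methylation_roles: dict[str, list[str]]


def generate(cfg: SynthConfig | None = None) -> SyntheticCohort:
    """Generate a fully reproducible synthetic cohort from ``cfg.seed``."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    labels = sample_label_pair(
        cfg.n_samples, cfg.p_survival_long, cfg.p_alive, cfg.phi, rng,
        cfg.threshold_years,
    )
    expr, expr_roles = _expression_block(
        labels, cfg.expression_counts, cfg.delta, cfg.sigma, rng, "G"
    )
    meth, meth_roles = _methylation_block(labels, cfg.methylation_counts, cfg, rng, "M")
    clinical = _clinical_table(labels, cfg, rng)
    return SyntheticCohort(
        clinical=clinical,
        expression=expr,
        methylation=meth,
        labels=labels,
        expression_roles=expr_roles,
        methylation_roles=meth_roles,
    )
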