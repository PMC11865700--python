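"""Synthetic competing-risks data generators with exposed ground truth.

Two designs are provided:

* a high-dimensional block-correlated design emulating gene-expression
  data (n = 400, p = 5000 at defaults): standard-normal covariates with a
  shared-factor block structure, effects of +/-0.5 placed so that block 1
  carries effects shared by both causes, block 2 opposing effects, block 3
  cause-disjoint effects, and blocks 4 / the remainder pure noise;
* a low-dimensional proof-of-concept design (n = 1000, p = 14) with four
  scenarios (A-D) differing in how much effect information the two causes
  share, and baseline hazards calibrated to stated status prevalences.

Event times follow the inverse-transform construction for an exponential
baseline: ``T_ik = -log(U_ik) / (lambda * exp(x_i' beta_k))`` for each cause
and an independent exponential censoring time; the observed time is the
minimum and the status records which latent time won (0 = censoring).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .cox_core import SurvivalDataset

__all__ = [
    "BlockSpec",
    "HighDimConfig",
    "PoCScenario",
    "SimulatedDataset",
    "default_highdim_blocks",
    "gen_block_covariates",
    "gen_highdim_dataset",
    "gen_poc_dataset",
    "calibrate_poc",
    "POC_SCENARIOS",
]


@dataclass
class BlockSpec:
    """One correlated covariate block and its per-cause effects.

    Effect lists may be shorter than the block; unlisted features have
    effect 0.  ``sublabels`` optionally partitions the block into named
    evaluation sub-blocks (label, count).
    """

    name: str
    size: int
    rho: float
    effects_cause1: list[float] = field(default_factory=list)
    effects_cause2: list[float] = field(default_factory=list)
    sublabels: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"block {self.name}: rho must lie in [0, 1)")
        if len(self.effects_cause1) > self.size or len(self.effects_cause2) > self.size:
            raise ValueError(f"block {self.name}: effect vector longer than the block")
        if self.sublabels is not None and sum(c for _, c in self.sublabels) != self.size:
            raise ValueError(f"block {self.name}: sublabels must partition the block")

    def labels(self) -> list[str]:
        if self.sublabels is None:
            return [self.name] * self.size
        out: list[str] = []
        for lab, count in self.sublabels:
            out.extend([lab] * count)
        return out

    def effects(self, cause: int) -> np.ndarray:
        eff = self.effects_cause1 if cause == 1 else self.effects_cause2
        out = np.zeros(self.size)
        out[: len(eff)] = eff
        return out


def default_highdim_blocks() -> list[BlockSpec]:
    """Block layout of the high-dimensional design.

    B1 "mutual": 4 shared effects; B2 "reversed": 4 opposing effects; B3
    (one weakly correlated block of 500, scored as sub-blocks B3.1/B3.2):
    4 cause-1-only and 4 cause-2-only effects; B4: correlated noise.  All
    effects are +/-0.5 on the first features of their (sub-)block.
    """
    return [
        BlockSpec("B1", 250, 0.5, [0.5] * 4, [0.5] * 4),
        BlockSpec("B2", 250, 0.35, [0.5] * 4, [-0.5] * 4),
        BlockSpec("B3", 500, 0.05,
                  effects_cause1=[-0.5] * 4,
                  effects_cause2=[0.0] * 250 + [0.5] * 4,
                  sublabels=[("B3.1", 250), ("B3.2", 250)]),
        BlockSpec("B4", 500, 0.32),
    ]


@dataclass
class HighDimConfig:
    """Configuration of the high-dimensional block-correlated design."""

    n: int = 400
    blocks: list[BlockSpec] = field(default_factory=default_highdim_blocks)
    n_uncorrelated_noise: int = 3500
    baseline_hazard: float = 0.1
    censoring_hazard: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.censoring_hazard <= 0:
            raise ValueError("hazard rates must be positive")
        if self.n < 2 or self.n_uncorrelated_noise < 0:
            raise ValueError("invalid sizes")

    @property
    def p(self) -> int:
        return sum(b.size for b in self.blocks) + self.n_uncorrelated_noise


@dataclass
class SimulatedDataset:
    """A survival dataset together with its generating truth."""

    data: SurvivalDataset
    beta1_true: np.ndarray
    beta2_true: np.ndarray
    block_label: np.ndarray

    def beta_true(self, cause: int) -> np.ndarray:
        if cause == 1:
            return self.beta1_true
        if cause == 2:
            return self.beta2_true
        raise ValueError(f"unknown cause {cause!r}")


def gen_block_covariates(n: int, blocks: list[BlockSpec], n_noise: int,
                         rng: np.random.Generator | int) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal covariates with exact within-block correlation rho.

    Within a block, ``x_j = sqrt(rho) * f + sqrt(1 - rho) * e_j`` with one
    shared standard-normal factor f per block: every marginal is N(0, 1) and
    every within-block pair has correlation exactly rho in expectation.
    Trailing noise features are i.i.d. N(0, 1).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for b in blocks:
        f = rng.standard_normal((n, 1))
        e = rng.standard_normal((n, b.size))
        cols.append(np.sqrt(b.rho) * f + np.sqrt(1.0 - b.rho) * e)
        labels.extend(b.labels())
    if n_noise > 0:
        cols.append(rng.standard_normal((n, n_noise)))
        labels.extend(["noise"] * n_noise)
    return np.hstack(cols), np.asarray(labels)


def _latent_competing_times(rng: np.random.Generator, s1: np.ndarray, s2: np.ndarray,
                            lam1: float, lam2: float,
                            lam_c: float) -> tuple[np.ndarray, np.ndarray]:
    """Observed (time, status) from latent exponential cause and censoring times."""
    n = s1.shape[0]
    u = rng.uniform(size=(n, 3))
    t1 = -np.log(u[:, 0]) / (lam1 * np.exp(s1))
    t2 = -np.log(u[:, 1]) / (lam2 * np.exp(s2))
    c = -np.log(u[:, 2]) / lam_c
    stacked = np.column_stack([c, t1, t2])
    status = np.argmin(stacked, axis=1)
    time = stacked[np.arange(n), status]
    return time, status.astype(np.int64)


def gen_highdim_dataset(config: HighDimConfig | None = None, **overrides) -> SimulatedDataset:
    """Generate one replicate of the high-dimensional design."""
    if config is None:
        config = HighDimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config object or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    X, labels = gen_block_covariates(config.n, config.blocks,
                                     config.n_uncorrelated_noise, rng)
    beta1 = np.concatenate([b.effects(1) for b in config.blocks]
                           + [np.zeros(config.n_uncorrelated_noise)])
    beta2 = np.concatenate([b.effects(2) for b in config.blocks]
                           + [np.zeros(config.n_uncorrelated_noise)])
    time, status = _latent_competing_times(
        rng, X @ beta1, X @ beta2,
        config.baseline_hazard, config.baseline_hazard, config.censoring_hazard)
    names = [f"{lab}_{j + 1}" for j, lab in enumerate(labels)]
    ds = SurvivalDataset(time=time, status=status, X=X, feature_names=names)
    return SimulatedDataset(data=ds, beta1_true=beta1, beta2_true=beta2,
                            block_label=labels)


# ---------------------------------------------------------------------------
# proof-of-concept design


@dataclass
class PoCScenario:
    """One low-dimensional scenario: 3 candidate effects + 11 noise features."""

    id: str
    effects_cause1: tuple[float, ...]
    effects_cause2: tuple[float, ...]
    target_prevalence: tuple[float, float]
    n: int = 1000
    p: int = 14

    def beta(self, cause: int) -> np.ndarray:
        eff = self.effects_cause1 if cause == 1 else self.effects_cause2
        out = np.zeros(self.p)
        out[: len(eff)] = eff
        return out


POC_SCENARIOS: dict[str, PoCScenario] = {
    "A": PoCScenario("A", (1.0,), (1.0,), (0.35, 0.35)),
    "B": PoCScenario("B", (1.0,), (0.0, 1.0), (0.35, 0.35)),
    "C": PoCScenario("C", (1.0,), (0.25,), (0.55, 0.07)),
    "D": PoCScenario("D", (1.0, 0.75, -0.5), (1.0, 0.75, -0.5), (0.55, 0.07)),
}

# lazily filled cache of calibrated (h01, h02, censor_rate) per scenario id
_POC_RATES: dict[str, tuple[float, float, float]] = {}
_CALIBRATION_SEED = 202409
_CALIBRATION_DRAWS = 50_000


def calibrate_poc(scenario: PoCScenario | str, n_draws: int = _CALIBRATION_DRAWS,
                  tol: float = 0.015) -> tuple[float, float, float]:
    """Baseline hazards and censoring rate matching a scenario's prevalences.

    With constant cause-specific hazards ``h_k exp(x' beta_k)`` and
    exponential censoring at rate c, the status probabilities given x are
    the rate ratios, so the expected prevalences are smooth functions of
    (h01, h02) evaluated exactly over a fixed Monte-Carlo sample of
    covariates (internal seed, >= 50 000 draws).  Proportions depend on the
    rates only through ratios, so the censoring rate is fixed at 1 and the
    two baseline hazards are solved for by a root finder.
    """
    sc = POC_SCENARIOS[scenario] if isinstance(scenario, str) else scenario
    rng = np.random.default_rng(_CALIBRATION_SEED)
    x3 = rng.uniform(-3.0, 3.0, size=(n_draws, 3))
    b1 = sc.beta(1)[:3]
    b2 = sc.beta(2)[:3]
    s1 = x3 @ b1
    s2 = x3 @ b2
    t1, t2 = sc.target_prevalence

    def props(log_h: np.ndarray) -> np.ndarray:
        r1 = np.exp(log_h[0] + s1)
        r2 = np.exp(log_h[1] + s2)
        tot = r1 + r2 + 1.0
        return np.array([np.mean(r1 / tot), np.mean(r2 / tot)])

    pc = max(1.0 - t1 - t2, 0.05)
    x0 = np.log(np.array([t1, t2]) / pc)
    sol = optimize.root(lambda lh: props(lh) - np.array([t1, t2]), x0, method="hybr")
    achieved = props(sol.x)
    if not sol.success or np.max(np.abs(achieved - np.array([t1, t2]))) > tol:
        raise RuntimeError(
            f"calibration failed for scenario {sc.id}: targets {(t1, t2)}, "
            f"achieved {tuple(np.round(achieved, 4))}, solver: {sol.message}")
    return float(np.exp(sol.x[0])), float(np.exp(sol.x[1])), 1.0


def _poc_rates(sc: PoCScenario) -> tuple[float, float, float]:
    if sc.id not in _POC_RATES:
        _POC_RATES[sc.id] = calibrate_poc(sc)
    return _POC_RATES[sc.id]


def gen_poc_dataset(scenario: PoCScenario | str, seed: int,
                    n: int | None = None) -> SimulatedDataset:
    """Generate one replicate of a proof-of-concept scenario.

    The three candidate covariates are uniform on [-3, 3]; the 11 noise
    covariates are independent standard normal.  Baseline hazards come from
    the cached calibration for the scenario's stated prevalences.
    """
    sc = POC_SCENARIOS[scenario] if isinstance(scenario, str) else scenario
    h01, h02, cens = _poc_rates(sc)
    n = sc.n if n is None else n
    rng = np.random.default_rng(seed)
    x3 = rng.uniform(-3.0, 3.0, size=(n, 3))
    noise = rng.standard_normal((n, sc.p - 3))
    X = np.hstack([x3, noise])
    b1, b2 = sc.beta(1), sc.beta(2)
    time, status = _latent_competing_times(rng, X @ b1, X @ b2, h01, h02, cens)
    labels = np.asarray(["signal"] * 3 + ["noise"] * (sc.p - 3))
    names = [f"X{j + 1}" for j in range(sc.p)]
    ds = SurvivalDataset(time=time, status=status, X=X, feature_names=names)
    return SimulatedDataset(data=ds, beta1_true=b1, beta2_true=b2, block_label=labels)
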