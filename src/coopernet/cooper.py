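"""Cooperative penalized regression (CooPeR) for two competing events.

Two cause-specific feature-weighted Cox elastic nets are fit alternately:
after an initialization with plain cross-validated elastic nets
(``lambda.min``), each iteration first refits cause 2 using the magnitudes
of cause 1's current coefficients as prior relevance scores, then refits
cause 1 with the magnitudes of the fresh cause-2 coefficients.  Coefficients
shrunk to zero in one model thereby raise the complementary model's penalty
on the same feature, so shared effects are mutually amplified and noise is
suppressed in both models.  Iteration stops when the L2 change of both
coefficient vectors falls below ``epsilon`` or after ``mt_max_iter`` rounds.

Prior scores are the absolute coefficient values: the weight function reacts
to relative magnitudes only, and a protective (negative) effect is evidence
of relevance, not irrelevance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cox_core import SurvivalDataset
from .fwcoxnet import FwcoxnetFit, PenaltyConfig, fit_fwcoxnet

logger = logging.getLogger(__name__)

__all__ = [
    "CooperConfig",
    "CooperFit",
    "fit_cooper",
    "extract_coefficients",
    "shared_selection",
    "convergence_check",
]


@dataclass
class CooperConfig:
    """Settings for one CooPeR run.

    ``mt_max_iter`` bounds the outer alternations (0 reduces the method to
    the two initial plain elastic nets); ``epsilon`` is the L2 stopping
    threshold on consecutive coefficient vectors.  ``penalty`` is shared by
    both cause-specific models; the seed drives data-independent choices
    (CV fold draws) through a deterministic stream split.
    """

    mt_max_iter: int = 3
    epsilon: float = 1e-8
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mt_max_iter < 0:
            raise ValueError("mt_max_iter must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class CooperFit:
    """Final and initial cause-specific fits with the iteration history."""

    fit_cause1: FwcoxnetFit
    fit_cause2: FwcoxnetFit
    initial_fit_cause1: FwcoxnetFit
    initial_fit_cause2: FwcoxnetFit
    history: list[tuple[np.ndarray, np.ndarray]]
    n_iterations_run: int
    converged: bool


def convergence_check(history: list[tuple[np.ndarray, np.ndarray]],
                      epsilon: float) -> bool:
    """True iff ||beta_k^(last) - beta_k^(last-1)||_2 < epsilon for both causes."""
    if len(history) < 2:
        raise ValueError("need at least two history entries")
    (b1_prev, b2_prev), (b1, b2) = history[-2], history[-1]
    if b1.shape != b1_prev.shape or b2.shape != b2_prev.shape:
        raise ValueError("coefficient vectors in the history differ in length")
    return (float(np.linalg.norm(b1 - b1_prev)) < epsilon
            and float(np.linalg.norm(b2 - b2_prev)) < epsilon)


def fit_cooper(data: SurvivalDataset, config: CooperConfig | None = None) -> CooperFit:
    """Run the cooperative alternation on a two-cause competing-risks dataset."""
    cfg = config or CooperConfig()
    view1 = data.cause_view(1)
    view2 = data.cause_view(2)
    for view in (view1, view2):
        if view.n_events == 0:
            raise ValueError(f"cause {view.cause} has no events; CooPeR needs both causes observed")

    ss = np.random.SeedSequence(cfg.seed)
    # one fold seed per inner fit: 2 initial + 2 per outer iteration
    n_seeds = 2 + 2 * max(cfg.mt_max_iter, 0)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(max(n_seeds, 1))]
    seed_iter = iter(seeds)

    init1 = fit_fwcoxnet(view1, data.X, z=None, config=cfg.penalty,
                         seed=next(seed_iter), feature_names=data.feature_names)
    init2 = fit_fwcoxnet(view2, data.X, z=None, config=cfg.penalty,
                         seed=next(seed_iter), feature_names=data.feature_names)

    b1, b2 = init1.beta.copy(), init2.beta.copy()
    history: list[tuple[np.ndarray, np.ndarray]] = [(b1.copy(), b2.copy())]
    fit1, fit2 = init1, init2
    converged = False
    n_run = 0
    for it in range(cfg.mt_max_iter):
        try:
            # cause 2 first, informed by |beta_1|; then cause 1 by the fresh |beta_2|
            fit2 = fit_fwcoxnet(view2, data.X, z=np.abs(b1), config=cfg.penalty,
                                seed=next(seed_iter), feature_names=data.feature_names)
            b2 = fit2.beta.copy()
            fit1 = fit_fwcoxnet(view1, data.X, z=np.abs(b2), config=cfg.penalty,
                                seed=next(seed_iter), feature_names=data.feature_names)
            b1 = fit1.beta.copy()
        except ValueError as err:
            raise ValueError(f"inner fit failed in CooPeR iteration {it + 1}: {err}") from err
        history.append((b1.copy(), b2.copy()))
        n_run = it + 1
        logger.info("CooPeR iteration %d: |db1|=%.3g |db2|=%.3g", n_run,
                    float(np.linalg.norm(history[-1][0] - history[-2][0])),
                    float(np.linalg.norm(history[-1][1] - history[-2][1])))
        if convergence_check(history, cfg.epsilon):
            converged = True
            break
    return CooperFit(
        fit_cause1=fit1,
        fit_cause2=fit2,
        initial_fit_cause1=init1,
        initial_fit_cause2=init2,
        history=history,
        n_iterations_run=n_run,
        converged=converged,
    )


def extract_coefficients(fit: CooperFit, cause: int,
                         use_initial_fit: bool = False) -> dict[str, float]:
    """Sparse nonzero coefficients of the requested cause-specific model.

    ``use_initial_fit=True`` returns the step-1 plain elastic-net (Coxnet
    baseline) coefficients instead of the cooperative ones.
    """
    if cause == 1:
        f = fit.initial_fit_cause1 if use_initial_fit else fit.fit_cause1
    elif cause == 2:
        f = fit.initial_fit_cause2 if use_initial_fit else fit.fit_cause2
    else:
        raise ValueError(f"unknown cause code {cause!r}; expected 1 or 2")
    return f.nonzero()


def shared_selection(fit: CooperFit, use_initial_fit: bool = False) -> list[str]:
    """Features selected (nonzero) by both cause-specific models."""
    s1 = set(extract_coefficients(fit, 1, use_initial_fit))
    s2 = set(extract_coefficients(fit, 2, use_initial_fit))
    return sorted(s1 & s2)
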