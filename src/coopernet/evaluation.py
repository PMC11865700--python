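"""Variable-selection scoring and the replicated benchmark harness.

Selection is judged per cause and per covariate block: a feature counts as
selected when its estimated coefficient is nonzero (or, for importance-based
methods, when its importance exceeds the magnitude of the most negative
importance), and as a positive when its true effect for that cause is
nonzero.  PPV = TP/(TP+FP) and FPR = FP/(FP+TN) are the primary metrics;
PPV is undefined (NaN) in blocks without true positives for the cause, or
when nothing was selected.  Replicates are aggregated by median and
quartiles (linear-interpolation / type-7 quantiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cooper import CooperConfig, fit_cooper
from .simulators import HighDimConfig, SimulatedDataset, gen_highdim_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "SelectionMetrics",
    "BenchmarkResult",
    "classify_selection",
    "compute_metrics",
    "coefficient_bias",
    "threshold_importance",
    "run_benchmark",
]


@dataclass
class ConfusionCounts:
    """Selection confusion counts within one (cause, block) cell."""

    tp: int
    fp: int
    tn: int
    fn: int
    cause: int
    block: str

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def size(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SelectionMetrics:
    """PPV / FPR / TPR / F1; NaN encodes "not defined", never an error."""

    ppv: float
    fpr: float
    tpr: float
    f1: float


def classify_selection(beta_hat: np.ndarray, truth: SimulatedDataset,
                       cause: int) -> dict[str, ConfusionCounts]:
    """Per-block confusion counts for one cause-specific selection.

    ``beta_hat`` may be a coefficient vector (nonzero = selected) or a
    binary selection vector.
    """
    beta_hat = np.asarray(beta_hat)
    labels = np.asarray(truth.block_label)
    if beta_hat.shape[0] != labels.shape[0]:
        raise ValueError("beta_hat length does not match the number of features")
    if labels.size == 0:
        raise ValueError("block labels missing from the simulated dataset")
    selected = beta_hat != 0
    positive = truth.beta_true(cause) != 0
    out: dict[str, ConfusionCounts] = {}
    for block in dict.fromkeys(labels):  # preserves block order
        m = labels == block
        out[block] = ConfusionCounts(
            tp=int(np.sum(selected & positive & m)),
            fp=int(np.sum(selected & ~positive & m)),
            tn=int(np.sum(~selected & ~positive & m)),
            fn=int(np.sum(~selected & positive & m)),
            cause=cause,
            block=block,
        )
    return out


def compute_metrics(counts: ConfusionCounts) -> SelectionMetrics:
    """PPV, FPR, TPR and F1 from confusion counts; undefined cells are NaN.

    PPV is undefined when nothing was selected or when the block holds no
    true positives for the cause (only FPR is meaningful there).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    has_positives = (tp + fn) > 0
    ppv = tp / (tp + fp) if (tp + fp) > 0 and has_positives else np.nan
    fpr = fp / (fp + tn) if (fp + tn) > 0 else np.nan
    tpr = tp / (tp + fn) if has_positives else np.nan
    if np.isnan(ppv) or np.isnan(tpr) or (ppv + tpr) == 0:
        f1 = np.nan
    else:
        f1 = 2.0 * ppv * tpr / (ppv + tpr)
    return SelectionMetrics(ppv=ppv, fpr=fpr, tpr=tpr, f1=f1)


def coefficient_bias(beta_hat: np.ndarray, beta_true: np.ndarray) -> np.ndarray:
    """Elementwise estimation error beta_true - beta_hat."""
    beta_hat = np.asarray(beta_hat, dtype=np.float64)
    beta_true = np.asarray(beta_true, dtype=np.float64)
    if beta_hat.shape != beta_true.shape:
        raise ValueError("coefficient vectors differ in length")
    return beta_true - beta_hat


def threshold_importance(v: np.ndarray) -> np.ndarray:
    """Binary selection from an importance vector: keep v_j > |min v|.

    The magnitude of the most negative importance serves as an estimate of
    the noise level of the importance measure.
    """
    v = np.asarray(v, dtype=np.float64)
    return (v > np.abs(v.min())).astype(np.float64)


@dataclass
class BenchmarkResult:
    """Per-replicate selection metrics in long format plus aggregation."""

    rows: pd.DataFrame
    seeds: list[int]
    n_failures: int = 0

    def aggregate(self) -> pd.DataFrame:
        """Median / quartiles per method x cause x block x metric.

        Quantiles use linear interpolation (numpy's default, type 7); the
        IQR is reported both as q75 - q25 and through the quartile pair.
        """
        long = self.rows.melt(
            id_vars=["replicate", "method", "cause", "block"],
            value_vars=["ppv", "fpr", "tpr", "f1"],
            var_name="metric", value_name="value")
        grouped = long.groupby(["method", "cause", "block", "metric"])["value"]
        agg = grouped.agg(
            median=lambda s: np.nanmedian(s) if s.notna().any() else np.nan,
            q25=lambda s: np.nanquantile(s, 0.25) if s.notna().any() else np.nan,
            q75=lambda s: np.nanquantile(s, 0.75) if s.notna().any() else np.nan,
            n_defined="count",
        ).reset_index()
        agg["iqr"] = agg["q75"] - agg["q25"]
        return agg


def _rows_for(beta_by_cause: dict[int, np.ndarray], sim: SimulatedDataset,
              replicate: int, method: str) -> list[dict]:
    rows = []
    for cause, vec in beta_by_cause.items():
        for block, counts in classify_selection(vec, sim, cause).items():
            m = compute_metrics(counts)
            rows.append({
                "replicate": replicate, "method": method, "cause": cause,
                "block": block, "tp": counts.tp, "fp": counts.fp,
                "tn": counts.tn, "fn": counts.fn,
                "ppv": m.ppv, "fpr": m.fpr, "tpr": m.tpr, "f1": m.f1,
            })
    return rows


def run_benchmark(design: str = "highdim",
                  methods: tuple[str, ...] = ("cooper", "coxnet"),
                  n_replicates: int = 10,
                  base_seed: int = 0,
                  highdim_config: HighDimConfig | None = None,
                  cooper_config: CooperConfig | None = None,
                  adapters: dict[str, Callable] | None = None,
                  importance_adapters: frozenset[str] | set[str] = frozenset(),
                  ) -> BenchmarkResult:
    """Replicated variable-selection benchmark.

    Replicate r (1-based) simulates with seed ``base_seed + r`` and fits
    every requested method on the same dataset.  The built-in methods come
    from a single cooperative run per replicate: ``cooper`` scores the final
    fits and ``coxnet`` the initial plain elastic-net fits, so the baseline
    is exactly the initialization of the cooperative algorithm.  External
    adapters map ``(SimulatedDataset, seed)`` to per-cause vectors; names in
    ``importance_adapters`` are thresholded by the v_j > |min v| rule before
    classification.  Failing replicates of a method are recorded and
    skipped.
    """
    if design != "highdim":
        raise ValueError(f"unknown benchmark design {design!r}")
    adapters = adapters or {}
    unknown = [m for m in methods if m not in ("cooper", "coxnet") and m not in adapters]
    if unknown:
        raise ValueError(f"no adapter for methods {unknown}")
    base_cfg = highdim_config or HighDimConfig()
    rows: list[dict] = []
    seeds: list[int] = []
    n_failures = 0
    needs_cooper = "cooper" in methods or "coxnet" in methods
    for r in range(1, n_replicates + 1):
        seed = base_seed + r
        seeds.append(seed)
        cfg = HighDimConfig(n=base_cfg.n, blocks=base_cfg.blocks,
                            n_uncorrelated_noise=base_cfg.n_uncorrelated_noise,
                            baseline_hazard=base_cfg.baseline_hazard,
                            censoring_hazard=base_cfg.censoring_hazard,
                            seed=seed)
        sim = gen_highdim_dataset(cfg)
        if needs_cooper:
            ccfg = cooper_config or CooperConfig()
            ccfg = CooperConfig(mt_max_iter=ccfg.mt_max_iter, epsilon=ccfg.epsilon,
                                penalty=ccfg.penalty, seed=seed)
            try:
                fit = fit_cooper(sim.data, ccfg)
            except Exception:
                logger.exception("cooperative fit failed on replicate %d", r)
                n_failures += 1
                fit = None
            if fit is not None:
                if "cooper" in methods:
                    rows += _rows_for({1: fit.fit_cause1.beta, 2: fit.fit_cause2.beta},
                                      sim, r, "cooper")
                if "coxnet" in methods:
                    rows += _rows_for({1: fit.initial_fit_cause1.beta,
                                       2: fit.initial_fit_cause2.beta},
                                      sim, r, "coxnet")
        for name, adapter in adapters.items():
            if name not in methods:
                continue
            try:
                vectors = adapter(sim, seed)
            except Exception:
                logger.exception("adapter %s failed on replicate %d", name, r)
                n_failures += 1
                continue
            if name in importance_adapters:
                vectors = {k: threshold_importance(v) for k, v in vectors.items()}
            rows += _rows_for(vectors, sim, r, name)
    return BenchmarkResult(rows=pd.DataFrame(rows), seeds=seeds, n_failures=n_failures)
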