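"""CSV / JSON input and output for survival data, truth and fits."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cooper import CooperFit, extract_coefficients, shared_selection
from .cox_core import SurvivalDataset
from .simulators import SimulatedDataset

__all__ = [
    "read_survival_csv",
    "write_survival_csv",
    "write_truth_json",
    "cooper_fit_to_dict",
]


def read_survival_csv(path: str | Path) -> SurvivalDataset:
    """Read a (time, status, features...) CSV into a SurvivalDataset.

    The header must contain ``time`` and ``status``; every other column is a
    covariate, order preserved.  Validation errors name the offending rows
    (0-based data rows).
    """
    df = pd.read_csv(path)
    for col in ("time", "status"):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    feature_cols = [c for c in df.columns if c not in ("time", "status")]
    na_rows = df.index[df.isna().any(axis=1)]
    if len(na_rows):
        raise ValueError(f"missing values in rows {na_rows[:10].tolist()}")
    time = df["time"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(time) | (time <= 0))
    if bad.size:
        raise ValueError(f"non-positive or non-finite times in rows {bad[:10].tolist()}")
    status = df["status"].to_numpy()
    bad = np.flatnonzero(~np.isin(status, (0, 1, 2)))
    if bad.size:
        raise ValueError(f"status outside {{0,1,2}} in rows {bad[:10].tolist()}")
    return SurvivalDataset(time=time, status=status.astype(int),
                           X=df[feature_cols].to_numpy(dtype=float),
                           feature_names=feature_cols)


def write_survival_csv(ds: SurvivalDataset, path: str | Path) -> None:
    features = pd.DataFrame(ds.X, columns=ds.feature_names)
    df = pd.concat([pd.DataFrame({"time": ds.time, "status": ds.status}), features],
                   axis=1)
    df.to_csv(path, index=False)


def write_truth_json(sim: SimulatedDataset, path: str | Path) -> None:
    payload = {
        "beta1_true": sim.beta1_true.tolist(),
        "beta2_true": sim.beta2_true.tolist(),
        "block_label": np.asarray(sim.block_label).tolist(),
        "feature_names": sim.data.feature_names,
    }
    Path(path).write_text(json.dumps(payload))


def cooper_fit_to_dict(fit: CooperFit, config: dict | None = None) -> dict:
    """JSON-serializable summary of a cooperative fit (sparse coefficients)."""
    out = {
        "converged": fit.converged,
        "n_iterations_run": fit.n_iterations_run,
        "causes": {},
        "shared_selection": shared_selection(fit),
        "shared_selection_initial": shared_selection(fit, use_initial_fit=True),
    }
    for cause in (1, 2):
        final = fit.fit_cause1 if cause == 1 else fit.fit_cause2
        out["causes"][str(cause)] = {
            "coefficients": extract_coefficients(fit, cause),
            "coefficients_initial": extract_coefficients(fit, cause, use_initial_fit=True),
            "theta": final.theta,
            "lambda_selected": final.lambda_selected,
        }
    if config is not None:
        out["config"] = config
    return out
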