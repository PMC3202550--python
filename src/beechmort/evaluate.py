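"""Model screening and goodness-of-fit: VIF, delta-DIC, AUC, calibration.

Candidate covariate sets are screened for collinearity with variance
inflation factors (combinations with any VIF >= 3 are rejected, which is
what keeps BA and BAL out of the same model).  Fitted models on the same
tree set are ranked by DIC, with differences >= 5 counted as substantial
and >= 10 as very strong evidence.  Discrimination is measured by the AUC
of the period-level death probability 1 - (1 - m_hat)^t against observed
deaths, and calibration by binning trees on predicted probability and
comparing each bin's observed death fraction with its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .hier_model import ModelData, PosteriorResult, linear_predictor

__all__ = [
    "compute_vif",
    "compare_models",
    "compute_auc",
    "calibration_bins",
    "period_death_probability",
    "EvaluationReport",
]

VIF_THRESHOLD = 3.0


def compute_vif(x: np.ndarray, names: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factor of each column regressed on the others.

    VIF_c = 1/(1 - R^2_c) with an intercept in each auxiliary regression.
    Perfect collinearity is reported as ``inf`` rather than raising.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 covariates")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    n, p = x.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    out = {}
    for c in range(p):
        target = x[:, c]
        others = np.column_stack([np.ones(n), np.delete(x, c, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_tot = float(np.sum((target - target.mean()) ** 2))
        if ss_tot == 0:
            out[names[c]] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        out[names[c]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def compare_models(
    models: Sequence[tuple[str, float]],
    n_obs: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Delta-DIC table with evidence labels.

    ``models`` is a sequence of (label, DIC) pairs fitted to the same tree
    set; pass ``n_obs`` to have that precondition checked.  Delta-DIC is
    relative to the minimum; exact ties are broken by listed order, with
    the tie noted in the table.  Labels: < 5 none, >= 5 substantial,
    >= 10 very strong.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    if n_obs is not None:
        if len(set(n_obs)) > 1:
            raise ValueError(f"models fit to different tree sets: n = {list(n_obs)}")
    labels = [m[0] for m in models]
    dics = np.array([m[1] for m in models], dtype=float)
    best_idx = int(np.argmin(dics))  # argmin takes the first on ties
    delta = dics - dics[best_idx]
    tied = (delta == 0).sum() > 1

    def evidence(dd: float) -> str:
        if dd >= 10:
            return "very strong"
        if dd >= 5:
            return "substantial"
        return "none"

    table = pd.DataFrame(
        {
            "model": labels,
            "dic": dics,
            "delta_dic": delta,
            "evidence": [evidence(dd) for dd in delta],
            "is_best": [i == best_idx for i in range(len(models))],
        }
    )
    table.attrs["note"] = (
        "exact DIC tie broken by listed order" if tied else ""
    )
    return table


def compute_auc(predicted: Sequence[float] | np.ndarray, died: Sequence[int] | np.ndarray) -> float:
    """Probability a random dead tree outranks a random survivor.

    Computed as the normalized rank-sum statistic with average ranks, so
    ties count one half; identical to the area under the ROC curve.
    """
    p = np.asarray(predicted, dtype=float)
    d = np.asarray(died).astype(bool)
    n1 = int(d.sum())
    n0 = int((~d).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(p)
    return float((ranks[d].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def calibration_bins(
    predicted: Sequence[float] | np.ndarray,
    died: Sequence[int] | np.ndarray,
    bin_edges: Sequence[float] | np.ndarray | None = None,
) -> pd.DataFrame:
    """Observed death fraction per predicted-probability bin.

    Default bins are ten equal-width intervals on [0, 1].  A prediction
    equal to an interior edge goes to the upper bin; the top edge belongs
    to the last bin.  Empty bins are reported with n = 0 and a missing
    observed fraction.
    """
    p = np.asarray(predicted, dtype=float)
    d = np.asarray(died).astype(int)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("predicted probabilities must lie in [0, 1]")
    edges = np.arange(11) / 10.0 if bin_edges is None else np.asarray(bin_edges, dtype=float)
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "midpoint": (edges[b] + edges[b + 1]) / 2.0,
                "n": n,
                "observed_fraction": float(d[mask].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def period_death_probability(
    result: PosteriorResult,
    data: ModelData,
    include_plot_effects: bool = True,
) -> np.ndarray:
    """Per-tree predicted death probability 1 - (1 - m_hat)^t.

    ``m_hat`` plugs in the posterior means of the parameters (including
    the plot effects by default), so the prediction lives on the same
    period-level scale as the observed death indicators.
    """
    beta = result.posterior_mean_beta()
    alpha = result.posterior_mean_alpha()
    if include_plot_effects and alpha.size:
        alpha_per_tree = alpha[data.plot_index]
    else:
        alpha_per_tree = 0.0
    m = expit(linear_predictor(beta, data.design.matrix, alpha_per_tree))
    return 1.0 - (1.0 - m) ** data.t_years


@dataclass(frozen=True)
class EvaluationReport:
    """Bundle of screening and fit diagnostics for one model family."""

    vif: pd.Series
    dic_table: pd.DataFrame
    auc: float
    calibration: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "vif": self.vif.to_dict(),
            "dic_table": self.dic_table.to_dict(orient="records"),
            "auc": self.auc,
            "calibration": self.calibration.to_dict(orient="records"),
        }
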