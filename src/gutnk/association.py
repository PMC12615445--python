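"""Score correlation, logistic risk models and ROC utilities.

Two logistic risk models are shipped as immutable fixtures with their
published coefficients: a cervical-cancer risk model on PD-1+ CD56bright NK
cells and the Escherichia/Ruminococcus CLR ratio, and a mortality model on
TIGIT+TIM-3+ CD56bright co-expression and CD56dim NK frequency.  Features
enter on their native scales: percent-positive on 0-100, ratios as CLR
differences (natural-log units).  ``fit_logistic`` refits models of the same
form by maximum likelihood (statsmodels) with Wald standard errors; stepwise
feature selection is out of scope — feature sets are fixed inputs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "RiskModel",
    "PRINTED_MODELS",
    "spearman_correlation",
    "evaluate_risk",
    "odds_ratio_from_coef",
    "fit_logistic",
    "roc_auc",
    "youden_cutoff",
]


@dataclass(frozen=True)
class RiskModel:
    name: str
    intercept: float
    coefficients: Mapping[str, float]
    provenance: str = "refit"  # "printed" | "refit"
    standard_errors: Mapping[str, float] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        object.__setattr__(self, "standard_errors", dict(self.standard_errors))

    @property
    def features(self) -> list[str]:
        return list(self.coefficients)

    def odds_ratios(self) -> dict[str, float]:
        return {f: odds_ratio_from_coef(b) for f, b in self.coefficients.items()}

    def wald_ci(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """OR confidence intervals exp(beta +/- z * SE) for refit models."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        out = {}
        for f, b in self.coefficients.items():
            se = self.standard_errors.get(f)
            if se is None:
                raise ValueError(f"no standard error stored for {f!r}")
            out[f] = (math.exp(b - z * se), math.exp(b + z * se))
        return out


PRINTED_MODELS: dict[str, RiskModel] = {
    # cervical-cancer risk from PD-1+ CD56bright NK cells (percent positive)
    # and the Escherichia/Ruminococcus CLR ratio
    "cc_risk_2var": RiskModel(
        name="cc_risk_2var",
        intercept=-3.3919,
        coefficients={
            "PD-1|CD56bright": 0.5938,
            "Escherichia/Ruminococcus": 2.6358,
        },
        provenance="printed",
    ),
    # mortality risk from TIGIT+TIM-3+ CD56bright co-expression and CD56dim
    # NK cell frequency (both percent)
    "mortality_2var": RiskModel(
        name="mortality_2var",
        intercept=-105.640,
        coefficients={
            "TIGIT+TIM-3|CD56bright": 0.208,
            "frequency|CD56dim": 1.058,
        },
        provenance="printed",
    ),
}


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties and a two-sided p.

    The p-value uses the t-approximation for n > 10 and an exact permutation
    enumeration for n <= 10, where the approximation is unreliable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    n = x.size
    if n > 10:
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total


def evaluate_risk(model: RiskModel, features: Mapping[str, float]) -> float:
    """P = logistic(beta0 + sum beta_j x_j); every model feature is required."""
    eta = model.intercept
    for name, beta in model.coefficients.items():
        if name not in features:
            raise KeyError(f"risk model {model.name!r} requires feature {name!r}")
        eta += beta * float(features[name])
    return float(1.0 / (1.0 + math.exp(-eta)))


def odds_ratio_from_coef(beta: float) -> float:
    return float(math.exp(beta))


def fit_logistic(features: pd.DataFrame, labels: Sequence[int],
                 name: str = "refit") -> RiskModel:
    """Maximum-likelihood logistic fit with Wald standard errors.

    Perfect separation (or any non-convergence) is flagged on the returned
    model rather than raised, with the last-iterate coefficients reported.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two subjects of each class")
    if np.any(features.std(axis=0).to_numpy() == 0):
        raise ValueError("constant feature column; drop it before fitting")
    X = sm.add_constant(features.to_numpy(dtype=float), has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=50, method="bfgs")
            converged = False
    params = np.asarray(res.params, dtype=float)
    ses = np.asarray(res.bse, dtype=float)
    # quasi-separated fits drift to huge coefficients without tripping the
    # optimizer's own convergence flag
    if np.any(np.abs(params) > 30) or not np.all(np.isfinite(ses)):
        converged = False
    cols = list(features.columns)
    return RiskModel(
        name=name,
        intercept=float(params[0]),
        coefficients={c: float(b) for c, b in zip(cols, params[1:])},
        provenance="refit",
        standard_errors={c: float(s) for c, s in zip(cols, ses[1:])},
        converged=converged,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outranks a random negative; ties 1/2."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(y, s))


def youden_cutoff(scores: Sequence[float], labels: Sequence[int]
                  ) -> tuple[float, float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between adjacent distinct score
    values; a subject is called positive when its score exceeds the
    threshold.  Ties in J are broken toward the lowest cutoff.  An
    anti-informative marker (J <= 0 everywhere) is reported as-is — the
    caller can inspect the returned sensitivity/specificity.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("cutoff search needs both classes present")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("all scores identical; no cutoff exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best = None
    for c in candidates:
        pred = s > c
        sens = float((pred & (y == 1)).sum() / n_pos)
        spec = float((~pred & (y == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), sens, spec)
    assert best is not None
    return best[1], best[2], best[3]
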