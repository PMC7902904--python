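"""Shared fit container for mixed and fixed-effect models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ModelFit:
    """Estimates and fit statistics for one fitted model.

    ``n_params`` counts fixed effects plus variance/covariance
    parameters (and the residual variance for Gaussian models), so the
    AIC/BIC identities hold exactly:
    ``AIC = 2 k - 2 logLik``; ``BIC = k ln(n) - 2 logLik``.
    """

    formula: str
    fixed_effects: pd.DataFrame
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    random_structure: str = ""
    cov_re: np.ndarray | None = None
    method: str = ""
    stat_label: str = "z"
    diagnostics: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * float(np.log(self.n_obs)) - 2.0 * self.loglik

    def summary(self) -> str:
        head = (f"{self.formula}  [{self.method}]\n"
                f"logLik={self.loglik:.1f}  AIC={self.aic:.1f}  "
                f"BIC={self.bic:.1f}  n={self.n_obs}  "
                f"params={self.n_params}  converged={self.converged}")
        return head + "\n" + self.fixed_effects.to_string()
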