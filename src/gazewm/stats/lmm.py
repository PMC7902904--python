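"""Linear mixed models (Gaussian response) and random-structure pruning.

Fitting is delegated to statsmodels ``MixedLM`` with the maximum
likelihood criterion; this module adds the fit container, per-condition
refits, and the PCA + likelihood-ratio procedure for simplifying an
overparameterized random-effects structure.  t statistics are Wald
(estimate / SE) with normal-approximation p values, labelled as such —
no Satterthwaite degrees of freedom are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .base import ModelFit


@dataclass
class LmmSpec:
    """Declarative description of one LMM so reduced refits are easy."""

    data: pd.DataFrame
    response: str
    fixed: list[str]                  # column names; intercept implicit
    group: str
    random_slopes: list[str] = field(default_factory=list)

    def with_slopes(self, slopes: list[str]) -> "LmmSpec":
        return LmmSpec(self.data, self.response, list(self.fixed),
                       self.group, list(slopes))


def fit_lmm(spec: LmmSpec, formula: str = "") -> ModelFit:
    """ML fit of ``response ~ 1 + fixed`` with by-group random intercept
    and the requested random slopes (fully correlated covariance)."""
    import statsmodels.api as sm

    data = spec.data
    endog = np.asarray(data[spec.response], dtype=float)
    exog = np.column_stack(
        [np.ones(len(data))] + [np.asarray(data[c], float) for c in spec.fixed])
    fe_names = ["intercept"] + list(spec.fixed)
    exog_re = np.column_stack(
        [np.ones(len(data))] + [np.asarray(data[c], float)
                                for c in spec.random_slopes])
    groups = np.asarray(data[spec.group])
    model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, method="lbfgs", maxiter=500)
    q = exog_re.shape[1]
    n_params = exog.shape[1] + q * (q + 1) // 2 + 1  # + residual variance
    t = res.fe_params / res.bse_fe
    table = pd.DataFrame({
        "estimate": res.fe_params, "se": res.bse_fe, "t": t,
        "p": 2 * sps.norm.sf(np.abs(t)),
    }, index=fe_names)
    singular = bool(np.linalg.eigvalsh(np.asarray(res.cov_re)).min()
                    < 1e-10 * max(np.trace(np.asarray(res.cov_re)), 1e-12))
    return ModelFit(
        formula=formula or (f"{spec.response} ~ 1 + {' + '.join(spec.fixed)}"
                            f" + (1 + {' + '.join(spec.random_slopes) or '0'}"
                            f" | {spec.group})"),
        fixed_effects=table, loglik=float(res.llf), n_params=n_params,
        n_obs=len(endog), converged=bool(res.converged),
        random_structure="intercept + " + ", ".join(spec.random_slopes),
        cov_re=np.asarray(res.cov_re),
        method="ML (statsmodels MixedLM)",
        stat_label="t (Wald, normal approximation; no Satterthwaite df)",
        diagnostics={"singular": singular,
                     "resid_var": float(res.scale)})


def fit_lmm_per_condition(spec: LmmSpec, condition_col: str = "condition_deg",
                          fixed: list[str] | None = None) -> dict[int, ModelFit]:
    """Separate (simpler) models per locomotion condition."""
    out = {}
    for cond, block in spec.data.groupby(condition_col):
        sub = LmmSpec(block, spec.response,
                      fixed if fixed is not None else spec.fixed,
                      spec.group, spec.random_slopes)
        out[int(cond)] = fit_lmm(sub, formula=f"condition {cond}")
    return out


def simplify_random_structure(spec: LmmSpec,
                              pca_tol: float = 1e-3,
                              alpha: float = 0.05,
                              ) -> tuple[ModelFit, LmmSpec, list[dict]]:
    """Prune random slopes that the data cannot support.

    A slope is removed only when (a) a principal component analysis of
    the fitted random-effects covariance shows a component carrying less
    than ``pca_tol`` of the total variance (0.1% by default: the ML
    optimizer reports near-boundary variances as small positive numbers,
    never exact zeros), and (b) a likelihood-ratio test against the
    model without that slope is non-significant.  The
    intercept is never removed.  Returns (final fit, final spec, audit
    trail).
    """
    audit: list[dict] = []
    current = spec
    fit = fit_lmm(current)
    while current.random_slopes:
        cov = fit.cov_re
        eigvals = np.linalg.eigvalsh(cov)
        total = float(eigvals.sum())
        unsupported = bool(eigvals.min() < pca_tol * max(total, 1e-300))
        if not unsupported:
            audit.append({"action": "stop",
                          "reason": "all PCA components supported",
                          "eigenvalues": eigvals.tolist()})
            break
        # try dropping each slope; keep the least harmful non-significant one
        best = None
        for slope in current.random_slopes:
            reduced = current.with_slopes(
                [s for s in current.random_slopes if s != slope])
            red_fit = fit_lmm(reduced)
            chi2 = max(0.0, 2.0 * (fit.loglik - red_fit.loglik))
            ddf = fit.n_params - red_fit.n_params
            p = float(sps.chi2.sf(chi2, ddf)) if ddf > 0 else 1.0
            if p > alpha and (best is None or p > best["p"]):
                best = {"slope": slope, "p": p, "chi2": chi2, "ddf": ddf,
                        "fit": red_fit, "spec": reduced}
        if best is None:
            audit.append({"action": "stop",
                          "reason": "PCA flagged overparameterization but "
                                    "every slope is significant by LRT",
                          "eigenvalues": eigvals.tolist()})
            break
        audit.append({"action": "remove", "slope": best["slope"],
                      "criteria": {"pca_component_share":
                                   float(eigvals.min() / max(total, 1e-300)),
                                   "lrt_p": best["p"],
                                   "lrt_chi2": best["chi2"],
                                   "lrt_ddf": best["ddf"]}})
        fit, current = best["fit"], best["spec"]
    return fit, current, audit
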