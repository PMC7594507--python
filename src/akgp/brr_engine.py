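"""Multi-component Bayesian Ridge Regression fitted by Gibbs sampling.

The model is ``y = mu*1 + sum_b W_b beta_b + eps`` with a flat prior on
the intercept, iid normal priors ``beta_b ~ N(0, s2_b I)`` per design
block, and scaled-inverse-chi-squared hyperpriors on every variance
(including the residual).  Each design block may be a kernel projection
basis P (so ``P beta`` is a genetic effect with covariance ``s2 P P'``),
an environment incidence matrix, or raw markers.

Test-set prediction works by Bayesian data augmentation: missing entries
of ``y`` are sampled from their predictive conditional every sweep, so
their running means are draws-averaged predictions.

Numerics: each block's design is rotated once into the eigenbasis of its
Gram matrix W'W, making every conditional coefficient precision diagonal;
a sweep then costs two matrix-vector products per block and no
decompositions.  The iid normal prior is rotation invariant, so the
posterior is unchanged; coefficient summaries are rotated back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelBlock",
    "ChainSettings",
    "PosteriorFit",
    "fit_gibbs",
    "closed_form_blup",
    "predict",
    "chain_diagnostics",
]

#: default hyperprior degrees of freedom for every variance component.
PRIOR_DF = 5.0

#: share of var(y) assigned a priori to the non-residual part of the model.
PRIOR_R2 = 0.5


@dataclass
class ModelBlock:
    """One design matrix with iid-normal coefficients.

    ``df``/``scale`` parametrize the scaled-inverse-chi-squared hyperprior
    of the block's variance.  ``scale=None`` invokes the R2-partition
    default: the prior mode of the block's contribution to var(y) is
    PRIOR_R2 * var(y) shared equally among blocks.  A huge ``df`` with an
    explicit ``scale`` is effectively a point-mass (fixed variance).
    """

    label: str
    design: np.ndarray
    df: float = PRIOR_DF
    scale: Optional[float] = None

    def __post_init__(self) -> None:
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        if self.design.ndim != 2 or self.design.shape[1] < 1:
            raise ValueError(f"block {self.label!r}: design must be n x q, q >= 1")
        if self.df <= 0:
            raise ValueError(f"block {self.label!r}: df must be > 0")
        if self.scale is not None and self.scale <= 0:
            raise ValueError(f"block {self.label!r}: scale must be > 0")

    @property
    def q(self) -> int:
        return self.design.shape[1]


@dataclass
class ChainSettings:
    """MCMC run length: defaults are 20,000 sweeps, 3,000 burn-in, thin 2."""

    n_iter: int = 20000
    burn_in: int = 3000
    thin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorFit:
    """Posterior summaries plus thinned variance/intercept samples."""

    mu: float
    coef_means: Dict[str, np.ndarray]
    var_means: Dict[str, float]
    var_sds: Dict[str, float]
    scaled_var_means: Dict[str, float]
    fitted: np.ndarray
    y_imputed: np.ndarray
    missing_mask: np.ndarray
    samples: Dict[str, np.ndarray]
    settings: ChainSettings
    block_q: Dict[str, int] = field(default_factory=dict)


def _prior_scales(y_obs: np.ndarray, blocks: Sequence[ModelBlock],
                  msx: Dict[str, float]):
    """R2-partition hyperprior scales (residual + one per block)."""
    vy = float(np.var(y_obs, ddof=1)) if len(y_obs) > 1 else 1.0
    vy = max(vy, 1e-12)
    df_e = PRIOR_DF
    S_e = vy * (1.0 - PRIOR_R2) * (df_e + 2.0) / df_e
    B = max(len(blocks), 1)
    scales = {}
    for b in blocks:
        if b.scale is not None:
            scales[b.label] = b.scale
        else:
            share = PRIOR_R2 * vy / B / max(msx[b.label], 1e-12)
            scales[b.label] = share * (b.df + 2.0) / b.df
    return df_e, S_e, scales


def fit_gibbs(y: np.ndarray, blocks: Sequence[ModelBlock],
              settings: Optional[ChainSettings] = None,
              resid_df: float = PRIOR_DF,
              resid_scale: Optional[float] = None) -> PosteriorFit:
    """Conjugate Gibbs sampler for the multi-block ridge model.

    ``y`` may contain NaN: those observations are treated as unknowns and
    sampled each sweep (their posterior means are the predictions).
    Deterministic given ``settings.seed``.
    """
    settings = settings or ChainSettings()
    y = np.asarray(y, dtype=float)
    n = len(y)
    miss = np.isnan(y)
    n_obs = int((~miss).sum())
    if n_obs == 0:
        raise ValueError("no observed phenotypes")
    labels = [b.label for b in blocks]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate block labels")
    for b in blocks:
        if b.design.shape[0] != n:
            raise ValueError(f"block {b.label!r}: design has "
                             f"{b.design.shape[0]} rows, y has {n}")
        if not np.any(b.design):
            warnings.warn(f"block {b.label!r} has an all-zero design; its "
                          "variance is unidentifiable", UserWarning)

    rng = np.random.default_rng(settings.seed)

    # rotate each block into the eigenbasis of its Gram matrix
    Wt, V, lam, msx = {}, {}, {}, {}
    for b in blocks:
        gram = b.design.T @ b.design
        ev, evec = np.linalg.eigh((gram + gram.T) / 2.0)
        lam[b.label] = np.clip(ev, 0.0, None)
        V[b.label] = evec
        Wt[b.label] = b.design @ evec
        msx[b.label] = float(np.trace(gram)) / n  # mean diag of W W'

    _, S_e_def, scales = _prior_scales(y[~miss], blocks, msx)
    df_e = resid_df
    if resid_scale is None:
        resid_scale = S_e_def

    # state
    y_work = y.copy()
    y_work[miss] = y[~miss].mean()
    mu = float(y_work.mean())
    theta = {b.label: np.zeros(b.q) for b in blocks}
    contrib = {b.label: np.zeros(n) for b in blocks}
    s2b = {b.label: scales[b.label] for b in blocks}
    s2e = resid_scale
    r = y_work - mu

    n_ret = settings.n_retained
    if n_ret < 1:
        raise ValueError("no retained samples under these settings")
    samples = {"mu": np.empty(n_ret), "sigma2_residual": np.empty(n_ret)}
    for lab in labels:
        samples[f"sigma2_{lab}"] = np.empty(n_ret)
    theta_sum = {lab: np.zeros_like(theta[lab]) for lab in labels}
    mu_sum = 0.0
    yimp_sum = np.zeros(int(miss.sum()))
    kept = 0

    for it in range(settings.n_iter):
        # intercept (flat prior)
        r += mu
        mu = rng.normal(r.mean(), np.sqrt(s2e / n))
        r -= mu
        # block coefficients (joint draw, diagonal in the rotated basis)
        for b in blocks:
            lab = b.label
            r += contrib[lab]
            rhs = Wt[lab].T @ r / s2e
            d = lam[lab] / s2e + 1.0 / s2b[lab]
            th = rhs / d + rng.standard_normal(b.q) / np.sqrt(d)
            theta[lab] = th
            contrib[lab] = Wt[lab] @ th
            r -= contrib[lab]
            ss = float(th @ th)
            s2b[lab] = (b.df * scales[lab] + ss) / rng.chisquare(b.df + b.q)
        # residual variance (data-augmented: all n residuals)
        s2e = (df_e * resid_scale + float(r @ r)) / rng.chisquare(df_e + n)
        # impute missing phenotypes from the predictive conditional
        if miss.any():
            eta_m = y_work[miss] - r[miss]
            y_new = eta_m + np.sqrt(s2e) * rng.standard_normal(eta_m.size)
            r[miss] += y_new - y_work[miss]
            y_work[miss] = y_new

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            samples["mu"][kept] = mu
            samples["sigma2_residual"][kept] = s2e
            for lab in labels:
                samples[f"sigma2_{lab}"][kept] = s2b[lab]
            for lab in labels:
                theta_sum[lab] += theta[lab]
            mu_sum += mu
            if miss.any():
                yimp_sum += y_work[miss]
            kept += 1

    mu_mean = mu_sum / kept
    coef_means = {lab: V[lab] @ (theta_sum[lab] / kept) for lab in labels}
    fitted = np.full(n, mu_mean)
    for b in blocks:
        fitted += b.design @ coef_means[b.label]
    y_imp = y.copy()
    if miss.any():
        y_imp[miss] = yimp_sum / kept
    var_means = {lab: float(samples[f"sigma2_{lab}"].mean()) for lab in labels}
    var_means["residual"] = float(samples["sigma2_residual"].mean())
    var_sds = {lab: float(samples[f"sigma2_{lab}"].std(ddof=1)) for lab in labels}
    var_sds["residual"] = float(samples["sigma2_residual"].std(ddof=1))
    scaled = {lab: var_means[lab] * msx[lab] for lab in labels}
    return PosteriorFit(
        mu=mu_mean, coef_means=coef_means, var_means=var_means,
        var_sds=var_sds, scaled_var_means=scaled, fitted=fitted,
        y_imputed=y_imp, missing_mask=miss, samples=samples,
        settings=settings, block_q={b.label: b.q for b in blocks})


def closed_form_blup(y: np.ndarray, blocks: Sequence[ModelBlock],
                     variances: Dict[str, float], resid_var: float = 1.0,
                     intercept: Optional[float] = None):
    """Exact generalized-ridge (BLUP) solution at fixed variances.

    Solves the mixed-model equations ``(W'W + D) b = W'(y - mu)`` with
    ``D`` block-diagonal, ``lambda_b = resid_var / s2_b``; the intercept
    is profiled jointly (unpenalized column) unless fixed by the caller.
    Returns ``(coef dict, mu, fitted)``.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("closed-form solution requires fully observed y")
    designs = [b.design for b in blocks]
    lam = []
    for b in blocks:
        s2 = variances[b.label]
        if s2 <= 0:
            raise ValueError(f"variance for block {b.label!r} must be > 0")
        lam.extend([resid_var / s2] * b.q)
    W = np.hstack(designs) if designs else np.zeros((len(y), 0))
    if intercept is None:
        A = np.hstack([np.ones((len(y), 1)), W])
        D = np.diag([0.0] + lam)
        target = y
    else:
        A = W
        D = np.diag(lam)
        target = y - intercept
    lhs = A.T @ A + D
    try:
        sol = np.linalg.solve(lhs, A.T @ target)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular mixed-model equations: {err}") from err
    if intercept is None:
        mu, coefs = float(sol[0]), sol[1:]
    else:
        mu, coefs = float(intercept), sol
    out, k = {}, 0
    for b in blocks:
        out[b.label] = coefs[k:k + b.q]
        k += b.q
    fitted = np.full(len(y), mu)
    for b in blocks:
        fitted += b.design @ out[b.label]
    return out, mu, fitted


def predict(fit: PosteriorFit, test_designs: Dict[str, np.ndarray]) -> np.ndarray:
    """Predictive means for new rows: mu + sum_b W_test beta_b.

    For a Gaussian predictive distribution the mean equals the mode, so
    these are the point predictions of the Bayesian model.
    """
    first = next(iter(test_designs.values()))
    out = np.full(np.atleast_2d(first).shape[0], fit.mu)
    for lab, W in test_designs.items():
        W = np.atleast_2d(np.asarray(W, dtype=float))
        if lab not in fit.coef_means:
            raise KeyError(f"unknown block {lab!r}")
        if W.shape[1] != fit.block_q[lab]:
            raise ValueError(f"block {lab!r}: test design has {W.shape[1]} "
                             f"columns, training had {fit.block_q[lab]}")
        out += W @ fit.coef_means[lab]
    return out


def chain_diagnostics(fit: PosteriorFit) -> pd.DataFrame:
    """Effective sample size and split-chain R-hat per retained parameter.

    Parameters with R-hat > 1.1 (or degenerate chains) are flagged.
    """
    import arviz as az

    rows = []
    for name, x in fit.samples.items():
        x = np.asarray(x, dtype=float)
        if x.size < 10:
            raise ValueError("fewer than 10 retained samples")
        half = x.size // 2
        split = x[:2 * half].reshape(2, half)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(x[None, :]))
            rhat = float(az.rhat(split))
        degenerate = not np.isfinite(ess) or np.var(x) == 0
        flagged = degenerate or (np.isfinite(rhat) and rhat > 1.1) or not np.isfinite(rhat)
        rows.append({"parameter": name, "ess": ess, "rhat": rhat,
                     "degenerate": degenerate, "flagged": flagged})
    return pd.DataFrame(rows).set_index("parameter")
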