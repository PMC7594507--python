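"""The four method-model combinations: FGSE, APSE, FGGE and APGE.

FGSE : full kernel, single environment    — ridge on P = U S^{1/2} of K.
APSE : Nystrom kernel, single environment — ridge on P = K_nm U S^{-1/2}.
FGGE : full kernels, multi-environment    — environment effect + main
       genetic effect (G) + interaction (GE = G # Ze E Ze').
APGE : Nystrom blocks of G and GE with a stratified inducing set.

Prediction is transductive: the kernel (or its Nystrom blocks) is built
over ALL observations, training and test alike, and test phenotypes are
masked during the Gibbs fit so the sampler imputes their predictive
values.  Inducing lines are always drawn from the training set only.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from . import brr_engine, ge_structures, kernels
from .brr_engine import ChainSettings, ModelBlock
from .evaluation import corr_metric, pmse_metric
from .kernels import KernelSpec, MarkerMatrix
from .streams import derive_seed

__all__ = [
    "AnalysisConfig",
    "FitResult",
    "fit_fgse",
    "fit_apse",
    "fit_fgge",
    "fit_apge",
    "forward_cycle_prediction",
]

#: full-kernel paths refuse more observations than this without force=True;
#: beyond it the approximation is the intended tool.
FULL_N_CAP = 15000


@dataclass
class AnalysisConfig:
    """Run configuration shared by all four pipelines."""

    method: str = "fgse"
    kernel: KernelSpec = field(default_factory=KernelSpec)
    m: Optional[int] = None
    stratified: bool = True
    chain: ChainSettings = field(default_factory=ChainSettings)
    seed: int = 0
    standardize_y: bool = False
    report_phi: bool = False
    center: bool = True
    scale: bool = False
    force_full: bool = False

    def __post_init__(self) -> None:
        self.method = self.method.lower()
        if self.method not in ("fgse", "apse", "fgge", "apge"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method in ("apse", "apge"):
            if self.m is None or self.m < 1:
                raise ValueError(f"method {self.method} requires m >= 1")


@dataclass
class FitResult:
    """Predictions plus test-set accuracy and variance components."""

    predictions: np.ndarray
    test_corr: Optional[float]
    test_pmse: Optional[float]
    sigma2_eps: float
    variance_components: Dict[str, float]
    scaled_variance_components: Dict[str, float]
    per_env_corr: Dict = field(default_factory=dict)
    per_env_pmse: Dict = field(default_factory=dict)
    phi: Optional[float] = None
    m: Optional[int] = None
    metadata: Dict = field(default_factory=dict)
    fit: Optional[brr_engine.PosteriorFit] = None


def _as_indices(idx, n: int) -> np.ndarray:
    idx = np.asarray(idx)
    if idx.dtype == bool:
        idx = np.where(idx)[0]
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValueError("index out of range")
    return idx.astype(int)


def _standardize(y: np.ndarray, on: bool):
    if not on:
        return y, (0.0, 1.0)
    mu = np.nanmean(y)
    sd = np.nanstd(y, ddof=1)
    if sd <= 0:
        raise ValueError("cannot standardize constant phenotype")
    return (y - mu) / sd, (mu, sd)


def _metrics(y_true, pred, test_idx, env=None):
    """Test-set CORR/PMSE, overall and per environment when labels given."""
    yt, pt = y_true[test_idx], pred[test_idx]
    corr = corr_metric(pt, yt) if len(test_idx) >= 3 else None
    pmse = pmse_metric(pt, yt) if len(test_idx) >= 1 else None
    per_c, per_p = {}, {}
    if env is not None:
        et = np.asarray(env)[test_idx]
        for lab in dict.fromkeys(et.tolist()):
            sel = et == lab
            if sel.sum() >= 3:
                per_c[lab] = corr_metric(pt[sel], yt[sel])
                per_p[lab] = pmse_metric(pt[sel], yt[sel])
    return corr, pmse, per_c, per_p


def _finish(y_raw, y_std, stats, fit, test_idx, env, phi, m, meta, t0):
    mu_y, sd_y = stats
    pred = fit.y_imputed * sd_y + mu_y
    pred_all = fit.fitted * sd_y + mu_y
    # observed rows keep their model-fitted values; masked rows their
    # imputation means (identical in expectation, imputation is the
    # predictive draw average)
    pred_out = np.where(fit.missing_mask, pred, pred_all)
    has_truth = test_idx.size and not np.isnan(y_raw[test_idx]).any()
    if has_truth:
        corr, pmse, per_c, per_p = _metrics(y_raw, pred_out, test_idx, env)
    else:
        corr = pmse = None
        per_c, per_p = {}, {}
    scaled = {lab: v * sd_y**2 for lab, v in fit.scaled_var_means.items()}
    varcomp = {lab: v * sd_y**2 for lab, v in fit.var_means.items()}
    meta = dict(meta, elapsed_s=time.perf_counter() - t0,
                standardized=(sd_y != 1.0 or mu_y != 0.0))
    return FitResult(
        predictions=pred_out, test_corr=corr, test_pmse=pmse,
        sigma2_eps=varcomp["residual"], variance_components=varcomp,
        scaled_variance_components=scaled, per_env_corr=per_c,
        per_env_pmse=per_p, phi=phi, m=m, metadata=meta, fit=fit)


def _mask(y: np.ndarray, test_idx: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).copy()
    y[test_idx] = np.nan
    return y


def _chain(config: AnalysisConfig) -> ChainSettings:
    c = config.chain
    return ChainSettings(c.n_iter, c.burn_in, c.thin,
                         derive_seed(config.seed, "sampler"))


# ---------------------------------------------------------------------------
# single-environment pipelines
# ---------------------------------------------------------------------------

def fit_fgse(y: np.ndarray, X: MarkerMatrix, train_idx, test_idx,
             config: AnalysisConfig) -> FitResult:
    """Full-kernel single-environment fit (exact eigen-projection)."""
    t0 = time.perf_counter()
    y = np.asarray(y, dtype=float)
    n = len(y)
    train_idx = _as_indices(train_idx, n)
    test_idx = _as_indices(test_idx, n)
    if n > FULL_N_CAP and not config.force_full:
        raise ValueError(f"full-kernel path refused for n = {n} > {FULL_N_CAP}; "
                         "use APSE or force_full=True")
    if config.kernel.kind == "gaussian":
        K = kernels.build_gaussian_kernel(X, config.kernel)
    else:
        K = kernels.build_gblup_kernel(X, config.center, config.scale)
    basis, dec = kernels.projection_full(K)
    y_std, stats = _standardize(y, config.standardize_y)
    fit = brr_engine.fit_gibbs(
        _mask(y_std, test_idx), [ModelBlock("u", basis.P)], _chain(config))
    phi = None
    if config.report_phi:
        phi = 100.0
    return _finish(y, y_std, stats, fit, test_idx, None, phi, None,
                   {"method": "fgse", "rank": dec.retained_rank}, t0)


def fit_apse(y: np.ndarray, X: MarkerMatrix, train_idx, test_idx,
             m: Optional[int] = None,
             config: Optional[AnalysisConfig] = None) -> FitResult:
    """Nystrom single-environment fit.

    Step 1: select m inducing lines from the training set; Step 2: build
    K_nm over all n lines; Step 3: eigendecompose K_mm; Step 4: ridge
    basis P = K_nm U S^{-1/2}; Step 5: Gibbs fit and prediction.
    """
    t0 = time.perf_counter()
    config = config or AnalysisConfig(method="apse", m=m)
    m = m if m is not None else config.m
    y = np.asarray(y, dtype=float)
    n = len(y)
    train_idx = _as_indices(train_idx, n)
    test_idx = _as_indices(test_idx, n)
    inducing = kernels.select_inducing_lines(
        X.line_ids[train_idx], m, seed=derive_seed(config.seed, "selection"))
    blocks = kernels.nystrom_blocks(X, inducing, config.kernel,
                                    config.center, config.scale)
    basis = kernels.projection_approx(blocks)
    y_std, stats = _standardize(y, config.standardize_y)
    fit = brr_engine.fit_gibbs(
        _mask(y_std, test_idx), [ModelBlock("u", basis.P)], _chain(config))
    phi = None
    if config.report_phi and n <= FULL_N_CAP:
        if config.kernel.kind == "gaussian":
            K = kernels.build_gaussian_kernel(X, config.kernel)
        else:
            K = kernels.build_gblup_kernel(X, config.center, config.scale)
        vals = np.linalg.eigvalsh(K.values)
        phi = kernels.phi_retained(vals, min(inducing.m, n))
    return _finish(y, y_std, stats, fit, test_idx, None, phi, inducing.m,
                   {"method": "apse", "rank": basis.rank}, t0)


# ---------------------------------------------------------------------------
# multi-environment (G x E) pipelines
# ---------------------------------------------------------------------------

def _env_block(design: ge_structures.EnvironmentDesign) -> ModelBlock:
    # iid env coefficients on Ze L (L = chol factor of E) give the
    # covariance s2_e Ze E Ze'
    if np.array_equal(design.E, np.eye(design.k)):
        Z = design.Z_e
    else:
        vals, vecs = np.linalg.eigh(design.E)
        L = vecs * np.sqrt(np.clip(vals, 0.0, None))
        Z = design.Z_e @ L
    return ModelBlock("env", Z)


def fit_fgge(y: np.ndarray, env: Sequence, X: MarkerMatrix, train_idx,
             test_idx, config: AnalysisConfig,
             lines: Optional[Sequence] = None) -> FitResult:
    """Full-kernel multi-environment fit: y = mu + e + g + ge + eps.

    ``X`` holds one marker row per observation (line rows repeated, under
    unique observation ids, when a line appears in several environments),
    so G = X_c X_c'/p over observations equals Zg K Zg'.  ``lines``
    optionally gives the true line label per observation (used to decide
    whether an unseen test environment still shares lines with training).
    """
    t0 = time.perf_counter()
    y = np.asarray(y, dtype=float)
    n = len(y)
    train_idx = _as_indices(train_idx, n)
    test_idx = _as_indices(test_idx, n)
    env = np.asarray(env)
    design = ge_structures.EnvironmentDesign(env)
    if design.k < 2:
        raise ValueError("single environment: use fit_fgse")
    if n > FULL_N_CAP and not config.force_full:
        raise ValueError(f"full-kernel path refused for n = {n} > {FULL_N_CAP}; "
                         "use APGE or force_full=True")
    test_envs = set(env[test_idx].tolist())
    train_envs = set(env[train_idx].tolist())
    unseen = test_envs - train_envs
    if unseen:
        obs_lines = np.asarray(lines) if lines is not None else X.line_ids
        shared = set(obs_lines[train_idx].tolist()) & set(obs_lines[test_idx].tolist())
        if not shared:
            warnings.warn(f"test environment(s) {sorted(unseen)} unseen in "
                          "training and no shared lines: predictions rely on "
                          "main effects only", UserWarning)
    if config.kernel.kind == "gaussian":
        G = kernels.build_gaussian_kernel(X, config.kernel)
    else:
        G = kernels.build_gblup_kernel(X, config.center, config.scale)
    GE = ge_structures.build_ge_kernel_full(G, design)
    Pg, dec_g = kernels.projection_full(G)
    Pge, _ = kernels.projection_full(GE)
    y_std, stats = _standardize(y, config.standardize_y)
    blocks = [_env_block(design), ModelBlock("g", Pg.P), ModelBlock("ge", Pge.P)]
    fit = brr_engine.fit_gibbs(_mask(y_std, test_idx), blocks, _chain(config))
    return _finish(y, y_std, stats, fit, test_idx, env, None, None,
                   {"method": "fgge", "k": design.k,
                    "rank_g": dec_g.retained_rank}, t0)


def fit_apge(y: np.ndarray, env: Sequence, X: MarkerMatrix, train_idx,
             test_idx, m: Optional[int] = None,
             config: Optional[AnalysisConfig] = None) -> FitResult:
    """Nystrom multi-environment fit.

    Step 1: stratified inducing set from the training observations (equal
    numbers per environment); Step 2: G blocks from markers; Step 3: GE
    blocks by Hadamard masking plus the bases P^g, P^ge; Step 4: Gibbs
    fit with blocks [Ze, P^g, P^ge].  The same inducing set drives both
    bases.
    """
    t0 = time.perf_counter()
    config = config or AnalysisConfig(method="apge", m=m)
    m = m if m is not None else config.m
    y = np.asarray(y, dtype=float)
    n = len(y)
    train_idx = _as_indices(train_idx, n)
    test_idx = _as_indices(test_idx, n)
    env = np.asarray(env)
    design = ge_structures.EnvironmentDesign(env)
    if design.k < 2:
        warnings.warn("single environment: interaction basis equals the main "
                      "basis and its variance is unidentifiable", UserWarning)
    if not config.stratified:
        warnings.warn("unstratified inducing selection for APGE: some "
                      "environments may contribute no inducing lines",
                      UserWarning)
    strata = env[train_idx] if config.stratified else None
    inducing = kernels.select_inducing_lines(
        X.line_ids[train_idx], m, strata=strata,
        seed=derive_seed(config.seed, "selection"))
    gblocks = kernels.nystrom_blocks(X, inducing, config.kernel,
                                     config.center, config.scale)
    inducing_env = env[train_idx][inducing.positions]
    geb = ge_structures.build_ge_blocks(gblocks.K_nm, gblocks.K_mm, design,
                                        inducing, inducing_env)
    Pg = kernels.projection_approx(
        kernels.NystromBlocks(geb.G_nm, geb.G_mm, inducing))
    Pge = kernels.projection_approx(
        kernels.NystromBlocks(geb.GE_nm, geb.GE_mm, inducing))
    y_std, stats = _standardize(y, config.standardize_y)
    blocks = [_env_block(design), ModelBlock("g", Pg.P), ModelBlock("ge", Pge.P)]
    fit = brr_engine.fit_gibbs(_mask(y_std, test_idx), blocks, _chain(config))
    return _finish(y, y_std, stats, fit, test_idx, env, None, inducing.m,
                   {"method": "apge", "k": design.k, "rank_g": Pg.rank,
                    "rank_ge": Pge.rank}, t0)


def forward_cycle_prediction(y: np.ndarray, cycles: Sequence, X: MarkerMatrix,
                             target_cycle, method: str = "apge",
                             m: Optional[int] = None,
                             config: Optional[AnalysisConfig] = None) -> FitResult:
    """Train on all cycles preceding ``target_cycle`` and predict it.

    Cycle order is first-appearance order of the labels.  The target
    cycle is the masked test environment; accuracy is reported on it.
    """
    cycles = np.asarray(cycles)
    order = list(dict.fromkeys(cycles.tolist()))
    if target_cycle not in order:
        raise ValueError(f"target cycle {target_cycle!r} not present")
    pos = order.index(target_cycle)
    if pos == 0:
        raise ValueError("target cycle is the earliest: no training cycles")
    keep_cycles = set(order[:pos]) | {target_cycle}
    keep = np.where(np.isin(cycles, list(keep_cycles)))[0]
    y_sub = np.asarray(y, dtype=float)[keep]
    cyc_sub = cycles[keep]
    X_sub = MarkerMatrix(X.line_ids[keep], X.marker_ids, X.values[keep],
                         X.centered, X.scaled)
    test_idx = np.where(cyc_sub == target_cycle)[0]
    train_idx = np.where(cyc_sub != target_cycle)[0]
    method = method.lower()
    if method == "fgge":
        cfg = config or AnalysisConfig(method="fgge")
        res = fit_fgge(y_sub, cyc_sub, X_sub, train_idx, test_idx, cfg)
    elif method == "apge":
        if m is None and (config is None or config.m is None):
            m = max(1, round(0.25 * len(train_idx)))  # 25% of training
        cfg = config or AnalysisConfig(method="apge", m=m)
        res = fit_apge(y_sub, cyc_sub, X_sub, train_idx, test_idx, m, cfg)
    else:
        raise ValueError("forward-cycle prediction uses fgge or apge")
    res.metadata.update(target_cycle=target_cycle,
                        training_cycles=order[:pos],
                        kept_indices=keep)
    return res
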