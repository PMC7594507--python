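"""Seeded simulators for marker panels and multi-environment phenotypes.

Phenotypes are drawn exactly from the generative mixed model

    y = mu + e + g + ge + eps

with e ~ N(0, s2_e Ze Ze'), g ~ N(0, s2_g G~), ge ~ N(0, s2_ge GE~) and
iid residuals, where G~ is the marker kernel normalized to unit mean
diagonal (so s2_g is the average genetic variance and heritabilities are
exact by construction) and GE~ masks G~ by environment sharing.  All true
effect vectors are stored, so the row-exact decomposition of y can be
asserted on every fixture.

The eigen-decay of the kernel is controlled through correlated marker
blocks: ``decay_blocks = b`` draws b independent founder markers and
fills the panel with noisy copies, concentrating the kernel spectrum on
roughly b directions (the fast-decay regime in which low-rank
approximation is safe).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .kernels import MarkerMatrix, build_gblup_kernel
from .streams import stream

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "simulate_markers",
    "simulate_phenotypes",
    "make_benchmark_fixture",
]


@dataclass
class SimulationSpec:
    """Study conditions for one simulated data set."""

    n_per_env: List[int] = field(default_factory=lambda: [100])
    p: int = 200
    freq_range: Tuple[float, float] = (0.05, 0.95)
    shared_lines: bool = False
    mu: float = 0.0
    sigma2_e: float = 0.0
    sigma2_g: float = 1.0
    sigma2_ge: float = 0.0
    sigma2_eps: float = 1.0
    decay_blocks: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1 or len(self.n_per_env) < 1:
            raise ValueError("need p >= 1 and k >= 1")
        for v in (self.sigma2_e, self.sigma2_g, self.sigma2_ge, self.sigma2_eps):
            if v < 0:
                raise ValueError("variances must be >= 0")
        lo, hi = self.freq_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"impossible allele-frequency range {self.freq_range}")
        if self.decay_blocks is not None and self.decay_blocks < 1:
            raise ValueError("decay_blocks must be >= 1")

    @property
    def k(self) -> int:
        return len(self.n_per_env)

    @property
    def n_lines(self) -> int:
        return self.n_per_env[0] if self.shared_lines else sum(self.n_per_env)

    @property
    def n_obs(self) -> int:
        return sum(self.n_per_env)


@dataclass
class SimulatedDataset:
    """Markers, phenotypes and the true effects behind them."""

    markers: MarkerMatrix
    pheno: pd.DataFrame
    truth: pd.DataFrame
    spec: SimulationSpec
    obs_rows: np.ndarray  # marker row per observation

    @property
    def y(self) -> np.ndarray:
        return self.pheno["value"].to_numpy()

    @property
    def env(self) -> np.ndarray:
        return self.pheno["env"].to_numpy()

    @property
    def lines(self) -> np.ndarray:
        return self.pheno["line_id"].to_numpy()

    @property
    def X_obs(self) -> MarkerMatrix:
        """Observation-level marker matrix (unique observation ids)."""
        obs_ids = np.array([f"{l}@{e}" for l, e in
                            zip(self.pheno["line_id"], self.pheno["env"])])
        return MarkerMatrix(obs_ids, self.markers.marker_ids,
                            self.markers.values[self.obs_rows])


def simulate_markers(spec: SimulationSpec,
                     rng: Optional[np.random.Generator] = None) -> MarkerMatrix:
    """Biallelic dosage panel: marker j ~ Binomial(2, q_j) per line."""
    rng = rng or stream(spec.seed, "markers")
    n = spec.n_lines
    lo, hi = spec.freq_range
    if spec.decay_blocks is None:
        q = rng.uniform(lo, hi, size=spec.p)
        V = rng.binomial(2, q[None, :].repeat(n, axis=0)).astype(float)
    else:
        b = min(spec.decay_blocks, spec.p)
        qb = rng.uniform(lo, hi, size=b)
        founders = rng.binomial(2, qb[None, :].repeat(n, axis=0)).astype(float)
        V = np.empty((n, spec.p))
        for j in range(spec.p):
            col = founders[:, j % b].copy()
            flip = rng.random(n) < 0.05  # small perturbation of the copies
            col[flip] = rng.binomial(2, qb[j % b], size=int(flip.sum()))
            V[:, j] = col
    zero_var = V.std(axis=0) == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance marker(s) in the "
                      "simulated panel", UserWarning)
    line_ids = np.array([f"L{i:05d}" for i in range(n)])
    marker_ids = np.array([f"M{j:05d}" for j in range(spec.p)])
    return MarkerMatrix(line_ids, marker_ids, V)


def _normalized_kernel(X: MarkerMatrix) -> np.ndarray:
    K = build_gblup_kernel(X, center=True).values
    d = float(np.mean(np.diag(K)))
    if d <= 0:
        raise ValueError("degenerate marker kernel (all lines identical?)")
    return K / d


def _mvn_factor(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((C + C.T) / 2.0)
    if vals[-1] <= 0:
        raise ValueError("covariance has no positive eigenvalue")
    if vals[0] < -1e-8 * vals[-1]:
        raise ValueError("covariance is not positive semidefinite")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_phenotypes(markers: MarkerMatrix,
                        spec: SimulationSpec) -> SimulatedDataset:
    """Draw phenotypes from the generative model with known components.

    With shared lines the same ``n_per_env[0]`` lines appear in every
    environment; otherwise consecutive slices of the marker matrix form
    disjoint per-environment line sets.  Environment sharing uses E = I
    (interaction effects independent across environments).
    """
    rng = stream(spec.seed, "phenotypes")
    k = spec.k
    if spec.shared_lines:
        if len(set(spec.n_per_env)) != 1:
            raise ValueError("shared_lines needs equal n per environment")
        rows = [np.arange(spec.n_per_env[0]) for _ in range(k)]
    else:
        offs = np.concatenate([[0], np.cumsum(spec.n_per_env)])
        if offs[-1] != markers.n:
            raise ValueError(f"marker matrix has {markers.n} lines, spec "
                             f"needs {offs[-1]}")
        rows = [np.arange(offs[i], offs[i + 1]) for i in range(k)]
    obs_rows = np.concatenate(rows)
    env = np.concatenate([[f"E{i + 1}"] * len(r) for i, r in enumerate(rows)])
    line_ids = markers.line_ids[obs_rows]
    n = len(obs_rows)

    Kt = _normalized_kernel(markers)  # unit mean diagonal

    # genetic main effect: drawn once per line, expanded to observations
    g_line = np.zeros(markers.n)
    if spec.sigma2_g > 0:
        F = _mvn_factor(Kt)
        g_line = np.sqrt(spec.sigma2_g) * (F @ rng.standard_normal(F.shape[1]))
    g = g_line[obs_rows]

    # interaction: independent across environments (E = I), kernel-correlated
    # within an environment
    ge = np.zeros(n)
    if k > 1 and spec.sigma2_ge > 0:
        pos = 0
        for r in rows:
            Fe = _mvn_factor(Kt[np.ix_(r, r)])
            ge[pos:pos + len(r)] = np.sqrt(spec.sigma2_ge) * (
                Fe @ rng.standard_normal(Fe.shape[1]))
            pos += len(r)

    # environment main effect
    e = np.zeros(n)
    if k > 1 and spec.sigma2_e > 0:
        e_env = np.sqrt(spec.sigma2_e) * rng.standard_normal(k)
        pos = 0
        for i, r in enumerate(rows):
            e[pos:pos + len(r)] = e_env[i]
            pos += len(r)

    eps = np.sqrt(spec.sigma2_eps) * rng.standard_normal(n)
    y = spec.mu + e + g + ge + eps

    pheno = pd.DataFrame({"line_id": line_ids, "env": env, "value": y})
    truth_cols = {"line_id": line_ids, "env": env, "g": g, "eps": eps}
    if k > 1:
        truth_cols["e"] = e
        truth_cols["ge"] = ge
    truth = pd.DataFrame(truth_cols)
    return SimulatedDataset(markers, pheno, truth, spec, obs_rows)


_FIXTURES = {
    "tiny": SimulationSpec(n_per_env=[30, 30], p=20, shared_lines=True,
                           mu=2.0, sigma2_e=0.5, sigma2_g=1.0,
                           sigma2_ge=0.5, sigma2_eps=1.0),
    "small": SimulationSpec(n_per_env=[200, 200, 200], p=500,
                            shared_lines=True, mu=5.0, sigma2_e=0.5,
                            sigma2_g=1.0, sigma2_ge=1.0, sigma2_eps=1.0,
                            decay_blocks=40),
    "medium": SimulationSpec(n_per_env=[1000, 1000, 1000], p=1000,
                             shared_lines=False, mu=5.0, sigma2_e=0.5,
                             sigma2_g=1.0, sigma2_ge=1.0, sigma2_eps=1.0,
                             decay_blocks=100),
}


def make_benchmark_fixture(size: str = "tiny", seed: int = 0) -> SimulatedDataset:
    """Documented fixtures: tiny (unit tests), small (recovery tests),
    medium (scaling smoke test)."""
    if size not in _FIXTURES:
        raise ValueError(f"size must be one of {sorted(_FIXTURES)}")
    spec = replace(_FIXTURES[size], seed=seed)
    markers = simulate_markers(spec)
    return simulate_phenotypes(markers, spec)
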