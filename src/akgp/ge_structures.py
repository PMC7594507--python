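"""Main-effect and genotype-by-environment covariance structures.

Multi-environment observations stack records from k environments.  The
environment effect has covariance ``Ze E Ze'`` (E defaults to the
identity, i.e. effects shared within an environment and independent
across environments).  The genetic main effect expands the line kernel K
to observations, ``G = Zg K Zg'``, and the interaction covariance is the
Hadamard product ``GE = G # (Ze E Ze')`` — genetic similarity masked by
environment sharing.  For the approximate path only the n x m and m x m
blocks of G and GE are ever formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kernels import InducingSet, KernelMatrix

__all__ = [
    "EnvironmentDesign",
    "GenotypeDesign",
    "GEBlocks",
    "build_env_covariance",
    "build_main_effect_kernel",
    "build_ge_kernel_full",
    "build_ge_blocks",
]


@dataclass
class EnvironmentDesign:
    """Incidence of observations onto environments, plus the k x k matrix E.

    Environment (column) order is first-appearance order of the labels.
    """

    env_labels: np.ndarray
    E: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.env_labels = np.asarray(self.env_labels)
        self.levels = list(dict.fromkeys(self.env_labels.tolist()))
        self.k = len(self.levels)
        idx = {lab: j for j, lab in enumerate(self.levels)}
        self.env_index = np.array([idx[lab] for lab in self.env_labels.tolist()])
        n = len(self.env_labels)
        self.Z_e = np.zeros((n, self.k))
        self.Z_e[np.arange(n), self.env_index] = 1.0
        if self.E is None:
            self.E = np.eye(self.k)
        else:
            self.E = np.asarray(self.E, dtype=float)
            if self.E.shape != (self.k, self.k):
                raise ValueError(f"E must be {self.k} x {self.k}")
            if np.abs(self.E - self.E.T).max() > 1e-10 * max(1.0, np.abs(self.E).max()):
                raise ValueError("E must be symmetric")
            if np.linalg.eigvalsh(self.E)[0] < -1e-8 * max(np.abs(self.E).max(), 1.0):
                raise ValueError("E must be positive semidefinite")

    @property
    def n(self) -> int:
        return len(self.env_labels)


@dataclass
class GenotypeDesign:
    """Incidence of observations onto the c unique lines."""

    obs_line_ids: np.ndarray
    line_ids: np.ndarray

    def __post_init__(self) -> None:
        self.obs_line_ids = np.asarray(self.obs_line_ids)
        self.line_ids = np.asarray(self.line_ids)
        idx = {lid: j for j, lid in enumerate(self.line_ids.tolist())}
        missing = [l for l in self.obs_line_ids.tolist() if l not in idx]
        if missing:
            raise ValueError(f"observations reference unknown lines: {missing[:5]}")
        self.line_index = np.array([idx[l] for l in self.obs_line_ids.tolist()])

    @property
    def n(self) -> int:
        return len(self.obs_line_ids)

    @property
    def c(self) -> int:
        return len(self.line_ids)

    @property
    def Z_g(self) -> np.ndarray:
        Z = np.zeros((self.n, self.c))
        Z[np.arange(self.n), self.line_index] = 1.0
        return Z


@dataclass
class GEBlocks:
    """Nystrom blocks of the main-effect and interaction kernels."""

    G_nm: np.ndarray
    G_mm: np.ndarray
    GE_nm: np.ndarray
    GE_mm: np.ndarray
    design: EnvironmentDesign
    inducing: InducingSet


def build_env_covariance(design: EnvironmentDesign) -> np.ndarray:
    """n x n covariance structure Ze E Ze' of the environment effect.

    With E = I the entry (i, j) is 1 iff observations i and j share an
    environment.
    """
    M = design.E[np.ix_(design.env_index, design.env_index)]
    return M


def build_main_effect_kernel(K_lines: KernelMatrix,
                             gdesign: GenotypeDesign) -> KernelMatrix:
    """Expand the line kernel to observations: G = Zg K Zg'."""
    idx = {lid: j for j, lid in enumerate(K_lines.line_ids.tolist())}
    missing = [l for l in gdesign.obs_line_ids.tolist() if l not in idx]
    if missing:
        raise ValueError(f"observation lines absent from kernel: {missing[:5]}")
    pos = np.array([idx[l] for l in gdesign.obs_line_ids.tolist()])
    G = K_lines.values[np.ix_(pos, pos)]
    return KernelMatrix(gdesign.obs_line_ids, G)


def build_ge_kernel_full(G: KernelMatrix, design: EnvironmentDesign) -> KernelMatrix:
    """Dense interaction kernel GE = G # (Ze E Ze') (Hadamard product)."""
    if G.n != design.n:
        raise ValueError(f"G is {G.n} x {G.n} but design has {design.n} observations")
    M = build_env_covariance(design)
    return KernelMatrix(G.line_ids, G.values * M)


def build_ge_blocks(G_nm: np.ndarray, G_mm: np.ndarray,
                    design: EnvironmentDesign, inducing: InducingSet,
                    inducing_env: Optional[Sequence] = None) -> GEBlocks:
    """Hadamard-mask the G blocks into the interaction blocks.

    ``GE_nm = G_nm # M_nm`` and ``GE_mm = G_mm # M_mm`` where M = Ze E Ze'
    restricted to the corresponding rows/columns.  ``inducing_env`` gives
    the environment label of each inducing observation; by default it is
    read off ``inducing.strata`` (stratified selection) or from the
    design at the inducing positions.
    """
    G_nm = np.asarray(G_nm, dtype=float)
    G_mm = np.asarray(G_mm, dtype=float)
    if inducing_env is not None:
        env_m = np.asarray(inducing_env)
    elif inducing.strata is not None:
        env_m = np.asarray(inducing.strata)
    else:
        env_m = design.env_labels[inducing.positions]
    idx = {lab: j for j, lab in enumerate(design.levels)}
    unknown = [lab for lab in env_m.tolist() if lab not in idx]
    if unknown:
        raise ValueError(f"unknown environment label(s): {unknown[:5]}")
    m_index = np.array([idx[lab] for lab in env_m.tolist()])
    if np.array_equal(design.E, np.eye(design.k)):
        absent = [lab for lab in design.levels if lab not in set(env_m.tolist())]
        if absent:
            warnings.warn(
                "environment(s) with no inducing lines under E = I: "
                f"{absent}; their interaction effects are not representable "
                "in the approximation", UserWarning)
    M_nm = design.E[np.ix_(design.env_index, m_index)]
    M_mm = design.E[np.ix_(m_index, m_index)]
    return GEBlocks(G_nm, G_mm, G_nm * M_nm, G_mm * M_mm, design, inducing)
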