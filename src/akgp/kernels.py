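"""Genomic kernels, Nystrom blocks, projection bases and spectral diagnostics.

The GBLUP kernel for ``n`` lines genotyped at ``p`` markers is
``K = X_c X_c' / p`` with ``X_c`` the (optionally column-centered/scaled)
dosage matrix.  The mixed model ``y = mu + u + eps`` with
``u ~ N(0, s2_u K)`` is equivalent to a ridge regression on the basis
``P = U S^{1/2}`` from the eigendecomposition ``K = U S U'``.

For large ``n`` the kernel is replaced by its Nystrom reconstruction
``Q = K_nm K_mm^{-1} K_nm'`` built from ``m`` randomly selected inducing
lines; the corresponding ridge basis is ``P = K_nm U_mm S_mm^{-1/2}``,
which satisfies ``P P' = Q`` without ever materializing the full n x n
kernel.  The diagnostic ``phi(m)`` — the percentage of total kernel
variance held by the top-m eigenvalues of the *full* kernel — predicts
when the approximation is safe (rule of thumb: phi > 98).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "MarkerMatrix",
    "KernelSpec",
    "KernelMatrix",
    "InducingSet",
    "NystromBlocks",
    "SpectralDecomposition",
    "ProjectionBasis",
    "PhiCurve",
    "impute_markers",
    "build_gblup_kernel",
    "build_gaussian_kernel",
    "select_inducing_lines",
    "nystrom_blocks",
    "nystrom_dense",
    "projection_full",
    "projection_approx",
    "phi_retained",
    "phi_curve",
]

#: relative eigenvalue truncation used everywhere a pseudo-inverse or
#: low-rank basis is formed; near-duplicate inducing lines make hard
#: inverses numerically unsafe.
EIG_TRUNCATION = 1e-10

#: relative symmetry tolerance for kernel matrices.
SYM_TOL = 1e-10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerMatrix:
    """Lines x markers allele-dosage matrix (the ``X`` of the model)."""

    line_ids: np.ndarray
    marker_ids: np.ndarray
    values: np.ndarray
    centered: bool = False
    scaled: bool = False

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 lines and p >= 1 markers, got {n} x {p}")
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise ValueError("id lengths do not match the dosage matrix")
        if len(set(self.line_ids.tolist())) != n:
            raise ValueError("duplicate line ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


@dataclass
class KernelSpec:
    """Which kernel to build: linear GBLUP or Gaussian."""

    kind: str = "linear"
    bandwidth: float = 1.0
    scale_percentile: float = 50.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian" and self.bandwidth <= 0:
            raise ValueError("gaussian bandwidth h must be > 0")
        if not 0 < self.scale_percentile <= 100:
            raise ValueError("scale_percentile must be in (0, 100]")


@dataclass
class KernelMatrix:
    """Symmetric PSD similarity matrix over lines (or observations)."""

    line_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids)
        self.values = np.asarray(self.values, dtype=float)
        K = self.values
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kernel must be square")
        scale = max(np.abs(K).max(), 1.0)
        if np.abs(K - K.T).max() > SYM_TOL * scale:
            raise ValueError("kernel matrix is not symmetric within tolerance")
        # exact symmetrization of round-off
        self.values = (K + K.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


@dataclass
class InducingSet:
    """The m randomly selected lines whose kernel slice defines Q."""

    selected_ids: np.ndarray
    positions: np.ndarray
    strata: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.selected_ids = np.asarray(self.selected_ids)
        self.positions = np.asarray(self.positions, dtype=int)
        if len(self.selected_ids) == 0:
            raise ValueError("inducing set is empty")
        if len(set(self.selected_ids.tolist())) != len(self.selected_ids):
            raise ValueError("duplicate inducing ids")

    @property
    def m(self) -> int:
        return len(self.selected_ids)


@dataclass
class NystromBlocks:
    """K_nm (all lines vs inducing) and K_mm (inducing vs inducing)."""

    K_nm: np.ndarray
    K_mm: np.ndarray
    inducing: InducingSet
    row_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.K_nm = np.asarray(self.K_nm, dtype=float)
        self.K_mm = np.asarray(self.K_mm, dtype=float)
        m = self.inducing.m
        if self.K_mm.shape != (m, m) or self.K_nm.shape[1] != m:
            raise ValueError("block shapes inconsistent with inducing set")
        self.K_mm = (self.K_mm + self.K_mm.T) / 2.0

    @property
    def n(self) -> int:
        return self.K_nm.shape[0]

    @property
    def m(self) -> int:
        return self.K_mm.shape[0]


@dataclass
class SpectralDecomposition:
    """Retained eigen pairs (descending), truncated at a relative tolerance."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    retained_rank: int
    truncation_tol: float


@dataclass
class ProjectionBasis:
    """Ridge-regression design whose Gram matrix reconstructs the kernel.

    ``source='full'``  : P = U S^{1/2}, P P' = K (within truncation).
    ``source='approx'``: P = K_nm U_mm S_mm^{-1/2}, P P' = Q exactly.
    """

    P: np.ndarray
    source: str
    row_ids: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def rank(self) -> int:
        return self.P.shape[1]

    def gram(self) -> np.ndarray:
        return self.P @ self.P.T


@dataclass
class PhiCurve:
    """Cumulative percent of kernel variance vs number of eigenvalues kept."""

    eigenvalues: np.ndarray
    cumulative_percent: np.ndarray

    def phi(self, m: int) -> float:
        return float(self.cumulative_percent[m - 1])


# ---------------------------------------------------------------------------
# marker preprocessing
# ---------------------------------------------------------------------------

def impute_markers(X: MarkerMatrix) -> MarkerMatrix:
    """Replace missing dosages by their marker (column) mean."""
    V = X.values
    if not np.isnan(V).any():
        return X
    V = V.copy()
    all_missing = np.isnan(V).all(axis=0)
    if all_missing.any():
        bad = X.marker_ids[all_missing]
        raise ValueError(f"markers with all values missing: {list(bad[:5])}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_means = np.nanmean(V, axis=0)
    idx = np.where(np.isnan(V))
    V[idx] = col_means[idx[1]]
    return MarkerMatrix(X.line_ids, X.marker_ids, V, X.centered, X.scaled)


def _center_scale(V: np.ndarray, marker_ids: np.ndarray, center: bool,
                  scale: bool, means: Optional[np.ndarray] = None,
                  sds: Optional[np.ndarray] = None) -> np.ndarray:
    """Apply column centering/scaling, optionally with supplied statistics."""
    out = V
    if center:
        mu = V.mean(axis=0) if means is None else means
        out = out - mu
    if scale:
        sd = V.std(axis=0, ddof=0) if sds is None else sds
        zero = sd <= 0
        if zero.any():
            bad = marker_ids[zero]
            raise ValueError(f"zero-variance marker(s) with scale=on: {list(bad[:5])}")
        out = out / sd
    return out


# ---------------------------------------------------------------------------
# kernel construction
# ---------------------------------------------------------------------------

def build_gblup_kernel(X: MarkerMatrix, center: bool = True,
                       scale: bool = False) -> KernelMatrix:
    """Linear (GBLUP) kernel K = X_c X_c' / p."""
    if X.has_missing():
        raise ValueError("marker matrix has missing values; impute first")
    Xc = _center_scale(X.values, X.marker_ids, center, scale)
    K = Xc @ Xc.T / X.p
    return KernelMatrix(X.line_ids, K)


def build_gaussian_kernel(X: MarkerMatrix, spec: KernelSpec) -> KernelMatrix:
    """Gaussian kernel K_h(x_i, x_i') = exp(-h d2_{ii'} / q).

    ``q`` is the ``spec.scale_percentile`` percentile of the off-diagonal
    squared Euclidean distances; it rescales the bandwidth h so that h ~ 1
    is a sensible default regardless of marker count.
    """
    if spec.kind != "gaussian":
        raise ValueError("spec.kind must be 'gaussian'")
    if X.has_missing():
        raise ValueError("marker matrix has missing values; impute first")
    d2 = pdist(X.values, metric="sqeuclidean")
    q = float(np.percentile(d2, spec.scale_percentile))
    if q <= 0:
        raise ValueError("all lines identical: distance scale q = 0")
    from scipy.spatial.distance import squareform

    D2 = squareform(d2)
    K = np.exp(-spec.bandwidth * D2 / q)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(X.line_ids, K)


# ---------------------------------------------------------------------------
# inducing lines and Nystrom blocks
# ---------------------------------------------------------------------------

def select_inducing_lines(train_ids: Sequence, m: int,
                          strata: Optional[Sequence] = None,
                          seed: int = 0) -> InducingSet:
    """Uniform random sample (without replacement) of m inducing lines.

    With ``strata`` (one environment label per training line) the sample is
    stratified: floor(m/k) lines per environment, the remainder going one
    each to the largest strata.
    """
    train_ids = np.asarray(train_ids)
    n_train = len(train_ids)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > n_train:
        warnings.warn(f"m = {m} exceeds training size {n_train}; clamped",
                      UserWarning)
        m = n_train
    rng = np.random.default_rng(seed)
    if strata is None:
        pos = np.sort(rng.choice(n_train, size=m, replace=False))
        sel_strata = None
    else:
        strata = np.asarray(strata)
        if len(strata) != n_train:
            raise ValueError("strata length must match train_ids")
        labels = list(dict.fromkeys(strata.tolist()))  # first-appearance order
        k = len(labels)
        base = m // k
        rem = m - base * k
        sizes = {lab: int((strata == lab).sum()) for lab in labels}
        # remainder to the largest strata (ties: first-appearance order)
        order = sorted(labels, key=lambda lab: -sizes[lab])
        quota = {lab: base for lab in labels}
        for lab in order[:rem]:
            quota[lab] += 1
        pos_parts = []
        for lab in labels:
            want = quota[lab]
            members = np.where(strata == lab)[0]
            if want > len(members):
                raise ValueError(
                    f"stratum {lab!r} has {len(members)} lines, "
                    f"{want} requested")
            if want:
                pos_parts.append(rng.choice(members, size=want, replace=False))
        pos = np.sort(np.concatenate(pos_parts)) if pos_parts else np.array([], int)
        sel_strata = strata[pos]
    return InducingSet(train_ids[pos], pos, sel_strata, seed)


def nystrom_blocks(X: MarkerMatrix, inducing: InducingSet,
                   spec: Optional[KernelSpec] = None, center: bool = True,
                   scale: bool = False) -> NystromBlocks:
    """K_nm and K_mm without materializing the full n x n kernel.

    Centering/scaling statistics come from ALL n lines (the full-data
    convention), so the blocks are exact sub-blocks of the full kernel.
    For the Gaussian kernel the distance scale q is the percentile of the
    n x m cross distances excluding self pairs (the full off-diagonal set
    is unavailable without the n x n matrix).
    """
    spec = spec or KernelSpec()
    if X.has_missing():
        raise ValueError("marker matrix has missing values; impute first")
    id_to_pos = {lid: i for i, lid in enumerate(X.line_ids.tolist())}
    missing = [lid for lid in inducing.selected_ids.tolist() if lid not in id_to_pos]
    if missing:
        raise ValueError(f"inducing ids not in marker matrix: {missing[:5]}")
    rows = np.array([id_to_pos[lid] for lid in inducing.selected_ids.tolist()])
    if spec.kind == "linear":
        Xc = _center_scale(X.values, X.marker_ids, center, scale)
        Xm = Xc[rows]
        K_nm = Xc @ Xm.T / X.p
        K_mm = Xm @ Xm.T / X.p
    else:
        D2 = cdist(X.values, X.values[rows], metric="sqeuclidean")
        off = D2[D2 > 0]
        if off.size == 0:
            raise ValueError("all lines identical: distance scale q = 0")
        q = float(np.percentile(off, spec.scale_percentile))
        K_nm = np.exp(-spec.bandwidth * D2 / q)
        K_mm = K_nm[rows]
    blocks = NystromBlocks(K_nm, K_mm, inducing, row_ids=X.line_ids)
    blocks.positions_in_X = rows  # row index of each inducing line in X
    return blocks


def _eigh_truncated(A: np.ndarray, tol: float) -> SpectralDecomposition:
    """Descending eigendecomposition with tiny negatives clipped and
    eigenvalues below ``tol * max`` dropped."""
    vals, vecs = np.linalg.eigh((A + A.T) / 2.0)
    vals = vals[::-1]
    vecs = vecs[:, ::-1]
    vals = np.clip(vals, 0.0, None)
    top = vals[0] if vals.size else 0.0
    if top <= 0:
        raise ValueError("matrix has no positive eigenvalue")
    r = int(np.sum(vals > tol * top))
    return SpectralDecomposition(vals[:r], vecs[:, :r], r, tol)


def nystrom_dense(blocks: NystromBlocks, tol: float = EIG_TRUNCATION) -> KernelMatrix:
    """Dense Q = K_nm K_mm^+ K_nm' (testing utility; small n only).

    K_mm is inverted through its truncated eigendecomposition.
    """
    dec = _eigh_truncated(blocks.K_mm, tol)
    B = blocks.K_nm @ (dec.eigenvectors / dec.eigenvalues)  # K_nm U S^-1
    Q = B @ (dec.eigenvectors.T @ blocks.K_nm.T)
    Q = (Q + Q.T) / 2.0
    return KernelMatrix(np.arange(blocks.n), Q)


# ---------------------------------------------------------------------------
# projection bases
# ---------------------------------------------------------------------------

def projection_full(K: KernelMatrix, tol: float = EIG_TRUNCATION):
    """Exact ridge basis P = U S^{1/2} of the full kernel.

    Returns the basis together with the spectral decomposition (whose
    eigenvalues also feed the phi diagnostic).
    """
    dec = _eigh_truncated(K.values, tol)
    P = dec.eigenvectors * np.sqrt(dec.eigenvalues)
    basis = ProjectionBasis(P, "full", K.line_ids)
    return basis, dec


def projection_approx(blocks: NystromBlocks, tol: float = EIG_TRUNCATION) -> ProjectionBasis:
    """Nystrom ridge basis P = K_nm U_mm S_mm^{-1/2}; P P' = Q exactly."""
    dec = _eigh_truncated(blocks.K_mm, tol)
    P = blocks.K_nm @ (dec.eigenvectors / np.sqrt(dec.eigenvalues))
    ids = blocks.row_ids if blocks.row_ids is not None else np.arange(blocks.n)
    return ProjectionBasis(P, "approx", np.asarray(ids))


# ---------------------------------------------------------------------------
# spectral diagnostics
# ---------------------------------------------------------------------------

def phi_retained(eigenvalues: np.ndarray, m: int) -> float:
    """phi(m) = 100 * sum of the top-m eigenvalues / sum of all."""
    s = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    if s.sum() <= 0:
        raise ValueError("all-zero spectrum")
    if not 1 <= m <= len(s):
        raise ValueError(f"m must be in [1, {len(s)}]")
    s = np.sort(s)[::-1]
    return float(100.0 * s[:m].sum() / s.sum())


def phi_curve(eigenvalues: np.ndarray) -> PhiCurve:
    """phi(m) for every m = 1..n (eigenvalues of the FULL kernel)."""
    s = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    if s.sum() <= 0:
        raise ValueError("all-zero spectrum")
    s = np.sort(s)[::-1]
    cum = 100.0 * np.cumsum(s) / s.sum()
    cum[-1] = 100.0
    return PhiCurve(s, cum)
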