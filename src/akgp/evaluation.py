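"""Cross-validation design, accuracy metrics and table-style summaries.

Accuracy is assessed over independent random training/testing partitions
(default: 20 replicates, 80% training), reporting per replicate the
Pearson correlation (CORR) and prediction mean squared error (PMSE)
between predicted and observed test values, plus the fitted residual
variance; summaries are means with (n-1)-denominator SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .streams import derive_seed

__all__ = [
    "PartitionSet",
    "CVSummary",
    "make_partitions",
    "corr_metric",
    "pmse_metric",
    "cv_run",
]


@dataclass
class PartitionSet:
    """Independent random train/test splits (not k-fold)."""

    replicates: List[Tuple[np.ndarray, np.ndarray]]
    train_fraction: float = 0.8
    n_reps: int = 20
    seed: int = 0

    def __iter__(self):
        return iter(self.replicates)

    def __len__(self):
        return len(self.replicates)


@dataclass
class CVSummary:
    """Per-replicate metrics plus their means and SDs."""

    per_rep: pd.DataFrame
    method: str = ""
    m: Optional[int] = None
    phi: Optional[float] = None
    failures: List[int] = field(default_factory=list)

    @property
    def mean_corr(self) -> float:
        return float(self.per_rep["corr"].mean())

    @property
    def sd_corr(self) -> float:
        return float(self.per_rep["corr"].std(ddof=1))

    @property
    def mean_pmse(self) -> float:
        return float(self.per_rep["pmse"].mean())

    @property
    def mean_sigma2_eps(self) -> float:
        return float(self.per_rep["sigma2_eps"].mean())

    def table(self) -> pd.DataFrame:
        """Mean (sd) rows for CORR / PMSE / sigma2_eps."""
        rows = {}
        for metric in ("corr", "pmse", "sigma2_eps"):
            mu = self.per_rep[metric].mean()
            sd = self.per_rep[metric].std(ddof=1)
            rows[metric] = f"{mu:.3f} ({sd:.3f})"
        return pd.DataFrame.from_dict(rows, orient="index", columns=["mean (sd)"])


def make_partitions(ids: Sequence, fraction: float = 0.8, reps: int = 20,
                    seed: int = 0) -> PartitionSet:
    """``reps`` independent uniform train/test splits of ``ids``.

    Replicate r draws from the derived stream (seed, r); same seed, same
    partitions.  Returned replicates hold positional indices into ``ids``.
    """
    ids = np.asarray(ids)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 ids to partition")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(round(fraction * n))
    if n_train == n or n_train == 0:
        raise ValueError(f"fraction {fraction} yields an empty train or test set")
    reps_out = []
    for r in range(reps):
        rng = np.random.default_rng(derive_seed(seed, "partitions", r))
        perm = rng.permutation(n)
        reps_out.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return PartitionSet(reps_out, fraction, reps, seed)


def corr_metric(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Pearson correlation between predicted and observed values."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed):
        raise ValueError("length mismatch")
    if len(predicted) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        warnings.warn("zero variance: correlation undefined", UserWarning)
        return float("nan")
    return float(sps.pearsonr(predicted, observed).statistic)


def pmse_metric(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Mean of the squared differences between predicted and observed."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed):
        raise ValueError("length mismatch")
    if len(predicted) < 1:
        raise ValueError("need at least 1 pair")
    return float(np.mean((predicted - observed) ** 2))


def cv_run(data, config, partitions: PartitionSet,
           split_by: str = "observation") -> CVSummary:
    """Run the configured pipeline once per partition and aggregate.

    ``data`` must expose ``y`` (phenotypes), ``X_obs`` (observation-level
    MarkerMatrix) and, for the GE methods, ``env``.  With
    ``split_by='line'`` the partitions are over unique lines (every
    observation of a line goes to the same side), the convention for data
    where the same lines appear in all environments.
    """
    from . import pipelines  # deferred: pipelines imports the metrics above

    y = np.asarray(data.y, dtype=float)
    X = data.X_obs
    env = getattr(data, "env", None)
    rows, failures = [], []
    for r, (tr, te) in enumerate(partitions):
        if split_by == "line":
            lines = np.asarray(data.lines)
            uniq = np.asarray(list(dict.fromkeys(lines.tolist())))
            tr_lines = set(uniq[tr].tolist())
            tr_idx = np.where(np.isin(lines, list(tr_lines)))[0]
            te_idx = np.setdiff1d(np.arange(len(y)), tr_idx)
        else:
            tr_idx, te_idx = tr, te
        cfg = pipelines.AnalysisConfig(
            method=config.method, kernel=config.kernel, m=config.m,
            stratified=config.stratified, chain=config.chain,
            seed=derive_seed(config.seed, "cv-rep", r),
            standardize_y=config.standardize_y,
            report_phi=config.report_phi and r == 0,
            center=config.center, scale=config.scale,
            force_full=config.force_full)
        try:
            if cfg.method == "fgse":
                res = pipelines.fit_fgse(y, X, tr_idx, te_idx, cfg)
            elif cfg.method == "apse":
                res = pipelines.fit_apse(y, X, tr_idx, te_idx, cfg.m, cfg)
            elif cfg.method == "fgge":
                res = pipelines.fit_fgge(y, env, X, tr_idx, te_idx, cfg)
            else:
                res = pipelines.fit_apge(y, env, X, tr_idx, te_idx, cfg.m, cfg)
        except Exception as err:  # noqa: BLE001 - per-replicate failures recorded
            warnings.warn(f"replicate {r} failed: {err}", UserWarning)
            failures.append(r)
            continue
        rows.append({"rep": r, "corr": res.test_corr, "pmse": res.test_pmse,
                     "sigma2_eps": res.sigma2_eps, "phi": res.phi,
                     "m": res.m})
    if not rows:
        raise RuntimeError("every CV replicate failed")
    per_rep = pd.DataFrame(rows).set_index("rep")
    phi_vals = per_rep["phi"].dropna()
    return CVSummary(per_rep, method=config.method, m=config.m,
                     phi=float(phi_vals.iloc[0]) if len(phi_vals) else None,
                     failures=failures)
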