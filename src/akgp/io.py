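"""File I/O: genotype and phenotype tables, kernels, spectra, manifests.

TSV is the canonical interchange format (dense line x marker matrices fit
no standard bioinformatics container).  PLINK ``.raw``-style files are
accepted for genotypes because genomic-selection dosage matrices commonly
arrive that way.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .kernels import KernelMatrix, MarkerMatrix

__all__ = [
    "RunManifest",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_kernel",
    "write_kernel",
    "write_spectrum",
]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
_MISSING_CODES = {"NA", "NaN", "nan", ""}


@dataclass
class RunManifest:
    """Everything needed to re-run a command bit-identically."""

    command: str
    config: Dict
    seed: int
    version: str
    input_checksums: Dict[str, str] = field(default_factory=dict)
    stage_timings: Dict[str, float] = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        payload = {k: getattr(self, k) for k in
                   ("command", "config", "seed", "version", "input_checksums",
                    "stage_timings", "outputs", "created")}
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")

    @staticmethod
    def checksum(path) -> str:
        h = hashlib.sha256()
        h.update(Path(path).read_bytes())
        return h.hexdigest()


def _to_float(df: pd.DataFrame, path) -> np.ndarray:
    df = df.replace(list(_MISSING_CODES), np.nan)
    try:
        return df.astype(float).to_numpy()
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric genotype cell ({err})") from err


def read_genotypes(path, dialect: str = "tsv") -> MarkerMatrix:
    """Read a dosage matrix.

    ``tsv``/``csv``: first column is the line id, header row holds marker
    ids.  ``plink_raw``: whitespace-separated with the six PLINK metadata
    columns; IID becomes the line id and -9 is an extra missing code.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genotype file not found: {path}")
    if dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        missing_meta = [c for c in _PLINK_META if c not in df.columns]
        if missing_meta:
            raise ValueError(f"{path}: not a plink_raw file "
                             f"(missing {missing_meta})")
        ids = df["IID"].astype(str).to_numpy()
        body = df.drop(columns=_PLINK_META).replace(-9, np.nan)
        values = _to_float(body, path)
        marker_ids = np.asarray(body.columns)
    elif dialect in ("tsv", "csv"):
        sep = "\t" if dialect == "tsv" else ","
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected id column plus markers")
        ids = df.iloc[:, 0].to_numpy()
        values = _to_float(df.iloc[:, 1:], path)
        marker_ids = np.asarray(df.columns[1:])
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    if len(set(ids.tolist())) != len(ids):
        dupes = pd.Series(ids).value_counts()
        raise ValueError(f"{path}: duplicate line ids "
                         f"{list(dupes[dupes > 1].index[:5])}")
    return MarkerMatrix(ids, marker_ids, values)


def write_genotypes(X: MarkerMatrix, path) -> None:
    df = pd.DataFrame(X.values, columns=X.marker_ids)
    df.insert(0, "line_id", X.line_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table: columns line_id, env (optional), value.

    Missing values stay as NaN (they mark prediction targets).  A file
    without an env column gets the single environment ``E1``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"phenotype file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if "line_id" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: need columns line_id and value")
    if "env" not in df.columns:
        df["env"] = "E1"
    df = df[["line_id", "env", "value"]].copy()
    df["line_id"] = df["line_id"].astype(str)
    df["env"] = df["env"].astype(str)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    dup = df.duplicated(subset=["line_id", "env"])
    if dup.any():
        pairs = df.loc[dup, ["line_id", "env"]].head(5).to_records(index=False)
        raise ValueError(f"{path}: duplicate (line_id, env) pairs {list(pairs)}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_kernel(K: KernelMatrix, path) -> None:
    df = pd.DataFrame(K.values, index=K.line_ids, columns=K.line_ids)
    df.to_csv(path, sep="\t", index_label="line_id")


def read_kernel(path) -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KernelMatrix(np.asarray(df.index), df.to_numpy(dtype=float))


def write_spectrum(eigenvalues: np.ndarray, path) -> None:
    """Two-column spectrum (rank, eigenvalue) plus the cumulative phi curve."""
    from .kernels import phi_curve

    curve = phi_curve(eigenvalues)
    df = pd.DataFrame({
        "rank": np.arange(1, len(curve.eigenvalues) + 1),
        "eigenvalue": curve.eigenvalues,
        "phi": curve.cumulative_percent,
    })
    df.to_csv(path, sep="\t", index=False)
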