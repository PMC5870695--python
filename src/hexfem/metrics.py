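"""Forward-accuracy error measures.

Two standard measures compare a numerical electrode-potential topography
u_num with a reference u_ref:

    RDM(u_num, u_ref)   = || u_num/||u_num||  -  u_ref/||u_ref|| ||_2
    lnMAG(u_num, u_ref) = ln( ||u_num|| / ||u_ref|| )

RDM is the l2 distance of the unit-normalized topographies (range [0, 2]; 0 =
identical shape, 2 = sign-flipped shape) and is scale-invariant in each
argument; lnMAG is the log magnitude ratio (0 = equal magnitude, positive =
overestimated magnitude).  Both are computed in the average-reference gauge by
default, since a common-mode offset is a reference choice, not an error.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fem import Leadfield, average_reference

DEFAULT_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.9, 0.95, 1.0)


def _prep(u: np.ndarray, rereference: bool) -> np.ndarray:
    u = np.asarray(u, dtype=float).ravel()
    if u.size < 2:
        raise ValueError("potential vectors need length >= 2")
    if rereference:
        u = u - u.mean()
    n = np.linalg.norm(u)
    if n == 0.0:
        raise ValueError("zero-norm potential vector: RDM/lnMAG undefined")
    return u / n


def rdm(u_num: np.ndarray, u_ref: np.ndarray, rereference: bool = True) -> float:
    """Relative difference measure in [0, 2]; scale-invariant, symmetric."""
    a = _prep(u_num, rereference)
    b = _prep(u_ref, rereference)
    if a.shape != b.shape:
        raise ValueError("potential vectors must have equal length")
    return float(np.linalg.norm(a - b))


def lnmag(u_num: np.ndarray, u_ref: np.ndarray, rereference: bool = True) -> float:
    """Log magnitude error ln(||u_num|| / ||u_ref||); antisymmetric."""
    a = np.asarray(u_num, dtype=float).ravel()
    b = np.asarray(u_ref, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("potential vectors must have equal length")
    if rereference:
        a, b = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-norm potential vector: lnMAG undefined")
    return float(np.log(na / nb))


@dataclass
class ErrorReport:
    """Per-topography RDM/lnMAG arrays plus cumulative quantile summaries."""

    rdm: np.ndarray
    lnmag: np.ndarray
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES

    def summary(self) -> pd.DataFrame:
        q = np.asarray(self.quantiles)
        return pd.DataFrame(
            {
                "quantile": q,
                "rdm": np.quantile(self.rdm, q),
                "lnmag": np.quantile(self.lnmag, q),
                "abs_lnmag": np.quantile(np.abs(self.lnmag), q),
            }
        )

    def per_source(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"column": np.arange(len(self.rdm)), "rdm": self.rdm, "lnmag": self.lnmag}
        )

    def to_tsv(self, path) -> None:
        per = self.per_source()
        per.insert(0, "row_type", "column")
        summ = self.summary()
        summ.insert(0, "row_type", "quantile")
        pd.concat([per, summ], axis=0).to_csv(path, sep="\t", index=False)


def error_sweep(
    num: Leadfield | np.ndarray,
    ref: Leadfield | np.ndarray,
    rereference: bool = True,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
) -> ErrorReport:
    """Column-wise RDM/lnMAG between two matched leadfields.

    Each column is one topography (one source position and moment axis); the
    two matrices must share electrodes, source space and reference.
    """
    A = num.matrix if isinstance(num, Leadfield) else np.asarray(num, dtype=float)
    B = ref.matrix if isinstance(ref, Leadfield) else np.asarray(ref, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"leadfield shape mismatch: {A.shape} vs {B.shape}")
    if rereference:
        A, B = average_reference(A), average_reference(B)
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    if np.any(na == 0.0) or np.any(nb == 0.0):
        raise ValueError("zero-norm leadfield column")
    rdms = np.linalg.norm(A / na - B / nb, axis=0)
    lnmags = np.log(na / nb)
    return ErrorReport(rdm=rdms, lnmag=lnmags, quantiles=quantiles)
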