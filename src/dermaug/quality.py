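"""Real-vs-synthetic fidelity metrics: HD, PCD, MAEP, RSVR.

Given a feature x present in the real data (PMF P_x) and the synthetic data
(PMF Q_x over the same k_x bins):

* Hellinger distance ``HD = (1/sqrt(2)) * sqrt(sum_j (sqrt(P(j)) - sqrt(Q(j)))^2)``
  in [0, 1]; 0 for identical PMFs, 1 for disjoint supports.
* ``MAEP = sum_j |P(j) - Q(j)|`` in [0, 2] (the summed absolute PMF error; a
  ``mean=True`` flag divides by k_x for users expecting a per-bin mean).
* ``PCD = || Corr(X_real) - Corr(X_syn) ||_F``, the Frobenius norm of the
  difference of Pearson correlation matrices (constant columns contribute
  correlation 0 by convention).
* ``RSVR`` = fraction of synthetic rows that exactly duplicate an earlier
  synthetic row (duplicates within the synthetic set only).

Continuous features are turned into PMFs by equal-width binning over the
pooled min-max of both columns (default 20 bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class PMFPair:
    """Aligned probability mass functions (real, synthetic) for one feature."""

    P: np.ndarray
    Q: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.P.shape != self.Q.shape or self.P.ndim != 1 or len(self.P) < 1:
            raise ValidationError("PMFPair: P and Q must be 1-D of equal length >= 1")
        for name, v in (("P", self.P), ("Q", self.Q)):
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValidationError(f"{name}: must be non-negative and sum to 1")


@dataclass
class QualityReport:
    """Per-feature HD/MAEP with their means, plus global PCD and RSVR."""

    hd: dict[str, float]
    maep: dict[str, float]
    pcd: float
    rsvr: float

    @property
    def mean_hd(self) -> float:
        return float(np.mean(list(self.hd.values())))

    @property
    def mean_maep(self) -> float:
        return float(np.mean(list(self.maep.values())))

    def to_dict(self) -> dict:
        return {
            "mean_hd": self.mean_hd,
            "mean_maep": self.mean_maep,
            "pcd": self.pcd,
            "rsvr": self.rsvr,
            "per_feature_hd": self.hd,
            "per_feature_maep": self.maep,
        }


def discretize_pair(real_col, syn_col, n_bins: int = 20) -> PMFPair:
    """Equal-width binning over the pooled min-max; zero-count bins allowed."""
    r = np.asarray(real_col, dtype=float).ravel()
    s = np.asarray(syn_col, dtype=float).ravel()
    if len(r) == 0 or len(s) == 0:
        raise ValidationError("columns: must be non-empty")
    if not (np.isfinite(r).all() and np.isfinite(s).all()):
        raise ValidationError("columns: values must be finite")
    lo = min(r.min(), s.min())
    hi = max(r.max(), s.max())
    if hi - lo < 1e-12:  # both constant and equal -> single shared bin
        return PMFPair(P=np.ones(1), Q=np.ones(1))
    edges = np.linspace(lo, hi, n_bins + 1)
    P, _ = np.histogram(r, bins=edges)
    Q, _ = np.histogram(s, bins=edges)
    return PMFPair(P=P / P.sum(), Q=Q / Q.sum())


def hellinger(pair: PMFPair) -> float:
    """Hellinger distance in [0, 1]."""
    d = np.sqrt(pair.P) - np.sqrt(pair.Q)
    return float(np.clip(np.sqrt((d**2).sum()) / np.sqrt(2.0), 0.0, 1.0))


def maep(pair: PMFPair, mean: bool = False) -> float:
    """Summed absolute PMF error in [0, 2] (``mean=True`` divides by k_x)."""
    total = float(np.abs(pair.P - pair.Q).sum())
    return total / len(pair.P) if mean else total


def _corr_zero_constant(X: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix with constant columns set to correlation 0."""
    sd = X.std(axis=0)
    live = sd > 0
    D = X.shape[1]
    C = np.zeros((D, D))
    if live.sum() >= 2:
        C[np.ix_(live, live)] = np.corrcoef(X[:, live], rowvar=False)
    elif live.sum() == 1:
        i = int(np.flatnonzero(live)[0])
        C[i, i] = 1.0
    np.fill_diagonal(C, 1.0)
    return C


def pcd(X_real, X_syn) -> float:
    """Frobenius norm of the difference between Pearson correlation matrices."""
    Xr = np.asarray(X_real, dtype=float)
    Xs = np.asarray(X_syn, dtype=float)
    if Xr.ndim != 2 or Xs.ndim != 2 or Xr.shape[1] != Xs.shape[1]:
        raise ValidationError("X: expected 2-D arrays with matching feature count")
    if Xr.shape[1] < 2:
        raise ValidationError("X: PCD needs >= 2 features")
    if len(Xr) < 3 or len(Xs) < 3:
        raise ValidationError("X: PCD needs >= 3 rows on each side")
    return float(np.linalg.norm(_corr_zero_constant(Xr) - _corr_zero_constant(Xs), "fro"))


def rsvr(X_syn) -> float:
    """Repeated-sample-vector rate: duplicate synthetic rows / total rows.

    Exact value equality; a row is a duplicate if an identical row appeared
    earlier in the synthetic set.  Empty input -> 0.
    """
    X = np.asarray(X_syn)
    if X.size == 0:
        return 0.0
    X = np.atleast_2d(X)
    seen: set[bytes] = set()
    dupes = 0
    for row in X:
        key = row.tobytes()
        if key in seen:
            dupes += 1
        else:
            seen.add(key)
    return dupes / len(X)


def quality_report(X_real, X_syn, n_bins: int = 20,
                   feature_names: list[str] | None = None) -> QualityReport:
    """Full fidelity summary; feature sets must match."""
    Xr = pd.DataFrame(X_real)
    Xs = pd.DataFrame(X_syn)
    if feature_names is not None:
        Xr.columns = Xs.columns = list(feature_names)
    if list(Xr.columns) != list(Xs.columns):
        raise ValidationError("features: real and synthetic columns must match")
    hd_map: dict[str, float] = {}
    maep_map: dict[str, float] = {}
    for col in Xr.columns:
        pair = discretize_pair(Xr[col].to_numpy(), Xs[col].to_numpy(), n_bins)
        hd_map[str(col)] = hellinger(pair)
        maep_map[str(col)] = maep(pair)
    return QualityReport(
        hd=hd_map,
        maep=maep_map,
        pcd=pcd(Xr.to_numpy(dtype=float), Xs.to_numpy(dtype=float)),
        rsvr=rsvr(Xs.to_numpy()),
    )
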