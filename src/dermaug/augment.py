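"""Imbalance-ratio-targeted minority oversampling for feature tables.

Melanoma rows are the minority in real dermoscopy tables, and the study
design sweeps the post-augmentation balance ratio
``r = (n_min + n_syn) / n_maj`` over {0.5, ..., 1.0} (1.0 = balanced).  Note
that the *dataset-overview* imbalance ratio (majority/minority, e.g. 4.00 for
a 160/40 table) is a different quantity, exposed as
:meth:`dermaug.datatypes.FeatureTable.imbalance_ratio`.

Three oversamplers share one contract (fit on training rows, emit exactly
``n_syn`` minority rows flagged ``source="synthetic"``):

* SMOTE, implemented here: each synthetic row is ``x + u * (x_nn - x)`` with
  ``u ~ U(0, 1)`` and ``x_nn`` one of the k nearest minority neighbours
  (Euclidean on z-scored features), so outputs stay inside the minority
  convex hull.
* CTGAN / TVAE adapters, which delegate to the ``sdv`` library when it is
  installed and raise :class:`CapabilityError` otherwise -- the SMOTE path
  always works.

The module also implements the mode-specific normalization transform used by
conditional tabular GANs as a standalone, reversible encoder: a variational
Gaussian mixture estimates the modes of each continuous column, each value is
assigned a mode by responsibility and encoded as (one-hot mode indicator,
within-mode standardized scalar).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import BayesianGaussianMixture
from sklearn.neighbors import NearestNeighbors

from .datatypes import SOURCE_SYNTHETIC, FeatureTable
from .errors import CapabilityError, ValidationError

OVERSAMPLERS = ("smote", "ctgan", "tvae")


@dataclass(frozen=True)
class IRSpec:
    """Class counts plus the sweep's target balance ratio r in (0, 1]."""

    n_min: int
    n_maj: int
    target_balance_ratio: float = 1.0

    def __post_init__(self):
        if self.n_min > self.n_maj:
            raise ValidationError("n_min: must be <= n_maj")
        if self.n_min < 0 or self.n_maj < 1:
            raise ValidationError("n_min/n_maj: invalid counts")
        if not 0.0 < self.target_balance_ratio <= 1.0:
            raise ValidationError("target_balance_ratio: must lie in (0, 1]")

    @property
    def table_ir(self) -> float:
        """Majority/minority ratio (dataset-overview convention)."""
        if self.n_min == 0:
            raise ValidationError("n_min: must be > 0 for an imbalance ratio")
        return self.n_maj / self.n_min


def n_synthetic_for_ratio(n_min: int, n_maj: int, r: float) -> int:
    """Synthetic minority rows needed to reach balance ratio ``r``:
    ``max(0, ceil(r * n_maj) - n_min)``."""
    IRSpec(n_min=n_min, n_maj=n_maj, target_balance_ratio=r)  # validates
    return max(0, math.ceil(r * n_maj) - n_min)


def smote_sample(X_min: np.ndarray, n_syn: int, k: int = 5,
                 seed: int | None = 0) -> np.ndarray:
    """``n_syn`` synthetic rows by nearest-neighbour interpolation.

    Rows are z-scored internally for the neighbour search; the emitted rows
    are on the original scale.  Deterministic given ``seed``.
    """
    X_min = np.asarray(X_min, dtype=float)
    if len(X_min) < 2:
        raise ValidationError("X_min: SMOTE needs at least 2 minority rows")
    if k < 1:
        raise ValidationError("k: must be >= 1")
    if n_syn == 0:
        return np.empty((0, X_min.shape[1]))
    rng = np.random.default_rng(seed)

    mu = X_min.mean(axis=0)
    sd = X_min.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X_min - mu) / sd
    k_eff = min(k, len(X_min) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Z)
    neighbours = nn.kneighbors(Z, return_distance=False)[:, 1:]  # drop self

    base = rng.integers(0, len(X_min), size=n_syn)
    pick = rng.integers(0, k_eff, size=n_syn)
    u = rng.uniform(0.0, 1.0, size=n_syn)
    x = X_min[base]
    x_nn = X_min[neighbours[base, pick]]
    return x + u[:, None] * (x_nn - x)


# ---------------------------------------------------------------------------
# Mode-specific normalization
# ---------------------------------------------------------------------------

@dataclass
class ModeNormalizedColumn:
    """Reversible mode-specific encoding of one numeric column.

    ``onehot[i]`` marks the mode assigned to value i; ``scalar[i]`` is the
    within-mode standardized value (x - mean_k) / (4 * std_k), the
    conditional-GAN convention that keeps most scalars in [-1, 1].
    """

    onehot: np.ndarray        # (n, m) one-hot mode assignment
    scalar: np.ndarray        # (n,) within-mode normalized values
    means: np.ndarray         # (m,) mode means
    stds: np.ndarray          # (m,) mode standard deviations
    weights: np.ndarray       # (m,) mixture weights (renormalized)

    @property
    def n_modes(self) -> int:
        return len(self.means)


def mode_specific_normalize(column, max_modes: int = 10,
                            weight_threshold: float = 0.005,
                            seed: int = 0) -> ModeNormalizedColumn:
    """Encode a numeric column as (mode one-hot, within-mode scalar).

    Steps: (i) fit a variational Gaussian mixture to estimate the number of
    modes; (ii) compute each value's responsibility under every retained mode;
    (iii) assign each value the highest-responsibility mode and standardize it
    within that mode.  Components with weight below ``weight_threshold`` are
    pruned.  A constant column yields a single mode with all scalars 0.
    """
    x = np.asarray(column, dtype=float).ravel()
    if len(x) < 10:
        raise ValidationError("column: mode-specific normalization needs >= 10 values")
    if not np.isfinite(x).all():
        raise ValidationError("column: values must be finite")

    if np.ptp(x) < 1e-12:  # degenerate constant column
        n = len(x)
        return ModeNormalizedColumn(
            onehot=np.ones((n, 1)),
            scalar=np.zeros(n),
            means=np.array([x[0]]),
            stds=np.array([1.0]),
            weights=np.array([1.0]),
        )

    gmm = BayesianGaussianMixture(
        n_components=max_modes,
        weight_concentration_prior=1e-3,
        max_iter=500,
        random_state=seed,
    )
    gmm.fit(x[:, None])
    keep = gmm.weights_ > weight_threshold
    means = gmm.means_.ravel()[keep]
    stds = np.sqrt(gmm.covariances_.ravel()[keep])
    weights = gmm.weights_[keep]
    weights = weights / weights.sum()

    # responsibilities under retained modes only
    from scipy.stats import norm

    dens = weights[None, :] * norm.pdf(x[:, None], loc=means[None, :],
                                       scale=stds[None, :])
    mode = np.argmax(dens, axis=1)
    onehot = np.zeros((len(x), len(means)))
    onehot[np.arange(len(x)), mode] = 1.0
    scalar = (x - means[mode]) / (4.0 * stds[mode])
    return ModeNormalizedColumn(onehot=onehot, scalar=scalar, means=means,
                                stds=stds, weights=weights)


def mode_specific_inverse(encoded: ModeNormalizedColumn) -> np.ndarray:
    """Reconstruct the column: x = scalar * 4 * std_k + mean_k."""
    mode = np.argmax(encoded.onehot, axis=1)
    return encoded.scalar * 4.0 * encoded.stds[mode] + encoded.means[mode]


# ---------------------------------------------------------------------------
# Oversampler adapters and the ratio-targeted entry point
# ---------------------------------------------------------------------------

def _sdv_sample(table: FeatureTable, n_syn: int, method: str, seed: int,
                epochs: int, fit_minority_only: bool) -> np.ndarray:
    """CTGAN/TVAE synthetic minority rows via the ``sdv`` library."""
    try:
        from sdv.metadata import SingleTableMetadata
        from sdv.single_table import CTGANSynthesizer, TVAESynthesizer
    except ImportError as exc:
        raise CapabilityError(
            f"{method}: the 'sdv' library is not installed; "
            "use method='smote' or install sdv"
        ) from exc

    minority = table.minority_label
    df = table.features.copy()
    df["label"] = table.labels.values
    if fit_minority_only:
        df = df[df["label"] == minority]
    metadata = SingleTableMetadata()
    metadata.detect_from_dataframe(df)
    cls = CTGANSynthesizer if method == "ctgan" else TVAESynthesizer
    synth = cls(metadata, epochs=epochs)
    synth.fit(df)
    out = []
    while sum(len(o) for o in out) < n_syn:
        batch = synth.sample(num_rows=max(n_syn, 64))
        batch = batch[batch["label"] == minority] if not fit_minority_only else batch
        out.append(batch)
    rows = pd.concat(out).head(n_syn)
    return rows[table.feature_names].to_numpy(dtype=float)


def augment_to_ratio(table: FeatureTable, method: str = "smote", r: float = 1.0,
                     seed: int = 0, k: int = 5, epochs: int = 300,
                     fit_minority_only: bool = False) -> FeatureTable:
    """Append synthetic minority rows until the balance ratio reaches ``r``.

    Real rows are never modified or deleted; synthetic rows carry the minority
    label and ``source="synthetic"``.  The achieved ratio is within 1/n_maj of
    the target by construction of :func:`n_synthetic_for_ratio`.
    """
    if method not in OVERSAMPLERS:
        raise ValidationError(f"method: unknown oversampler {method!r}")
    n_maj, n_min = table.class_counts()
    if n_min == 0:
        raise ValidationError("label: both classes must be present")
    minority = table.minority_label
    n_syn = n_synthetic_for_ratio(n_min, n_maj, r)
    if n_syn == 0:
        return table

    if method == "smote":
        X_min = table.features[table.labels == minority].to_numpy(dtype=float)
        synthetic = smote_sample(X_min, n_syn, k=k, seed=seed)
    else:
        synthetic = _sdv_sample(table, n_syn, method, seed, epochs, fit_minority_only)

    syn_df = pd.DataFrame(synthetic, columns=table.feature_names)
    combined = pd.concat([table.features.reset_index(drop=True), syn_df],
                         ignore_index=True)
    labels = np.concatenate([table.labels.to_numpy(),
                             np.full(n_syn, minority, dtype=int)])
    source = list(table.source) + [SOURCE_SYNTHETIC] * n_syn
    ids = list(table.sample_ids) + [f"syn_{method}_{i:05d}" for i in range(n_syn)]
    return FeatureTable(combined, labels, source, sample_ids=ids)
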