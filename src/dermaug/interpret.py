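"""Interpretability: bootstrap-CI class-difference tests, exact Shapley values,
and library-backed SHAP/UMAP adapters.

The bootstrap test asks, per feature, whether its mean (or proportion, for
binary features) differs between melanoma and not-melanoma rows: resample each
class with replacement M times (within class, preserving class sizes), form
the differences Delta^(i) = mu_melanoma^(i) - mu_not^(i), and take the
percentile (alpha/2, 1 - alpha/2) interval.  The difference is significant
exactly when 0 lies outside the interval; a positive point difference marks a
melanoma-associated feature.

The exact Shapley oracle enumerates all 2^D feature subsets with the
combinatorial weights |S|! (D - |S| - 1)! / D!, evaluating the model with
out-of-coalition features replaced by background means.  It is the ground
truth the library SHAP adapter is compared against, and satisfies the
efficiency identity sum_i phi_i = f(x) - f(baseline) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np

from .datatypes import FeatureTable
from .errors import CapabilityError, ValidationError


@dataclass(frozen=True)
class BootstrapTestConfig:
    """Resampling test parameters: M resamples, significance level alpha,
    statistic ('mean' for numeric, 'proportion' for binary features)."""

    M: int = 1000
    alpha: float = 0.05
    statistic: str = "mean"
    seed: int = 0

    def __post_init__(self):
        if self.M < 100:
            raise ValidationError("M: must be >= 100")
        if not 0.0 < self.alpha < 0.5:
            raise ValidationError("alpha: must lie in (0, 0.5)")
        if self.statistic not in ("mean", "proportion"):
            raise ValidationError("statistic: must be 'mean' or 'proportion'")


@dataclass
class BootstrapTestResult:
    """Point difference, percentile CI and the significance flag."""

    feature: str
    delta: float                 # mu_melanoma - mu_not_melanoma
    ci: tuple[float, float]
    significant: bool
    alpha: float

    def __post_init__(self):
        low, high = self.ci
        if low > high:
            raise ValidationError("ci: lower bound exceeds upper bound")
        # the flag is a pure function of the CI endpoints
        assert self.significant == (not (low <= 0.0 <= high))


def bootstrap_diff_test(X, y, feature: str | int = 0,
                        config: BootstrapTestConfig | None = None
                        ) -> BootstrapTestResult:
    """Bootstrap percentile-CI test of the between-class difference of one
    feature's mean/proportion; melanoma is label 1."""
    config = config or BootstrapTestConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        values = X
        name = str(feature)
    else:
        col = feature if isinstance(feature, int) else int(feature)
        values = X[:, col]
        name = str(feature)
    y = np.asarray(y)
    mel = values[y == 1]
    not_mel = values[y == 0]
    if len(mel) == 0 or len(not_mel) == 0:
        raise ValidationError("y: both classes must be non-empty")
    if config.statistic == "proportion":
        uniq = set(np.unique(values))
        if not uniq <= {0.0, 1.0}:
            raise ValidationError("statistic: 'proportion' requires a binary feature")

    rng = np.random.default_rng(config.seed)
    idx_m = rng.integers(0, len(mel), size=(config.M, len(mel)))
    idx_n = rng.integers(0, len(not_mel), size=(config.M, len(not_mel)))
    deltas = mel[idx_m].mean(axis=1) - not_mel[idx_n].mean(axis=1)
    low, high = np.percentile(deltas,
                              [100 * config.alpha / 2, 100 * (1 - config.alpha / 2)])
    significant = not (low <= 0.0 <= high)
    return BootstrapTestResult(
        feature=name,
        delta=float(mel.mean() - not_mel.mean()),
        ci=(float(low), float(high)),
        significant=significant,
        alpha=config.alpha,
    )


def run_all_feature_tests(table: FeatureTable,
                          config: BootstrapTestConfig | None = None,
                          bonferroni: bool = False) -> list[BootstrapTestResult]:
    """One bootstrap test per feature; positive delta = melanoma-associated.

    No multiple-testing correction by default; ``bonferroni=True`` divides
    alpha by the number of features.
    """
    config = config or BootstrapTestConfig()
    D = len(table.feature_names)
    alpha = config.alpha / D if bonferroni else config.alpha
    X = table.features.to_numpy(dtype=float)
    y = table.labels.to_numpy()
    seeds = np.random.SeedSequence(config.seed).spawn(D)
    results = []
    for j, name in enumerate(table.feature_names):
        cfg = BootstrapTestConfig(M=config.M, alpha=alpha,
                                  statistic=config.statistic,
                                  seed=int(seeds[j].generate_state(1)[0] % (2**31)))
        res = bootstrap_diff_test(X[:, j], y, feature=name, config=cfg)
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------

@dataclass
class ShapleyAttribution:
    """Per-feature attributions phi_i for one instance, plus the value
    function's endpoints (baseline and full predictions)."""

    phi: np.ndarray
    f_full: float
    f_baseline: float

    @property
    def efficiency_gap(self) -> float:
        return float(abs(self.phi.sum() - (self.f_full - self.f_baseline)))


def exact_shapley(predict_fn, instance, background, max_features: int = 15
                  ) -> ShapleyAttribution:
    """Exact Shapley attribution by full subset enumeration (D <= 15).

    ``predict_fn`` maps an (n, D) array to n scalar predictions.  The value of
    a coalition S is the prediction with out-of-S features replaced by the
    background means.  For larger D use a library adapter.
    """
    x = np.asarray(instance, dtype=float).ravel()
    bg = np.asarray(background, dtype=float)
    bg = np.atleast_2d(bg)
    if bg.shape[0] < 1:
        raise ValidationError("background: must be non-empty")
    D = len(x)
    if D > max_features:
        raise CapabilityError(
            f"exact_shapley enumerates 2^D subsets; D={D} > {max_features} -- "
            "use the library adapter")
    baseline = bg.mean(axis=0)

    # evaluate f on every coalition once
    masks = []
    for size in range(D + 1):
        masks.extend(combinations(range(D), size))
    rows = np.tile(baseline, (len(masks), 1))
    for r, members in enumerate(masks):
        rows[r, list(members)] = x[list(members)]
    values = np.asarray(predict_fn(rows), dtype=float).ravel()
    f_of = {frozenset(m): values[r] for r, m in enumerate(masks)}

    phi = np.zeros(D)
    fact = [factorial(s) for s in range(D + 1)]
    for i in range(D):
        others = [j for j in range(D) if j != i]
        for size in range(D):
            weight = fact[size] * fact[D - size - 1] / fact[D]
            for S in combinations(others, size):
                fs = frozenset(S)
                phi[i] += weight * (f_of[fs | {i}] - f_of[fs])
    return ShapleyAttribution(phi=phi, f_full=float(f_of[frozenset(range(D))]),
                              f_baseline=float(f_of[frozenset()]))


def shap_summary_adapter(model, X, feature_names=None):
    """Feature ranking from the SHAP library (KernelExplainer), when installed.

    Raises :class:`CapabilityError` when the ``shap`` package is unavailable;
    the rest of the pipeline is unaffected.
    """
    try:
        import shap
    except ImportError as exc:
        raise CapabilityError(
            "shap_summary_adapter: the 'shap' library is not installed; "
            "use exact_shapley for small feature counts"
        ) from exc
    X = np.asarray(X, dtype=float)
    predict = model.predict_proba if hasattr(model, "predict_proba") else model.predict
    explainer = shap.KernelExplainer(predict, X)
    shap_values = np.abs(np.asarray(explainer.shap_values(X))).mean(axis=0)
    if shap_values.ndim > 1:
        shap_values = shap_values[..., -1]
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    order = np.argsort(-shap_values)
    return [(names[i], float(shap_values[i])) for i in order]


def umap_projection_adapter(X, labels=None, source=None, seed: int = 0) -> dict:
    """2-D UMAP coordinates with real/synthetic/class tags for plotting.

    Points are tagged ``not-melanoma real`` / ``melanoma real`` /
    ``melanoma synthetic`` (and ``not-melanoma synthetic`` should it occur).
    Raises :class:`CapabilityError` if umap-learn is unavailable.
    """
    try:
        import umap
    except ImportError as exc:
        raise CapabilityError(
            "umap_projection_adapter: the 'umap-learn' library is not installed"
        ) from exc
    X = np.asarray(X, dtype=float)
    reducer = umap.UMAP(n_components=2, random_state=seed)
    coords = reducer.fit_transform(X)
    tags = []
    n = len(X)
    labels = np.zeros(n, int) if labels is None else np.asarray(labels)
    source = np.array(["real"] * n) if source is None else np.asarray(source)
    for lab, src in zip(labels, source):
        cls = "melanoma" if lab == 1 else "not-melanoma"
        tags.append(f"{cls} {src}")
    return {"coordinates": np.asarray(coords, dtype=float), "tags": tags}
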