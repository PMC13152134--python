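"""HSV color-statistic audit: counterfactual classification from color alone.

A classifier that separates normal from abnormal images using nothing but
six whole-image color statistics — hue mean/std, saturation mean/std, value
mean/std — cannot be reading pathology; it is reading acquisition
conditions (lighting, camera settings). This module extracts those
statistics, fits unpenalised logistic regressions on the raw features (no
selection, no standardization), and reports odds ratios with Wald
confidence intervals plus AUCs with DeLong intervals on internal and
external evaluation sets.

Conventions: hue in degrees [0, 360) with achromatic pixels assigned hue 0;
saturation and value on the 8-bit [0, 255] scale; population (not sample)
standard deviations over pixels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .data_model import ImageRecord, Manifest, as_raster, load_image
from .roc import RocResult, UndefinedAucError, delong_ci

__all__ = [
    "HsvFeatureVector",
    "LogisticModel",
    "OddsRatioRow",
    "SeparationWarning",
    "CollinearityError",
    "rgb_to_hsv_channels",
    "hsv_to_rgb_channels",
    "hsv_stats",
    "extract_features",
    "fit_logistic",
    "odds_ratios",
    "color_audit",
    "ColorAuditResult",
    "HSV6_FEATURES",
    "FEATURE_SETS",
]

HSV6_FEATURES = (
    "hue_mean",
    "hue_std",
    "sat_mean",
    "sat_std",
    "val_mean",
    "val_std",
)
FEATURE_SETS = {"hsv6": HSV6_FEATURES, "sat_std_only": ("sat_std",)}


class SeparationWarning(UserWarning):
    """The logistic likelihood has no finite maximum (separated classes)."""


class CollinearityError(ValueError):
    """The design matrix is rank-deficient."""


@dataclass(frozen=True)
class HsvFeatureVector:
    hue_mean: float
    hue_std: float
    sat_mean: float
    sat_std: float
    val_mean: float
    val_std: float

    def as_array(self, feature_set: str = "hsv6") -> np.ndarray:
        names = FEATURE_SETS[feature_set]
        return np.array([getattr(self, n) for n in names], dtype=float)


def rgb_to_hsv_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hexcone RGB -> (hue degrees, saturation 0-255, value 0-255) as floats."""
    rgb = np.asarray(image, dtype=float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    delta = mx - mn
    v = mx
    s = np.where(mx > 0, delta / np.where(mx > 0, mx, 1.0) * 255.0, 0.0)
    h = np.zeros_like(mx)
    chrom = delta > 0
    safe = np.where(chrom, delta, 1.0)
    is_r = chrom & (mx == r)
    is_g = chrom & (mx == g) & ~is_r
    is_b = chrom & ~is_r & ~is_g
    h = np.where(is_r, 60.0 * (((g - b) / safe) % 6.0), h)
    h = np.where(is_g, 60.0 * ((b - r) / safe + 2.0), h)
    h = np.where(is_b, 60.0 * ((r - g) / safe + 4.0), h)
    return h % 360.0, s, v


def hsv_to_rgb_channels(
    h: np.ndarray, s: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Inverse hexcone transform; inputs as from :func:`rgb_to_hsv_channels`.

    Returns a float RGB array on the 0-255 scale (not rounded).
    """
    hh = (np.asarray(h, dtype=float) % 360.0) / 60.0
    ss = np.clip(np.asarray(s, dtype=float), 0.0, 255.0) / 255.0
    vv = np.asarray(v, dtype=float)
    i = np.floor(hh).astype(int) % 6
    f = hh - np.floor(hh)
    p = vv * (1.0 - ss)
    q = vv * (1.0 - ss * f)
    t = vv * (1.0 - ss * (1.0 - f))
    r = np.choose(i, [vv, q, p, p, t, vv])
    g = np.choose(i, [t, vv, vv, q, p, p])
    b = np.choose(i, [p, p, t, vv, vv, q])
    return np.stack([r, g, b], axis=-1)


def hsv_stats(
    image: np.ndarray, pixel_mask: np.ndarray | None = None
) -> HsvFeatureVector:
    """Whole-image (or masked) HSV means and population standard deviations."""
    img = as_raster(image)
    h, s, v = rgb_to_hsv_channels(img)
    if pixel_mask is not None:
        pixel_mask = np.asarray(pixel_mask, dtype=bool)
        if pixel_mask.shape != img.shape[:2]:
            raise ValueError(
                f"pixel_mask shape {pixel_mask.shape} does not match "
                f"image shape {img.shape[:2]}"
            )
        if not pixel_mask.any():
            raise ValueError("pixel_mask selects no pixels")
        h, s, v = h[pixel_mask], s[pixel_mask], v[pixel_mask]
    return HsvFeatureVector(
        hue_mean=float(h.mean()),
        hue_std=float(h.std()),
        sat_mean=float(s.mean()),
        sat_std=float(s.std()),
        val_mean=float(v.mean()),
        val_std=float(v.std()),
    )


def field_of_view_mask(image: np.ndarray, value_threshold: float = 10.0) -> np.ndarray:
    """Optional pixel mask excluding near-black border pixels (V <= threshold)."""
    _, _, v = rgb_to_hsv_channels(as_raster(image))
    return v > value_threshold


@dataclass
class LogisticModel:
    """Unpenalised binary logistic regression fitted by IRLS.

    ``covariance`` is the inverse observed Fisher information over
    ``(intercept, *coefficients)``; ``loglik_trace`` records the
    log-likelihood after each Newton step (non-decreasing by construction).
    """

    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    covariance: np.ndarray
    converged: bool
    n_iterations: int
    loglik_trace: tuple[float, ...] = field(default_factory=tuple)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(X))


@dataclass(frozen=True)
class OddsRatioRow:
    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _name_collinear(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, sv, vt = np.linalg.svd(X, full_matrices=False)
    null = np.abs(vt[-1])
    return [n for n, w in zip(names, null[1:]) if w > 1e-8]  # skip intercept


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticModel:
    """Maximum-likelihood logistic fit on raw (unstandardized) features.

    Newton/IRLS with step-halving so the log-likelihood never decreases;
    convergence when the max absolute coefficient change drops below ``tol``.
    Complete separation (divergence / non-convergence) yields a model flagged
    ``converged=False`` with a :class:`SeparationWarning`; a rank-deficient
    design raises :class:`CollinearityError` naming candidate features.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    n, p = X.shape
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(p))
    feature_names = tuple(feature_names)
    if len(feature_names) != p:
        raise ValueError("feature_names length does not match feature count")
    if n < p + 1:
        raise ValueError(f"need at least p+1={p + 1} samples, got {n}")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both classes must be present")
    Xd = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xd) < p + 1:
        bad = _name_collinear(Xd, feature_names)
        raise CollinearityError(
            "design matrix is rank-deficient; collinear feature candidates: "
            + (", ".join(bad) if bad else "(intercept-confounded)")
        )
    beta = np.zeros(p + 1)
    ll = _loglik(Xd @ beta, y)
    trace = [ll]
    converged = False
    n_iter = 0
    hess = None
    for n_iter in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = Xd.T @ (y - mu)
        hess = (Xd * w[:, None]).T @ Xd
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break  # weights collapsed: separation
        step = 1.0
        new_ll = _loglik(Xd @ (beta + step * delta), y)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            halvings += 1
            new_ll = _loglik(Xd @ (beta + step * delta), y)
        beta = beta + step * delta
        trace.append(new_ll)
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            ll = new_ll
            break
        ll = new_ll
    if converged:
        mu = expit(Xd @ beta)
        # Fitted probabilities indistinguishable from the labels mean the
        # optimum is at infinity and the "converged" step was vacuous.
        if np.max(np.abs(y - mu)) < 1e-8:
            converged = False
    if not converged:
        warnings.warn(
            "logistic fit did not converge: classes appear perfectly separable",
            SeparationWarning,
            stacklevel=2,
        )
    mu = expit(Xd @ beta)
    w = mu * (1.0 - mu)
    hess = (Xd * w[:, None]).T @ Xd
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    return LogisticModel(
        feature_names=feature_names,
        coefficients=beta[1:].copy(),
        intercept=float(beta[0]),
        covariance=cov,
        converged=converged,
        n_iterations=n_iter,
        loglik_trace=tuple(trace),
    )


def odds_ratios(model: LogisticModel, level: float = 0.95) -> list[OddsRatioRow]:
    """Per-feature odds ratio exp(beta) with Wald CI and two-sided Wald p."""
    if not model.converged:
        raise ValueError(
            "odds ratios are unavailable for a non-converged model: the "
            "likelihood has no finite maximum, so Wald intervals are meaningless"
        )
    z = norm.ppf(0.5 + level / 2)
    rows = []
    for i, name in enumerate(model.feature_names):
        beta = float(model.coefficients[i])
        se = float(np.sqrt(max(0.0, model.covariance[i + 1, i + 1])))
        wald_z = beta / se if se > 0 else np.inf * np.sign(beta) if beta else 0.0
        p = float(2 * norm.sf(abs(wald_z))) if np.isfinite(wald_z) else 0.0
        rows.append(
            OddsRatioRow(
                feature=name,
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - z * se)),
                ci_high=float(np.exp(beta + z * se)),
                p_value=p,
            )
        )
    return rows


ImageProvider = Callable[[ImageRecord], np.ndarray]


def _default_provider(record: ImageRecord) -> np.ndarray:
    return load_image(record.path)


def extract_features(
    records: Sequence[ImageRecord],
    feature_set: str = "hsv6",
    image_provider: ImageProvider | None = None,
) -> np.ndarray:
    """HSV feature matrix (n_records x n_features) for a feature set."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature_set {feature_set!r}")
    provider = image_provider or _default_provider
    return np.array(
        [hsv_stats(provider(r)).as_array(feature_set) for r in records], dtype=float
    )


@dataclass
class ColorAuditResult:
    feature_set: str
    model: LogisticModel
    odds_ratio_rows: list[OddsRatioRow]
    auc_rows: list[dict]

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(self.auc_rows)


def color_audit(
    train: Manifest,
    eval_sets: Sequence[Manifest] = (),
    feature_set: str = "hsv6",
    image_provider: ImageProvider | None = None,
    level: float = 0.95,
) -> ColorAuditResult:
    """Fit a color-feature logistic model on the train split and score
    the internal validation split plus each external manifest.

    External manifests are scored in full and are never seen during fitting.
    Evaluation sets with a single class yield a row with an ``error`` note
    instead of an AUC.
    """
    train_records = train.subset("train")
    if not train_records:
        raise ValueError("train manifest has no records with split='train'")
    names = FEATURE_SETS[feature_set]
    X = extract_features(train_records, feature_set, image_provider)
    y = np.array([r.label for r in train_records])
    model = fit_logistic(X, y, feature_names=names)
    or_rows = odds_ratios(model, level) if model.converged else []

    evals: list[tuple[str, Sequence[ImageRecord]]] = []
    internal = train.subset("internal_val")
    if internal:
        evals.append(("internal_val", internal))
    for i, m in enumerate(eval_sets):
        evals.append((m.dataset_id or f"external_{i}", m.records))

    auc_rows = []
    for name, records in evals:
        Xe = extract_features(records, feature_set, image_provider)
        ye = np.array([r.label for r in records])
        row: dict = {"eval_set": name, "n": len(records)}
        try:
            res: RocResult = delong_ci(model.linear_predictor(Xe), ye, level)
        except UndefinedAucError as exc:
            row["error"] = str(exc)
        else:
            row.update(
                auc=res.auc,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                n_pos=res.n_pos,
                n_neg=res.n_neg,
            )
        auc_rows.append(row)
    return ColorAuditResult(
        feature_set=feature_set,
        model=model,
        odds_ratio_rows=or_rows,
        auc_rows=auc_rows,
    )
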