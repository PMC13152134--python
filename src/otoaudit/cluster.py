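"""Near-duplicate and stylistic-bias detection from image embeddings.

Images are embedded as unit vectors, pairwise cosine distances are
thresholded, and connected components of the resulting graph
(single-linkage) become near-duplicate sets (tight threshold ``alpha``) or
style clusters (looser ``alpha_style``). Single-linkage is the one linkage
for which a larger threshold always coarsens the grouping, which the
property tests exploit.

The default embedder is deterministic and training-free: per-channel
32-bin intensity histograms concatenated with a 16x16 bilinear-downsampled
luminance grid, L2-normalised. A trainable embedder can be plugged in via
the factory argument of :func:`crossfold_embeddings`, which then averages
embeddings from k stratified-fold models.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import fisher_exact
from sklearn.model_selection import StratifiedKFold

from .data_model import ImageRecord, Manifest, as_raster, load_image
from .roc import RocResult, UndefinedAucError, delong_ci, delong_test_unpaired

__all__ = [
    "EmbeddingMatrix",
    "DuplicateSetCollection",
    "RedundancyReport",
    "StyleCluster",
    "embed_default",
    "crossfold_embeddings",
    "group_by_threshold",
    "redundancy_report",
    "leakage_auc_compare",
    "style_report",
]


def _bilinear_resize(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear downsampling by sampling target pixel centres."""
    H, W = arr.shape
    h, w = shape
    ys = (np.arange(h) + 0.5) * H / h - 0.5
    xs = (np.arange(w) + 0.5) * W / w - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, H - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, W - 1)
    y1 = np.clip(y0 + 1, 0, H - 1)
    x1 = np.clip(x0 + 1, 0, W - 1)
    fy = np.clip(ys - y0, 0.0, 1.0)[:, None]
    fx = np.clip(xs - x0, 0.0, 1.0)[None, :]
    top = arr[np.ix_(y0, x0)] * (1 - fx) + arr[np.ix_(y0, x1)] * fx
    bot = arr[np.ix_(y1, x0)] * (1 - fx) + arr[np.ix_(y1, x1)] * fx
    return top * (1 - fy) + bot * fy


def embed_default(image: np.ndarray) -> np.ndarray:
    """Deterministic 352-dim embedding: color histograms + luminance grid."""
    img = as_raster(image)
    hists = [
        np.bincount((img[..., c] >> 3).ravel(), minlength=32).astype(float)
        for c in range(3)
    ]
    npix = img.shape[0] * img.shape[1]
    hist = np.concatenate(hists) / npix
    lum = (
        0.299 * img[..., 0].astype(float)
        + 0.587 * img[..., 1].astype(float)
        + 0.114 * img[..., 2].astype(float)
    )
    grid = _bilinear_resize(lum, (16, 16)).ravel() / 255.0
    vec = np.concatenate([hist, grid])
    return vec / np.linalg.norm(vec)


@dataclass(frozen=True)
class EmbeddingMatrix:
    ids: tuple[str, ...]
    vectors: np.ndarray  # (n, d), unit rows

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(self.ids):
            raise ValueError("vectors must be (n_ids, d)")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("embedding rows must be unit-norm")


ImageProvider = Callable[[ImageRecord], np.ndarray]
# factory(train_images, train_labels, seed) -> callable(image) -> vector
EmbedderFactory = Callable[[list, np.ndarray, int], Callable[[np.ndarray], np.ndarray]]


def crossfold_embeddings(
    manifest: Manifest,
    image_provider: ImageProvider | None = None,
    embedder_factory: EmbedderFactory | None = None,
    k: int = 5,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Average embeddings over k stratified-fold embedders and re-normalise.

    For each of ``k`` stratified folds an embedder is built from the other
    ``k-1`` folds (when the factory trains one) and applied to *all* images;
    the k vectors per image are averaged and re-normalised. With no factory
    the default training-free embedder is used in a single pass, which
    equals the averaged result by fold-invariance.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    provider = image_provider or (lambda r: load_image(r.path))
    ids = tuple(r.image_id for r in manifest.records)
    images = [provider(r) for r in manifest.records]
    if embedder_factory is None:
        vectors = np.stack([embed_default(im) for im in images])
        return EmbeddingMatrix(ids=ids, vectors=vectors)
    labels = manifest.labels
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    total = None
    for fold_i, (train_idx, _) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        try:
            embed = embedder_factory(
                [images[i] for i in train_idx], labels[train_idx], seed + fold_i
            )
            fold_vecs = np.stack([np.asarray(embed(im), dtype=float) for im in images])
        except Exception as exc:
            raise RuntimeError(f"embedder failed on fold {fold_i}: {exc}") from exc
        total = fold_vecs if total is None else total + fold_vecs
    mean = total / k
    mean /= np.linalg.norm(mean, axis=1, keepdims=True)
    return EmbeddingMatrix(ids=ids, vectors=mean)


@dataclass(frozen=True)
class DuplicateSetCollection:
    """Disjoint groups (size >= 2) of images within cosine distance alpha."""

    sets: tuple[tuple[str, ...], ...]
    alpha: float

    def membership(self) -> dict[str, int]:
        return {iid: k for k, s in enumerate(self.sets) for iid in s}


def group_by_threshold(
    embeddings: EmbeddingMatrix, alpha: float
) -> DuplicateSetCollection:
    """Single-linkage grouping: connected components of the cosine-distance
    graph with an edge wherever distance <= alpha; components of size >= 2.

    All pairs are computed exactly (no approximate index); the result is
    independent of input row order.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    vecs = embeddings.vectors
    n = len(embeddings.ids)
    dist = 1.0 - vecs @ vecs.T
    adj = dist <= alpha
    np.fill_diagonal(adj, False)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[str]] = {}
    for iid, c in zip(embeddings.ids, comp):
        groups.setdefault(int(c), []).append(iid)
    sets = sorted(
        (tuple(sorted(g)) for g in groups.values() if len(g) >= 2),
        key=lambda s: s[0],
    )
    return DuplicateSetCollection(sets=tuple(sets), alpha=float(alpha))


@dataclass(frozen=True)
class RedundancyReport:
    """Summary of near-duplicate structure and train/test leakage exposure."""

    set_count: int
    avg_size: float
    max_size: int
    redundant_count: int  # sum over sets of (size - 1)
    test_set_size: int
    test_with_dup_count: int
    test_with_dup_abnormal_ratio: float
    test_without_dup_count: int
    test_without_dup_abnormal_ratio: float
    test_with_dup_ids: tuple[str, ...] = ()


def redundancy_report(
    sets: DuplicateSetCollection, manifest: Manifest
) -> RedundancyReport:
    """Count duplicate sets and how many internal-validation images share a
    set with at least one training image (the leakage-exposed subset)."""
    sizes = [len(s) for s in sets.sets]
    split_of = {r.image_id: r.split for r in manifest.records}
    label_of = {r.image_id: r.label for r in manifest.records}
    test_ids = [r.image_id for r in manifest.records if r.split == "internal_val"]
    with_dup = []
    for s in sets.sets:
        if any(split_of.get(i) == "train" for i in s):
            with_dup.extend(i for i in s if split_of.get(i) == "internal_val")
    with_set = sorted(set(with_dup))
    without = [i for i in test_ids if i not in set(with_set)]

    def _abn_ratio(ids: Sequence[str]) -> float:
        return float(np.mean([label_of[i] for i in ids])) if ids else 0.0

    return RedundancyReport(
        set_count=len(sizes),
        avg_size=float(np.mean(sizes)) if sizes else 0.0,
        max_size=max(sizes) if sizes else 0,
        redundant_count=int(sum(s - 1 for s in sizes)),
        test_set_size=len(test_ids),
        test_with_dup_count=len(with_set),
        test_with_dup_abnormal_ratio=_abn_ratio(with_set),
        test_without_dup_count=len(without),
        test_without_dup_abnormal_ratio=_abn_ratio(without),
        test_with_dup_ids=tuple(with_set),
    )


def leakage_auc_compare(
    scores: np.ndarray,
    labels: np.ndarray,
    with_dup_mask: np.ndarray,
    level: float = 0.95,
) -> dict:
    """DeLong CIs for the leakage-exposed vs clean test subsets and a
    one-sided unpaired DeLong p for AUC(with duplicates) > AUC(without)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    mask = np.asarray(with_dup_mask, dtype=bool)
    out: dict = {
        "n_with": int(mask.sum()),
        "n_without": int((~mask).sum()),
    }
    results: dict[str, RocResult | None] = {}
    for key, sel in (("with", mask), ("without", ~mask)):
        try:
            res = delong_ci(scores[sel], labels[sel], level)
        except (UndefinedAucError, ValueError) as exc:
            out[f"auc_{key}"] = None
            out[f"auc_{key}_error"] = str(exc)
            results[key] = None
        else:
            out[f"auc_{key}"] = res.auc
            out[f"ci_{key}"] = (res.ci_low, res.ci_high)
            results[key] = res
    if results["with"] is not None and results["without"] is not None:
        out["p_value"] = delong_test_unpaired(
            results["with"], results["without"], alternative="greater"
        )
    else:
        out["p_value"] = None
    return out


@dataclass(frozen=True)
class StyleCluster:
    image_ids: tuple[str, ...]
    size: int
    n_abnormal: int
    purity: float  # majority-class fraction
    fisher_p: float  # label-cluster association (two-sided Fisher exact)
    flagged: bool


def style_report(
    embeddings: EmbeddingMatrix,
    manifest: Manifest,
    alpha_style: float,
    min_size: int = 20,
    purity_threshold: float = 0.9,
) -> list[StyleCluster]:
    """Cluster at the looser style threshold and flag label-pure clusters.

    Clusters of at least ``min_size`` images are reported with their label
    composition; purity >= ``purity_threshold`` flags a candidate stylistic
    bias. The Fisher exact test contrasts abnormal counts inside vs outside
    each cluster.
    """
    if alpha_style <= 0:
        raise ValueError("alpha_style must be > 0")
    vecs = embeddings.vectors
    dist = 1.0 - vecs @ vecs.T
    adj = dist <= alpha_style
    np.fill_diagonal(adj, False)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    label_of = {r.image_id: r.label for r in manifest.records}
    n_abn_total = sum(label_of[i] for i in embeddings.ids)
    n_total = len(embeddings.ids)
    groups: dict[int, list[str]] = {}
    for iid, c in zip(embeddings.ids, comp):
        groups.setdefault(int(c), []).append(iid)
    clusters = []
    for members in groups.values():
        if len(members) < min_size:
            continue
        size = len(members)
        n_abn = sum(label_of[i] for i in members)
        purity = max(n_abn, size - n_abn) / size
        table = [
            [n_abn, size - n_abn],
            [n_abn_total - n_abn, (n_total - size) - (n_abn_total - n_abn)],
        ]
        _, p = fisher_exact(table, alternative="two-sided")
        clusters.append(
            StyleCluster(
                image_ids=tuple(sorted(members)),
                size=size,
                n_abnormal=int(n_abn),
                purity=float(purity),
                fisher_p=float(p),
                flagged=purity >= purity_threshold,
            )
        )
    clusters.sort(key=lambda c: (-c.size, c.image_ids))
    return clusters
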