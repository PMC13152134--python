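"""Synthetic otoscope-like images with planted, ground-truthed biases.

The generator emulates the geometry of an otoscopic photograph — a dark
corner border, a bright circular field of view, a textured ear-canal
annulus, and an interior "membrane" disk — and lets each known failure
mode of real datasets be planted independently and recorded as ground
truth:

* a *clinical signal*: a reddish blob strictly inside the central membrane
  region, so a sufficiently large central occlusion provably removes it;
* *saturation-variability bias*: the within-image spread of the saturation
  channel is scaled up on abnormal images, imitating class-correlated
  acquisition settings;
* *framing styles* I (full-field) and II (zoomed, off-centre) that can be
  linked to the class label;
* *near-duplicate sets* with controllable jitter, optionally leaked across
  the train / validation split.

One master seed feeds named substreams (style, render, signal,
duplication, split) so toggling one bias never perturbs the others.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .data_model import (
    ImageRecord,
    Manifest,
    as_raster,
    save_image,
    stratified_split,
    write_manifest,
)
from .color import hsv_to_rgb_channels, rgb_to_hsv_channels

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "STYLE_PARAMS",
    "render_base_image",
    "inject_clinical_signal",
    "inject_saturation_bias",
    "make_duplicates",
    "generate_images",
    "generate_dataset",
]

# Framing styles: fraction of min(H, W) used as field-of-view radius and
# fractional centre offset. Style I frames the whole field; Style II is a
# zoomed partial view, off-centre.
STYLE_PARAMS = {
    "I": {"radius_frac": 0.48, "offset_frac": (0.0, 0.0)},
    "II": {"radius_frac": 0.34, "offset_frac": (0.06, 0.10)},
}
MEMBRANE_FRAC = 0.55  # membrane disk radius as a fraction of the FOV radius

_STREAMS = ("style", "render", "signal", "dup", "split")


def _stream_rng(seed: int, name: str) -> np.random.Generator:
    idx = _STREAMS.index(name)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic site.

    ``saturation_bias`` multiplies the within-image saturation spread of
    abnormal images by ``(1 + saturation_bias)``; ``style_bias_prob`` is the
    probability that an image's framing style is dictated by its class;
    ``duplicate_jitter`` is both the maximum pixel translation and the
    additive noise std (8-bit units) applied to near-duplicate copies.
    """

    n_per_class: int = 200
    image_size: tuple[int, int] = (64, 64)
    clinical_contrast: float = 80.0
    saturation_bias: float = 0.0
    style_bias_prob: float = 0.0
    duplicate_fraction: float = 0.0
    duplicate_jitter: float = 0.0
    leak_across_split: bool = False
    val_fraction: float = 0.2
    seed: int = 0
    dataset_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0 <= self.clinical_contrast <= 255:
            raise ValueError("clinical_contrast must be in [0, 255]")
        for name in ("style_bias_prob", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.duplicate_jitter < 0 or self.saturation_bias < 0:
            raise ValueError("duplicate_jitter and saturation_bias must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What was actually planted, keyed by image_id."""

    true_duplicate_sets: tuple[tuple[str, ...], ...]
    per_image_style: dict[str, str]
    bias_params: SyntheticConfig
    clinical_signal_present: dict[str, bool]


def render_base_image(
    rng: np.random.Generator, style: str, size: tuple[int, int] = (64, 64)
) -> np.ndarray:
    """Render one artifact-free otoscope-like frame.

    Deterministic given the generator state: a dark warm-toned corner
    border, a bright circular field of view whose radius/centre depend on
    the style, a streaked canal annulus, and a pinkish membrane disk, all
    with per-image color jitter drawn from ``rng``.
    """
    H, W = size
    if H < 32 or W < 32:
        raise ValueError("image size must be at least 32x32")
    params = STYLE_PARAMS[style]
    m = min(H, W)
    # Per-image framing jitter within a style: hand-held otoscopes never
    # frame two shots identically, and downstream duplicate detection
    # depends on distinct images being geometrically distinguishable.
    R = params["radius_frac"] * m * rng.uniform(0.95, 1.05)
    cy = (H - 1) / 2.0 + (params["offset_frac"][0] + rng.uniform(-0.03, 0.03)) * H
    cx = (W - 1) / 2.0 + (params["offset_frac"][1] + rng.uniform(-0.03, 0.03)) * W
    yy, xx = np.mgrid[0:H, 0:W]
    rho = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)

    # Border: dim, strongly saturated orange-brown texture (all channels < 20).
    border_v = rng.uniform(9.0, 13.0)
    v = np.clip(border_v + rng.normal(0.0, 3.0, (H, W)), 2.0, 19.0)
    sat_tex = np.clip(rng.uniform(0.35, 0.95, (H, W)), 0.0, 1.0)
    border = np.stack([v, v * (1.0 - 0.55 * sat_tex), v * (1.0 - sat_tex)], axis=-1)

    # Canal annulus: orange-tan with radial streaks.
    canal_base = np.array(
        [rng.uniform(150, 185), rng.uniform(95, 125), rng.uniform(55, 80)]
    )
    theta = np.arctan2(yy - cy, xx - cx)
    streaks = 14.0 * np.sin(theta * rng.integers(4, 8) + rng.uniform(0, 2 * np.pi))
    canal_tex = streaks + rng.normal(0.0, 8.0, (H, W))
    canal = canal_base + canal_tex[..., None] * np.array([1.0, 0.8, 0.6])

    # Membrane disk: pinkish-gray with fine speckle and a gentle highlight.
    mem_base = np.array(
        [rng.uniform(148, 172), rng.uniform(112, 138), rng.uniform(98, 124)]
    )
    hy, hx = cy + rng.uniform(-0.08, 0.08) * m, cx + rng.uniform(-0.08, 0.08) * m
    highlight = 22.0 * np.exp(-(((yy - hy) ** 2 + (xx - hx) ** 2) / (0.1 * m**2)))
    mem_tex = rng.normal(0.0, 6.0, (H, W)) + highlight
    membrane = mem_base + mem_tex[..., None] * np.array([1.0, 0.9, 0.85])

    img = border
    img = np.where((rho <= R)[..., None], canal, img)
    img = np.where((rho <= MEMBRANE_FRAC * R)[..., None], membrane, img)
    img = np.clip(img, 0, 255)

    # Benign acquisition variability: every image gets its own saturation
    # spread (lognormal factor), so planted spread *biases* shift a class
    # distribution rather than creating an unrealistic clean separation.
    factor = float(np.exp(rng.normal(0.0, 0.35)))
    img = _scale_saturation_spread(img, factor)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def inject_clinical_signal(
    image: np.ndarray, rng: np.random.Generator, contrast: float
) -> np.ndarray:
    """Add an inflamed-looking blob wholly inside the central membrane region.

    G and B are reduced by ``contrast`` (clipped at 0) inside a small disk
    near the image centre, reddening it. The blob (centre offset <= 0.08 and
    radius <= 0.06 of min(H, W)) lies entirely inside the central ellipse of
    extent 0.5, so any occlusion of extent >= 0.5 removes it completely.
    ``contrast=0`` is the identity.
    """
    img = as_raster(image)
    if not 0 <= contrast <= 255:
        raise ValueError("contrast must be in [0, 255]")
    if contrast == 0:
        return img.copy()
    H, W = img.shape[:2]
    m = min(H, W)
    by = (H - 1) / 2.0 + rng.uniform(-0.08, 0.08) * m
    bx = (W - 1) / 2.0 + rng.uniform(-0.08, 0.08) * m
    r = rng.uniform(0.04, 0.06) * m
    yy, xx = np.mgrid[0:H, 0:W]
    blob = (yy - by) ** 2 + (xx - bx) ** 2 <= r**2
    out = img.astype(np.int16)
    for ch in (1, 2):
        out[..., ch] = np.where(blob, out[..., ch] - int(round(contrast)), out[..., ch])
    return np.clip(out, 0, 255).astype(np.uint8)


def _scale_saturation_spread(rgb: np.ndarray, factor: float) -> np.ndarray:
    """Multiply the deviation of each pixel's saturation from the image mean
    saturation by ``factor`` (float in, float out, 0-255 scale)."""
    h, s, v = rgb_to_hsv_channels(rgb)
    s_mean = s.mean()
    s_new = np.clip(s_mean + factor * (s - s_mean), 0.0, 255.0)
    return hsv_to_rgb_channels(h, s_new, v)


def inject_saturation_bias(image: np.ndarray, bias_scale: float) -> np.ndarray:
    """Scale the within-image saturation spread by ``(1 + bias_scale)``.

    Saturation deviations from the image's own mean saturation are
    amplified (clipped to the valid range) and the image converted back to
    RGB. The mean is untouched: the planted artifact is saturation
    *variability*, not a mean shift. ``bias_scale=0`` is the identity up to
    round-trip rounding (at most one intensity level per pixel).
    """
    img = as_raster(image)
    if bias_scale < 0:
        raise ValueError("bias_scale must be >= 0")
    rgb = _scale_saturation_spread(img, 1.0 + bias_scale)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def _shift_edge(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    if dy == 0 and dx == 0:
        return img.copy()
    H, W = img.shape[:2]
    p = max(abs(dy), abs(dx))
    padded = np.pad(img, ((p, p), (p, p), (0, 0)), mode="edge")
    return padded[p - dy : p - dy + H, p - dx : p - dx + W]


_OPPOSITE_SPLIT = {"train": "internal_val", "internal_val": "train"}


def make_duplicates(
    images: list[np.ndarray],
    manifest: Manifest,
    fraction: float,
    jitter: float,
    leak_across_split: bool,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], Manifest, tuple[tuple[str, ...], ...]]:
    """Append 1-3 near-duplicate copies for a fraction of source images.

    Each copy is the source translated by at most ``jitter`` pixels (edge
    replicated) with additive Gaussian noise of std ``jitter``, registered
    under the source's label. With ``leak_across_split`` the first copy of
    each source lands in the opposite split. ``jitter=0`` produces
    bit-identical copies. Returns the extended image list, the extended
    manifest, and the ground-truth sets (source + its copies).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    n = len(manifest)
    n_src = int(np.floor(fraction * n + 0.5))
    if n_src == 0:
        return list(images), manifest, ()
    src_idx = np.sort(rng.choice(n, size=n_src, replace=False))
    out_images = list(images)
    new_records: list[ImageRecord] = []
    sets = []
    max_shift = int(np.floor(jitter))
    for si in src_idx:
        rec = manifest.records[si]
        n_copies = int(rng.integers(1, 4))
        member_ids = [rec.image_id]
        for k in range(1, n_copies + 1):
            img = images[si]
            if jitter > 0:
                dy, dx = rng.integers(-max_shift, max_shift + 1, size=2)
                img = _shift_edge(img, int(dy), int(dx))
                noisy = img.astype(float) + rng.normal(0.0, jitter, img.shape)
                img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
            else:
                img = img.copy()
            split = rec.split
            if leak_across_split and k == 1 and split in _OPPOSITE_SPLIT:
                split = _OPPOSITE_SPLIT[split]
            dup_id = f"{rec.image_id}_d{k}"
            new_records.append(
                replace(rec, image_id=dup_id, path=f"{dup_id}.png", split=split)
            )
            out_images.append(img)
            member_ids.append(dup_id)
        sets.append(tuple(sorted(member_ids)))
    merged = Manifest(
        records=manifest.records + tuple(new_records), dataset_id=manifest.dataset_id
    )
    return out_images, merged, tuple(sets)


def generate_images(
    config: SyntheticConfig,
) -> tuple[Manifest, GroundTruth, list[np.ndarray]]:
    """Generate the dataset in memory; images align with manifest records."""
    n = config.n_per_class
    labels = [0] * n + [1] * n
    ids = [f"{config.dataset_id}_n{i:04d}" for i in range(n)] + [
        f"{config.dataset_id}_a{i:04d}" for i in range(n)
    ]

    style_rng = _stream_rng(config.seed, "style")
    styles = []
    for lab in labels:
        if style_rng.random() < config.style_bias_prob:
            styles.append("I" if lab == 0 else "II")
        else:
            styles.append(str(style_rng.choice(["I", "II"])))

    render_children = np.random.SeedSequence(
        config.seed, spawn_key=(_STREAMS.index("render"),)
    ).spawn(2 * n)
    signal_children = np.random.SeedSequence(
        config.seed, spawn_key=(_STREAMS.index("signal"),)
    ).spawn(2 * n)

    images = []
    for i, (lab, style) in enumerate(zip(labels, styles)):
        img = render_base_image(
            np.random.default_rng(render_children[i]), style, config.image_size
        )
        if lab == 1:
            img = inject_clinical_signal(
                img,
                np.random.default_rng(signal_children[i]),
                config.clinical_contrast,
            )
            if config.saturation_bias > 0:
                img = inject_saturation_bias(img, config.saturation_bias)
        images.append(img)

    records = tuple(
        ImageRecord(
            image_id=iid,
            path=f"{iid}.png",
            label=lab,
            split="unassigned",
            dataset_id=config.dataset_id,
        )
        for iid, lab in zip(ids, labels)
    )
    manifest = Manifest(records=records, dataset_id=config.dataset_id)
    manifest = stratified_split(manifest, config.val_fraction, seed=config.seed)

    images, manifest, dup_sets = make_duplicates(
        images,
        manifest,
        config.duplicate_fraction,
        config.duplicate_jitter,
        config.leak_across_split,
        _stream_rng(config.seed, "dup"),
    )

    style_of = dict(zip(ids, styles))
    signal_of = {iid: (lab == 1 and config.clinical_contrast > 0)
                 for iid, lab in zip(ids, labels)}
    for r in manifest.records:
        if r.image_id not in style_of:  # a duplicate: inherit from its source
            src = r.image_id.rsplit("_d", 1)[0]
            style_of[r.image_id] = style_of[src]
            signal_of[r.image_id] = signal_of[src]
    truth = GroundTruth(
        true_duplicate_sets=dup_sets,
        per_image_style=style_of,
        bias_params=config,
        clinical_signal_present=signal_of,
    )
    return manifest, truth, images


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Manifest, GroundTruth]:
    """Generate and write PNGs, ``manifest.csv`` and ``ground_truth.json``.

    Fully deterministic given ``config.seed``: re-running with the same
    config produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, truth, images = generate_images(config)
    records = []
    for rec, img in zip(manifest.records, images):
        path = out_dir / f"{rec.image_id}.png"
        save_image(img, path)
        records.append(replace(rec, path=str(path)))
    manifest = Manifest(records=tuple(records), dataset_id=manifest.dataset_id)
    write_manifest(manifest, out_dir / "manifest.csv")
    payload = {
        "duplicate_sets": [list(s) for s in truth.true_duplicate_sets],
        "styles": truth.per_image_style,
        "clinical_signal_present": truth.clinical_signal_present,
        "config": asdict(config),
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return manifest, truth
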