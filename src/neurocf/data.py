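"""Activation-map data model, I/O, preprocessing and a synthetic generator.

An activation map is a 2D grid of nonnegative intensities in [0, 1] on a
fixed brain mask (pixels outside the mask are exactly zero), with one task
label per map.  The synthetic generator emulates multi-subject task-contrast
maps: all classes share a smooth background pattern, each class adds a few
localized activation blobs at class-specific locations, and each subject's
map carries amplitude jitter, blob-position jitter and pixel noise, all
scaled by a single noise level so the noise-free limit is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "ActivationMap",
    "LabeledDataset",
    "SynthConfig",
    "default_mask",
    "generate_synthetic_dataset",
    "downsample",
    "minmax_normalize",
    "save_dataset",
    "load_dataset",
    "export_png",
    "stratified_split",
]


@dataclass
class ActivationMap:
    """One masked 2D activation image with an optional class label."""

    values: np.ndarray
    mask: np.ndarray
    label: Optional[int] = None
    id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if np.any(self.values[~self.mask] != 0):
            raise ValueError("out-of-mask pixels must be exactly zero")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, id: Optional[str] = None) -> "ActivationMap":
        return ActivationMap(values, self.mask, label=self.label,
                             id=self.id if id is None else id)


class LabeledDataset:
    """An ordered collection of activation maps sharing one mask."""

    def __init__(self, maps: Sequence[ActivationMap], class_names: Sequence[str]):
        self.maps = list(maps)
        self.class_names = list(class_names)
        k = len(self.class_names)
        if self.maps:
            shape = self.maps[0].shape
            mask = self.maps[0].mask
            for m in self.maps:
                if m.shape != shape:
                    raise ValueError("all maps must share one shape")
                if not np.array_equal(m.mask, mask):
                    raise ValueError("all maps must share one mask")
                if m.label is not None and not (0 <= m.label < k):
                    raise ValueError(f"label {m.label} outside 0..{k - 1}")
            self.mask = mask
        else:
            self.mask = None

    def __len__(self) -> int:
        return len(self.maps)

    def __getitem__(self, i: int) -> ActivationMap:
        return self.maps[i]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def values_array(self) -> np.ndarray:
        return np.stack([m.values for m in self.maps]) if self.maps else np.empty((0, 0, 0))

    def labels_array(self) -> np.ndarray:
        return np.array(
            [-1 if m.label is None else m.label for m in self.maps], dtype=np.int64
        )

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.maps[i] for i in indices], self.class_names)

    def class_mean(self, label: int) -> np.ndarray:
        vals = [m.values for m in self.maps if m.label == label]
        if not vals:
            raise ValueError(f"no maps with label {label}")
        return np.mean(vals, axis=0)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic multi-class activation dataset.

    ``noise_sd`` is the pixel-noise standard deviation and also scales the
    per-subject amplitude jitter (``amplitude_jitter_scale * noise_sd``,
    multiplicative) and blob-position jitter
    (``center_jitter_scale * noise_sd`` pixels), so ``noise_sd = 0`` yields
    identical maps within a class.
    """

    H: int = 32
    W: int = 64
    K: int = 7
    n_per_class: int = 40
    background_amplitude: float = 0.35
    class_amplitude: float = 0.5
    noise_sd: float = 0.18
    blob_width: float = 3.0
    blobs_per_class: int = 3
    amplitude_jitter_scale: float = 2.5
    center_jitter_scale: float = 12.0
    seed: int = 0
    class_names: Optional[list[str]] = None

    def __post_init__(self):
        if min(self.H, self.W, self.K, 1 if self.n_per_class == 0 else self.n_per_class) < 1:
            raise ValueError("H, W, K must be positive and n_per_class nonnegative")
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be nonnegative")
        if min(self.background_amplitude, self.class_amplitude, self.noise_sd) < 0:
            raise ValueError("amplitudes and noise_sd must be nonnegative")

    def resolved_class_names(self) -> list[str]:
        if self.class_names is not None:
            if len(self.class_names) != self.K:
                raise ValueError("class_names length must equal K")
            return list(self.class_names)
        return [f"task{k}" for k in range(self.K)]


def default_mask(H: int, W: int) -> np.ndarray:
    """Two side-by-side elliptical 'sheets' emulating flattened hemispheres,
    separated by a gap at the vertical midline."""
    r, c = np.mgrid[0:H, 0:W]
    semi_h = H / 2 - 0.5
    semi_w = max(1.0, W / 4 - 1.5)
    left = (((r - (H - 1) / 2) / semi_h) ** 2
            + ((c - (W - 1) / 4) / semi_w) ** 2) <= 1.0
    right = (((r - (H - 1) / 2) / semi_h) ** 2
             + ((c - 3 * (W - 1) / 4) / semi_w) ** 2) <= 1.0
    return left | right


def _gaussian_bump(H: int, W: int, center, sigma: float) -> np.ndarray:
    r, c = np.mgrid[0:H, 0:W]
    return np.exp(-(((r - center[0]) ** 2 + (c - center[1]) ** 2) / (2.0 * sigma**2)))


def _place_blob_centers(cfg: SynthConfig, mask: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Class-specific blob centers, pairwise separated across all classes."""
    inside = np.argwhere(mask).astype(float)
    n_needed = cfg.K * cfg.blobs_per_class
    min_sep = 2.5 * cfg.blob_width
    # greedy pick over a shuffled candidate list; relax separation if the
    # packing jams (centers stay distinct, so class means stay distinct)
    while min_sep >= 1.0:
        order = rng.permutation(len(inside))
        centers: list[np.ndarray] = []
        for i in order:
            cand = inside[i]
            if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
                centers.append(cand)
                if len(centers) == n_needed:
                    return np.array(centers).reshape(cfg.K, cfg.blobs_per_class, 2)
        min_sep *= 0.85
    raise ValueError(
        "could not place disjoint blob centers; mask too small or "
        "blob_width too large"
    )


def generate_synthetic_dataset(cfg: SynthConfig,
                               mask: Optional[np.ndarray] = None) -> LabeledDataset:
    """Generate ``K * n_per_class`` masked maps, reproducible from ``cfg.seed``.

    Every map is min-max normalized within the mask, so stored values span
    [0, 1] exactly (which makes downstream renormalization an identity).
    """
    if mask is None:
        mask = default_mask(cfg.H, cfg.W)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (cfg.H, cfg.W):
        raise ValueError("mask shape must be (H, W)")
    if not mask.any():
        raise ValueError("degenerate mask: no pixels inside the brain")

    rng = np.random.default_rng(cfg.seed)
    class_names = cfg.resolved_class_names()

    # shared smooth background (fixed across classes and subjects)
    inside = np.argwhere(mask)
    background = np.zeros((cfg.H, cfg.W))
    for _ in range(3):
        c = inside[rng.integers(len(inside))].astype(float)
        background += _gaussian_bump(cfg.H, cfg.W, c, sigma=max(cfg.H, cfg.W) / 4.0)
    if background.max() > 0:
        background *= cfg.background_amplitude / background.max()

    centers = _place_blob_centers(cfg, mask, rng)

    amp_sd = cfg.amplitude_jitter_scale * cfg.noise_sd
    jit_sd = cfg.center_jitter_scale * cfg.noise_sd

    maps: list[ActivationMap] = []
    for k in range(cfg.K):
        for s in range(cfg.n_per_class):
            img = background.copy()
            amp = cfg.class_amplitude * max(0.2, 1.0 + amp_sd * rng.standard_normal())
            for b in range(cfg.blobs_per_class):
                center = centers[k, b] + jit_sd * rng.standard_normal(2)
                img += amp * _gaussian_bump(cfg.H, cfg.W, center, cfg.blob_width)
            if cfg.noise_sd > 0:
                img += cfg.noise_sd * rng.standard_normal((cfg.H, cfg.W))
            img = np.clip(img, 0.0, 1.0)
            inner = img[mask]
            lo, hi = inner.min(), inner.max()
            if hi > lo:
                img = (img - lo) / (hi - lo)
            img[~mask] = 0.0
            img = np.clip(img, 0.0, 1.0)
            maps.append(ActivationMap(img, mask, label=k, id=f"c{k}s{s}"))
    return LabeledDataset(maps, class_names)


def downsample(amap: ActivationMap, target_h: int, target_w: int) -> ActivationMap:
    """Area-weighted downsampling; mask downsampled by area majority vote."""
    H, W = amap.shape
    if target_h < 1 or target_w < 1:
        raise ValueError("target dims must be positive")
    if target_h > H or target_w > W:
        raise ValueError("target dims must not exceed source dims")
    wr = _overlap_weights(H, target_h)
    wc = _overlap_weights(W, target_w)
    values = wr @ amap.values @ wc.T
    mask_frac = wr @ amap.mask.astype(float) @ wc.T
    mask = mask_frac >= 0.5
    values = np.where(mask, values, 0.0)
    return ActivationMap(values, mask, label=amap.label, id=amap.id)


def _overlap_weights(n_src: int, n_tgt: int) -> np.ndarray:
    """Row-stochastic matrix of interval-overlap areas between grids."""
    w = np.zeros((n_tgt, n_src))
    step = n_src / n_tgt
    for i in range(n_tgt):
        lo, hi = i * step, (i + 1) * step
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_src)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w / step


def minmax_normalize(amap: ActivationMap) -> ActivationMap:
    """Affine rescale over within-mask pixels so min -> 0 and max -> 1."""
    inner = amap.values[amap.mask]
    if inner.size == 0:
        raise ValueError("empty mask")
    lo, hi = inner.min(), inner.max()
    if hi <= lo:
        raise ValueError("degenerate normalization: constant within-mask image")
    values = (amap.values - lo) / (hi - lo)
    values[~amap.mask] = 0.0
    return amap.with_values(values)


def save_dataset(ds: LabeledDataset, path) -> None:
    """Write a dataset to a single-file .npz archive (values, mask, labels, names)."""
    if ds.maps:
        values = ds.values_array()
        mask = ds.mask
    else:
        values = np.empty((0, 0, 0))
        mask = np.empty((0, 0), dtype=bool)
    meta = {"class_names": ds.class_names, "ids": [m.id for m in ds.maps]}
    np.savez(
        path,
        values=values,
        mask=mask,
        labels=ds.labels_array(),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_dataset(path) -> LabeledDataset:
    with np.load(path) as z:
        values, mask, labels = z["values"], z["mask"], z["labels"]
        meta = json.loads(bytes(z["meta"]).decode())
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values/labels length mismatch in archive")
    maps = [
        ActivationMap(values[i], mask,
                      label=None if labels[i] < 0 else int(labels[i]),
                      id=meta["ids"][i])
        for i in range(values.shape[0])
    ]
    return LabeledDataset(maps, meta["class_names"])


def export_png(amap: ActivationMap, path) -> None:
    """8-bit grayscale export; quantization is round(value * 255) on [0, 1]."""
    v = np.clip(amap.values, 0.0, 1.0)
    img = np.rint(v * 255.0).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


def stratified_split(ds: LabeledDataset, val_fraction: float,
                     seed: int) -> tuple[LabeledDataset, LabeledDataset]:
    """Label-stratified train/validation split (validation gets the ceil share)."""
    rng = np.random.default_rng(seed)
    labels = ds.labels_array()
    train_idx, val_idx = [], []
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        rng.shuffle(idx)
        n_val = int(np.ceil(len(idx) * val_fraction))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return ds.subset(sorted(train_idx)), ds.subset(sorted(val_idx))
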