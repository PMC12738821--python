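"""Procedural four-class synthetic leaf-image benchmark.

The generator emulates the phenotypes of a four-class cotton leaf disease
taxonomy on a textured soil background:

* ``brown_spot`` — 2-6 elongated (axis ratio >= 2.5) brown "spindle" lesions
  scattered over the leaf interior;
* ``verticillium_wilt`` — chlorotic (yellowing) discoloration confined to a
  band along the leaf edge;
* ``healthy`` — uniform green lamina, no lesions;
* ``fusarium_wilt`` — wilt discoloration covering >= 60% of the whole leaf.

Every image is drawn from an explicit ``LeafImageSpec`` + seeded generator,
so identical (class, spec, seed) triples are bitwise identical. The module
also provides classical augmentation (rotation / scaling / flipping),
manifest construction with explicit per-class totals, and the stratified
3:1:1 train/val/test split (val = test = floor(total/5) per class, train =
remainder), which reproduces the published split table row for row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

CLASS_NAMES = ("brown_spot", "verticillium_wilt", "healthy", "fusarium_wilt")

__all__ = [
    "CLASS_NAMES",
    "LeafImageSpec",
    "SplitSpec",
    "DatasetManifest",
    "generate_leaf_image",
    "augment_image",
    "build_dataset",
    "split_dataset",
    "load_images",
]


@dataclass(frozen=True)
class LeafImageSpec:
    """Phenotype constants of the generator (RGB in [0, 1])."""

    size: int = 64
    background_rgb: tuple[float, float, float] = (0.42, 0.36, 0.28)
    background_noise: float = 0.045
    leaf_rgb: tuple[float, float, float] = (0.18, 0.52, 0.20)
    leaf_noise: float = 0.025
    # brown spot: elongated necrotic lesions
    spot_rgb: tuple[float, float, float] = (0.42, 0.26, 0.09)
    spot_count: tuple[int, int] = (2, 6)
    spot_length_frac: tuple[float, float] = (0.10, 0.18)
    spot_axis_ratio: tuple[float, float] = (2.5, 4.0)
    # verticillium: chlorosis along the leaf margin
    chlorosis_rgb: tuple[float, float, float] = (0.78, 0.74, 0.18)
    edge_band_frac: float = 0.10
    # fusarium: whole-leaf wilt
    wilt_rgb: tuple[float, float, float] = (0.58, 0.47, 0.12)
    wilt_cover: tuple[float, float] = (0.65, 0.85)


@dataclass(frozen=True)
class SplitSpec:
    """3:1:1 stratified split; val = test = floor(total/5) per class."""

    ratio: tuple[int, int, int] = (3, 1, 1)
    seed: int = 0


def _ellipse_mask(size, cy, cx, a, b, theta):
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _blend(img, mask, rgb, strength):
    target = np.asarray(rgb)
    s = strength if np.ndim(strength) else float(strength)
    w = (mask.astype(float) * s)[..., None]
    img[:] = img * (1.0 - w) + target * w


def generate_leaf_image(
    cls: str, spec: LeafImageSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One labelled leaf image; returns (RGB uint8 array, lesion mask).

    The lesion mask is the ground-truth boolean map of diseased pixels
    (empty for the healthy class).
    """
    if cls not in CLASS_NAMES:
        raise ValueError(f"unknown disease class {cls!r}")
    size = spec.size
    if size < 32:
        raise ValueError("image size must be at least 32")

    img = np.asarray(spec.background_rgb) + rng.normal(
        0.0, spec.background_noise, size=(size, size, 3)
    )

    cy, cx = size / 2 + rng.uniform(-0.04, 0.04, 2) * size
    a = 0.40 * size * (1 + rng.uniform(-0.08, 0.08))
    b = 0.28 * size * (1 + rng.uniform(-0.08, 0.08))
    theta = rng.uniform(0, np.pi)
    leaf = _ellipse_mask(size, cy, cx, a, b, theta)

    lamina = np.asarray(spec.leaf_rgb) + rng.normal(
        0.0, spec.leaf_noise, size=(size, size, 3)
    )
    img[leaf] = lamina[leaf]

    lesions = np.zeros((size, size), dtype=bool)
    interior = ndimage.binary_erosion(leaf, iterations=max(2, size // 20))

    if cls == "brown_spot":
        n = int(rng.integers(spec.spot_count[0], spec.spot_count[1] + 1))
        ys, xs = np.nonzero(interior)
        for _ in range(n):
            j = int(rng.integers(len(ys)))
            length = rng.uniform(*spec.spot_length_frac) * size
            ratio = rng.uniform(*spec.spot_axis_ratio)
            ang = rng.uniform(0, np.pi)
            spot = _ellipse_mask(size, ys[j], xs[j], length, length / ratio, ang)
            lesions |= spot & interior
        _blend(img, lesions, spec.spot_rgb, 0.9)
    elif cls == "verticillium_wilt":
        band_px = max(2, int(round(spec.edge_band_frac * size)))
        core = ndimage.binary_erosion(leaf, iterations=band_px)
        band = leaf & ~core
        strength = np.clip(0.75 + rng.normal(0, 0.08, (size, size)), 0.4, 1.0)
        _blend(img, band, spec.chlorosis_rgb, strength)
        lesions = band
    elif cls == "fusarium_wilt":
        cover = rng.uniform(*spec.wilt_cover)
        noise = ndimage.gaussian_filter(rng.normal(size=(size, size)), size / 16)
        vals = noise[leaf]
        thresh = np.quantile(vals, 1.0 - cover)
        wilt = leaf & (noise >= thresh)
        strength = np.clip(0.85 + rng.normal(0, 0.05, (size, size)), 0.5, 1.0)
        _blend(img, wilt, spec.wilt_rgb, strength)
        lesions = wilt
    # healthy: no lesions by construction

    img = np.clip(img, 0.0, 1.0)
    return (img * 255).round().astype(np.uint8), lesions


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentOp:
    rotate: float = 0.0  # degrees in [0, 360)
    scale: float = 1.0  # in (0, inf); nominal range [0.8, 1.2]
    flip: str | None = None  # None | "horizontal" | "vertical"


def _center_fit(arr: np.ndarray, size: int) -> np.ndarray:
    """Center-crop or zero-pad the spatial axes back to (size, size)."""
    h, w = arr.shape[:2]
    if h > size:
        off = (h - size) // 2
        arr = arr[off : off + size]
    elif h < size:
        pad = size - h
        arr = np.pad(arr, [(pad // 2, pad - pad // 2)] + [(0, 0)] * (arr.ndim - 1))
    if w > size:
        off = (w - size) // 2
        arr = arr[:, off : off + size]
    elif w < size:
        pad = size - w
        arr = np.pad(arr, [(0, 0), (pad // 2, pad - pad // 2)] + [(0, 0)] * (arr.ndim - 2))
    return arr


def augment_image(img: np.ndarray, op: AugmentOp, order: int = 1) -> np.ndarray:
    """Deterministic rotate -> scale -> flip; output keeps the input size.

    Right-angle rotations take an exact (interpolation-free) path so four
    90-degree turns are the identity; use ``order=0`` for label masks.
    """
    if op.scale <= 0:
        raise ValueError("scale must be positive")
    if not 0.0 <= op.rotate < 360.0:
        raise ValueError("rotation must lie in [0, 360) degrees")
    out = np.asarray(img)
    size = out.shape[0]
    if op.rotate:
        if op.rotate % 90 == 0:
            out = np.rot90(out, k=int(op.rotate // 90), axes=(0, 1))
        else:
            out = ndimage.rotate(
                out, op.rotate, axes=(1, 0), reshape=False, order=order, mode="nearest"
            )
    if op.scale != 1.0:
        zoom = [op.scale, op.scale] + [1.0] * (out.ndim - 2)
        out = ndimage.zoom(out, zoom, order=order, mode="nearest")
        out = _center_fit(out, size)
    if op.flip is not None:
        axis = {"horizontal": 1, "vertical": 0}[op.flip]
        out = np.flip(out, axis=axis)
    return np.ascontiguousarray(out)


def random_augment_op(rng: np.random.Generator) -> AugmentOp:
    flip = rng.choice([None, "horizontal", "vertical"])
    return AugmentOp(
        rotate=float(rng.uniform(0, 360)),
        scale=float(rng.uniform(0.8, 1.2)),
        flip=None if flip is None else str(flip),
    )


# ---------------------------------------------------------------------------
# manifests, dataset construction, splitting


@dataclass
class DatasetManifest:
    """(id, path, class, split) records with unique ids."""

    records: pd.DataFrame

    def __post_init__(self):
        required = {"id", "path", "class", "split"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"manifest needs columns {sorted(required)}")
        if self.records["id"].duplicated().any():
            raise ValueError("manifest ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = self.records["class"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CLASS_NAMES}

    def split_counts(self) -> pd.DataFrame:
        return self.records.pivot_table(
            index="class", columns="split", values="id", aggfunc="count", fill_value=0
        )

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(self.records[self.records["split"] == split].reset_index(drop=True))

    def save(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False)
        return cls(df)


def build_dataset(
    class_counts: dict[str, int],
    spec: LeafImageSpec,
    out_dir: str | Path,
    seed: int = 0,
    base_fraction: float = 0.4,
) -> DatasetManifest:
    """Generate exactly the requested number of images per class.

    ``base_fraction`` of each class is drawn fresh from the generator and the
    remainder is produced by classical augmentation of those base images
    (mirroring an original-plus-augmented corpus); the realised proportions
    and seeds are logged in a JSON sidecar next to the manifest.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    log: dict[str, dict] = {}
    for ci, cls in enumerate(CLASS_NAMES):
        count = int(class_counts.get(cls, 0))
        if count <= 0:
            raise ValueError(f"class count for {cls!r} must be positive")
        rng = np.random.default_rng(np.random.SeedSequence((seed, ci)))
        n_base = max(1, int(round(count * base_fraction)))
        n_base = min(n_base, count)
        base_imgs, base_masks = [], []
        for b in range(n_base):
            img, mask = generate_leaf_image(cls, spec, rng)
            base_imgs.append(img)
            base_masks.append(mask)
        for j in range(count):
            if j < n_base:
                img, mask = base_imgs[j], base_masks[j]
                kind = "base"
            else:
                src = int(rng.integers(n_base))
                op = random_augment_op(rng)
                img = augment_image(base_imgs[src], op, order=1)
                mask = augment_image(
                    base_masks[src].astype(np.uint8), op, order=0
                ).astype(bool)
                kind = "augmented"
            img_id = f"{cls}_{j:05d}"
            rel = f"images/{img_id}.png"
            Image.fromarray(img).save(out_dir / rel)
            Image.fromarray(mask.astype(np.uint8) * 255).save(
                out_dir / "masks" / f"{img_id}.png"
            )
            rows.append({"id": img_id, "path": rel, "class": cls, "split": "unassigned", "kind": kind})
        log[cls] = {"total": count, "base": n_base, "augmented": count - n_base}
    manifest = DatasetManifest(pd.DataFrame(rows))
    manifest.save(out_dir / "manifest.csv")
    sidecar = {"seed": seed, "spec": asdict(spec), "classes": log}
    (out_dir / "manifest.json").write_text(json.dumps(sidecar, indent=2))
    return manifest


def split_sizes(total: int) -> tuple[int, int, int]:
    """(train, val, test) under the 3:1:1 rule: val = test = floor(total/5)."""
    val = test = total // 5
    return total - val - test, val, test


def split_dataset(manifest: DatasetManifest, split: SplitSpec | None = None) -> DatasetManifest:
    """Assign per-class stratified train/val/test splits under a seed."""
    split = split or SplitSpec()
    if split.ratio != (3, 1, 1):
        raise ValueError("only the 3:1:1 ratio is supported")
    df = manifest.records.copy()
    if (df["split"] != "unassigned").any():
        raise ValueError("manifest already contains assigned splits")
    rng = np.random.default_rng(split.seed)
    for cls in df["class"].unique():
        idx = df.index[df["class"] == cls].to_numpy()
        perm = rng.permutation(len(idx))
        _, n_val, n_test = split_sizes(len(idx))
        df.loc[idx[perm[:n_val]], "split"] = "val"
        df.loc[idx[perm[n_val : n_val + n_test]], "split"] = "test"
        df.loc[idx[perm[n_val + n_test :]], "split"] = "train"
    return DatasetManifest(df)


def load_images(
    manifest: DatasetManifest, root: str | Path, split: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Load (images in [0,1] float, integer labels) for one split (or all)."""
    root = Path(root)
    df = manifest.records
    if split is not None:
        df = df[df["split"] == split]
    imgs, labels = [], []
    for _, row in df.iterrows():
        arr = np.asarray(Image.open(root / row["path"]), dtype=float) / 255.0
        imgs.append(arr)
        labels.append(CLASS_NAMES.index(row["class"]))
    return np.stack(imgs), np.asarray(labels, dtype=int)
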