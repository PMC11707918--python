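"""Seeded BUSI-like ultrasound phantoms and folder-layout I/O.

The generator emulates the three-class structure of public breast
ultrasound collections (normal / benign / malignant) at desk scale:

* **normal** — speckled textured background, no lesion;
* **benign** — a smooth-boundary hypoechoic ellipse (regular margin);
* **malignant** — a larger, star-perturbed (spiculated) hypoechoic
  lesion with an irregular margin.

Speckle is modeled as clipped multiplicative Gaussian noise
(``pixel *= 1 + sigma * N(0,1)``); a Rayleigh variant is available via
``speckle_model="rayleigh"``.  The phantoms capture only the coarse
statistics that matter for exercising the pipeline — lesion shape
regularity, contrast and multiplicative texture — not acoustic physics.
Images are quantized to 8 bits at generation time so a PNG round trip is
lossless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_NAMES",
    "PhantomSpec",
    "LabeledImageSet",
    "generate_phantoms",
    "write_busi_layout",
    "load_busi_folder",
    "split_train_test",
]

#: class-name -> label id, alphabetical (matches folder loading order)
CLASS_NAMES = ("benign", "malignant", "normal")


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom set.

    ``n_per_class`` is ordered (normal, benign, malignant).
    ``lesion_contrast`` is the fractional intensity drop inside a lesion;
    ``irregularity`` the radial boundary-perturbation amplitude used for
    malignant lesions (benign margins are nearly regular).
    """

    n_per_class: tuple[int, int, int] = (50, 50, 50)
    image_size: int = 64
    speckle_sigma: float = 0.12
    lesion_contrast: float = 0.4
    irregularity: float = 0.35
    speckle_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("counts must be >= 0")
        if sum(self.n_per_class) == 0:
            raise ValueError("at least one image must be requested")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be >= 0")
        if self.speckle_model not in ("gaussian", "rayleigh"):
            raise ValueError("speckle_model must be 'gaussian' or 'rayleigh'")


@dataclass
class LabeledImageSet:
    """Grayscale images in [0,1] with class ids and per-image metadata."""

    images: np.ndarray          # (n, H, W) float32
    labels: np.ndarray          # (n,) int, indices into class_names
    class_names: tuple[str, ...] = CLASS_NAMES
    metadata: list[dict] = field(default_factory=list)
    source_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.images.shape[0]


def _lesion_mask(
    size: int,
    center: tuple[float, float],
    radii: tuple[float, float],
    angle: float,
    irregularity: float,
    lobes: int,
    phase: float,
) -> np.ndarray:
    """Binary mask of an (optionally spiculated) ellipse.

    The boundary radius is modulated as ``1 + irregularity * sin(lobes *
    theta + phase)`` in the lesion's polar frame; irregularity 0 gives
    the exact analytic ellipse.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / radii[0]
    v = (-sa * dx + ca * dy) / radii[1]
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    boundary = 1.0 + irregularity * np.sin(lobes * theta + phase)
    return (rho <= boundary).astype(float)


def generate_phantoms(spec: PhantomSpec) -> LabeledImageSet:
    """Deterministic phantom set for the given spec.

    Classes are statistically separable at the default settings: benign
    and malignant differ in boundary regularity and mean lesion area,
    and both differ from the lesion-free normal class in intensity.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    images, labels, metadata = [], [], []
    n_normal, n_benign, n_malignant = spec.n_per_class
    plan = (
        [("normal", None)] * n_normal
        + [("benign", "regular")] * n_benign
        + [("malignant", "irregular")] * n_malignant
    )
    for class_name, margin in plan:
        base = 0.55 + 0.02 * rng.standard_normal()
        background = base + 0.05 * gaussian_filter(
            rng.standard_normal((s, s)), sigma=s / 10
        )
        img = background
        meta: dict = {"class": class_name, "lesion_area": 0.0}
        if margin is not None:
            center = (
                s / 2 + rng.uniform(-0.05, 0.05) * s,
                s / 2 + rng.uniform(-0.05, 0.05) * s,
            )
            if margin == "regular":
                # benign: smaller, regular margin, milder hypoechogenicity
                radii = (rng.uniform(0.13, 0.18) * s, rng.uniform(0.11, 0.16) * s)
                irregularity = 0.04
                lobes = int(rng.integers(4, 7))
                contrast = 0.7 * spec.lesion_contrast
            else:
                # malignant: larger, spiculated, deeper intensity drop
                radii = (rng.uniform(0.21, 0.28) * s, rng.uniform(0.17, 0.24) * s)
                irregularity = spec.irregularity
                lobes = int(rng.integers(6, 10))
                contrast = spec.lesion_contrast
            angle = rng.uniform(0, np.pi)
            phase = rng.uniform(0, 2 * np.pi)
            mask = _lesion_mask(s, center, radii, angle, irregularity, lobes, phase)
            soft = gaussian_filter(mask, sigma=0.8) if spec.speckle_sigma > 0 else mask
            img = img * (1.0 - contrast * soft)
            meta.update(
                center=center, radii=radii, angle=angle, phase=phase,
                irregularity=irregularity, lobes=lobes,
                lesion_area=float(mask.sum()),
            )
        if spec.speckle_sigma > 0:
            if spec.speckle_model == "gaussian":
                noise = 1.0 + spec.speckle_sigma * rng.standard_normal((s, s))
            else:
                ray = rng.rayleigh(scale=1.0, size=(s, s))
                noise = 1.0 + spec.speckle_sigma * (ray - np.sqrt(np.pi / 2))
            img = img * noise
        img = np.clip(img, 0.0, 1.0)
        img = np.round(img * 255.0) / 255.0  # 8-bit grid: PNG round trip is exact
        images.append(img.astype(np.float32))
        labels.append(CLASS_NAMES.index(class_name))
        metadata.append(meta)
    order = np.argsort(np.array(labels), kind="stable")  # group by class id
    images_arr = np.stack(images)[order]
    labels_arr = np.array(labels)[order]
    metadata = [metadata[i] for i in order]
    source_ids = [f"{CLASS_NAMES[lbl]}_{i:04d}" for i, lbl in enumerate(labels_arr)]
    return LabeledImageSet(images_arr, labels_arr, CLASS_NAMES, metadata, source_ids)


def write_busi_layout(image_set: LabeledImageSet, root: str | Path) -> list[Path]:
    """Write ``root/<class>/<class> (i).png`` plus a manifest CSV.

    Empty classes get no subfolder.  Returns the written image paths.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest_rows = ["path,class,params"]
    counters: dict[str, int] = {}
    metadata = image_set.metadata or [{} for _ in range(len(image_set))]
    for img, lbl, meta in zip(image_set.images, image_set.labels, metadata):
        name = image_set.class_names[lbl]
        counters[name] = counters.get(name, 0) + 1
        cls_dir = root / name
        cls_dir.mkdir(exist_ok=True)
        path = cls_dir / f"{name} ({counters[name]}).png"
        Image.fromarray(np.round(img * 255.0).astype(np.uint8), mode="L").save(path)
        paths.append(path)
        params = json.dumps(meta, default=lambda v: list(v) if isinstance(v, tuple) else v)
        manifest_rows.append(f'"{path}",{name},"{params.replace(chr(34), chr(39))}"')
    (root / "manifest.csv").write_text("\n".join(manifest_rows) + "\n")
    return paths


def load_busi_folder(root: str | Path) -> LabeledImageSet:
    """Load a class-per-subfolder PNG tree.

    Class names map to ids alphabetically; files whose stem ends in
    ``_mask`` (any case, optionally followed by an index) are skipped,
    as are unreadable files (with a logged warning).
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"{root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subfolders under {root}")
    images, labels, source_ids = [], [], []
    class_names = tuple(d.name for d in class_dirs)
    n_skipped = 0
    for lbl, d in enumerate(class_dirs):
        for path in sorted(d.iterdir()):
            if path.suffix.lower() not in (".png", ".jpg", ".jpeg", ".tif", ".tiff"):
                continue
            stem = path.stem.lower()
            if stem.endswith("_mask") or stem.rstrip("0123456789_ ()").endswith("_mask"):
                continue
            try:
                with Image.open(path) as im:
                    arr = np.asarray(im.convert("L"), dtype=np.float32) / 255.0
            except Exception:
                n_skipped += 1
                logger.warning("skipping unreadable image %s", path)
                continue
            images.append(arr)
            labels.append(lbl)
            source_ids.append(str(path))
    if n_skipped:
        logger.warning("skipped %d unreadable files under %s", n_skipped, root)
    if not images:
        raise ValueError(f"no readable images under {root}")
    return LabeledImageSet(
        np.stack(images), np.array(labels), class_names, [], source_ids
    )


def split_train_test(
    image_set: LabeledImageSet, fraction: float, seed: int
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Stratified split; ``fraction`` is the held-out (second) share.

    The two sets are disjoint, their union is the input, and the split
    is reproducible from the seed.  Every class present must have at
    least 2 items.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    labels = image_set.labels
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(f"class {image_set.class_names[c]} has < 2 items")
        rng.shuffle(idx)
        n_test = int(round(fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 1)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))

    def subset(indices: np.ndarray) -> LabeledImageSet:
        return LabeledImageSet(
            image_set.images[indices],
            image_set.labels[indices],
            image_set.class_names,
            [image_set.metadata[i] for i in indices] if image_set.metadata else [],
            [image_set.source_ids[i] for i in indices] if image_set.source_ids else [],
        )

    return subset(train_idx), subset(test_idx)
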