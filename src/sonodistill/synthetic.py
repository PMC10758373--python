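"""Synthetic ultrasound-like datasets and benchmark manifest I/O.

The generator produces labelled grayscale images with the statistical
structure a standard-plane classifier has to cope with: six visually
distinct anatomical templates, a fan-shaped scan mask, multiplicative
Rayleigh speckle, per-image acquisition gain variation, and per-patient
geometric jitter so that images group naturally into patients.  Splits are
always patient-disjoint.

The six class templates echo the plane classes of the public fetal-plane
benchmark: a bright ring with interior structure (brain), an ellipse with
two interior blobs (abdomen), a bright oblique bar (femur), periodic
vertical bands inside an ellipse (thorax), a bright wedge (cervix), and
random clutter (other).  Geometry is deliberately analytic and simple so
that full distillation experiments run in minutes on one CPU; the images
do not model beamforming, attenuation or a realistic point-spread
function.

On-disk layout mirrors the public benchmark: 8-bit grayscale PNGs plus a
delimited manifest with columns ``Image_name``, ``Patient_num``,
``Plane``, ``Train`` (1 = training split, 0 = test).  Both comma- and
semicolon-delimited manifests are accepted (the distributed metadata file
is known to vary in dialect).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from scipy import ndimage

__all__ = [
    "CLASS_NAMES",
    "ImageSample",
    "SyntheticSpec",
    "generate_dataset",
    "read_manifest",
    "write_dataset",
    "load_images",
    "samples_to_arrays",
    "ManifestFormatError",
]

CLASS_NAMES = ("Fetal abdomen", "Fetal brain", "Fetal femur", "Fetal thorax", "Maternal cervix", "Other")

MANIFEST_COLUMNS = ("Image_name", "Patient_num", "Plane", "Train")


class ManifestFormatError(ValueError):
    """Raised when a dataset manifest violates the expected table format."""


@dataclass
class ImageSample:
    """One grayscale image in [0,1] with label, patient id and split flag."""

    pixels: np.ndarray
    label: int
    patient_id: str
    split: str  # "train" | "test"
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.label < 0:
            raise ValueError("label must be a valid class index")
        if self.split not in ("train", "test"):
            raise ValueError("split must be 'train' or 'test'")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; the dataset is a pure function of this spec.

    images_per_class counts train + test together; test_fraction of each
    class's patients (and images) goes to the test side.  speckle_shape is
    the Rayleigh scale before normalisation to unit mean; gain_range
    emulates per-acquisition gain settings; structure_jitter scales the
    per-patient geometric deformation (0 disables it).
    """

    n_classes: int = 6
    images_per_class: int = 150
    image_size: tuple[int, int] = (32, 32)
    patients_per_class: int = 15
    test_fraction: float = 1.0 / 3.0
    speckle_shape: float = 1.0
    speckle_smoothing: float = 0.7
    gain_range: tuple[float, float] = (0.7, 1.3)
    structure_jitter: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.n_classes > len(CLASS_NAMES):
            raise ValueError(f"n_classes must be in [2, {len(CLASS_NAMES)}]")
        if self.images_per_class < 1 or self.patients_per_class < 1:
            raise ValueError("counts must be positive")
        if self.images_per_class < self.patients_per_class:
            raise ValueError("need at least one image per patient")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie strictly in (0, 1)")
        if min(self.image_size) < 8:
            raise ValueError("image size too small to render structures")


def _fan_mask(h: int, w: int) -> np.ndarray:
    """Circular sector opening downward from an apex above the top edge."""
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = -0.15 * h, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    ang = np.arctan2(xx - cx, yy - cy)  # 0 = straight down
    return (r < 1.12 * h) & (np.abs(ang) < np.deg2rad(38.0))


def _gauss_blob(yy, xx, cy, cx, sy, sx):
    return np.exp(-0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))


def _render_template(
    label: int, h: int, w: int, jitter: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Noise-free echogenicity map for one class, geometry shifted by the
    patient's jitter vector (dy, dx, scale, angle)."""
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy, dx, ds, da = jitter
    cy, cx = h / 2.0 + dy * h, w / 2.0 + dx * w
    s = (1.0 + ds) * min(h, w)
    img = np.full((h, w), 0.12)  # tissue background
    if label == 0:  # abdomen: ellipse + two interior blobs
        e = (((yy - cy) / (0.38 * s)) ** 2 + ((xx - cx) / (0.32 * s)) ** 2) < 1.0
        img[e] = 0.35
        img += 0.55 * _gauss_blob(yy, xx, cy - 0.12 * s, cx - 0.10 * s, 0.06 * s, 0.06 * s)
        img += 0.55 * _gauss_blob(yy, xx, cy + 0.10 * s, cx + 0.12 * s, 0.05 * s, 0.05 * s)
    elif label == 1:  # brain: bright skull ring, mid-gray interior
        r = np.hypot((yy - cy) / 1.0, (xx - cx) / 0.85)
        ring = np.abs(r - 0.36 * s) < 0.05 * s
        img[r < 0.36 * s] = 0.30
        img[ring] = 0.85
        img += 0.25 * _gauss_blob(yy, xx, cy, cx, 0.10 * s, 0.04 * s)
    elif label == 2:  # femur: bright oblique bar
        ang = np.deg2rad(30.0 + 10.0 * da)
        u = (xx - cx) * np.cos(ang) + (yy - cy) * np.sin(ang)
        v = -(xx - cx) * np.sin(ang) + (yy - cy) * np.cos(ang)
        bar = (np.abs(u) < 0.38 * s) & (np.abs(v) < 0.045 * s)
        img[bar] = 0.9
    elif label == 3:  # thorax: periodic vertical bands (ribs) in an ellipse
        e = (((yy - cy) / (0.40 * s)) ** 2 + ((xx - cx) / (0.34 * s)) ** 2) < 1.0
        bands = 0.5 + 0.45 * np.sin(2.0 * np.pi * (xx - cx) / (0.22 * s))
        img[e] = (0.25 + 0.5 * bands)[e]
    elif label == 4:  # cervix: bright wedge
        u, v = yy - cy, xx - cx
        wedge = (u > -0.1 * s) & (np.abs(v) < 0.05 * s + 0.45 * (u + 0.1 * s))
        img[wedge & (u < 0.4 * s)] = 0.75
    else:  # other: random clutter
        for _ in range(5):
            bcy, bcx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
            img += rng.uniform(0.2, 0.6) * _gauss_blob(
                yy, xx, bcy, bcx, rng.uniform(0.04, 0.12) * s, rng.uniform(0.04, 0.12) * s
            )
    return np.clip(img, 0.0, 1.2)


def _speckle_field(shape, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative Rayleigh speckle, lightly smoothed to give
    the granular texture characteristic of ultrasound."""
    raw = rng.rayleigh(spec.speckle_shape, size=shape)
    if spec.speckle_smoothing > 0:
        raw = ndimage.gaussian_filter(raw, spec.speckle_smoothing, mode="reflect")
    return raw / raw.mean()


def _split_patients(
    patients: list[str], images_per_class: int, test_fraction: float, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, int]]:
    """Assign patients to splits and distribute the class's images evenly
    over patients within each split."""
    n_test_imgs = int(round(test_fraction * images_per_class))
    n_test_imgs = min(max(n_test_imgs, 1), images_per_class - 1)
    n_test_pat = min(max(int(round(test_fraction * len(patients))), 1), len(patients) - 1)
    order = list(patients)
    rng.shuffle(order)
    split_of = {p: ("test" if i < n_test_pat else "train") for i, p in enumerate(order)}
    counts: dict[str, int] = {}
    for side, n_imgs in (("test", n_test_imgs), ("train", images_per_class - n_test_imgs)):
        side_pats = [p for p in order if split_of[p] == side]
        base, extra = divmod(n_imgs, len(side_pats))
        for i, p in enumerate(side_pats):
            counts[p] = base + (1 if i < extra else 0)
    return split_of, counts


def generate_dataset(spec: SyntheticSpec) -> tuple[list[ImageSample], pd.DataFrame]:
    """Generate samples plus a manifest table; bit-identical per seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    mask = _fan_mask(h, w)
    samples: list[ImageSample] = []
    rows = []
    patient_counter = 0
    for label in range(spec.n_classes):
        patients = [f"P{patient_counter + i:04d}" for i in range(spec.patients_per_class)]
        patient_counter += spec.patients_per_class
        jitters = {
            p: np.array(
                [
                    rng.normal(0, spec.structure_jitter),
                    rng.normal(0, spec.structure_jitter),
                    rng.normal(0, spec.structure_jitter),
                    rng.normal(0, 1.0),
                ]
            )
            for p in patients
        }
        split_of, counts = _split_patients(
            patients, spec.images_per_class, spec.test_fraction, rng
        )
        idx = 0
        for p in patients:
            for _ in range(counts[p]):
                template = _render_template(label, h, w, jitters[p], rng)
                speckle = _speckle_field((h, w), spec, rng)
                gain = rng.uniform(*spec.gain_range)
                img = np.clip(template * speckle * gain, 0.0, 1.0)
                img[~mask] = 0.0
                name = f"class{label}_{p}_{idx:04d}.png"
                samples.append(
                    ImageSample(
                        pixels=img,
                        label=label,
                        patient_id=p,
                        split=split_of[p],
                        name=name,
                    )
                )
                rows.append(
                    {
                        "Image_name": name,
                        "Patient_num": p,
                        "Plane": CLASS_NAMES[label],
                        "Train": 1 if split_of[p] == "train" else 0,
                    }
                )
                idx += 1
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    return samples, manifest


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a benchmark-style manifest table.

    Comma- and semicolon-delimited files with a header row are both
    accepted.  The predefined split is honoured as given.  Raises
    :class:`ManifestFormatError` on missing columns, duplicate filenames
    or unknown plane labels.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ManifestFormatError(f"manifest {path} is missing required column {col!r}")
    if df["Image_name"].duplicated().any():
        dup = df.loc[df["Image_name"].duplicated(), "Image_name"].iloc[0]
        raise ManifestFormatError(f"duplicate image filename in manifest: {dup!r}")
    if df["Plane"].isna().any() or (df["Plane"].astype(str).str.strip() == "").any():
        raise ManifestFormatError("manifest contains empty plane labels")
    unknown = set(df["Plane"].astype(str)) - set(CLASS_NAMES)
    if unknown:
        raise ManifestFormatError(f"unknown plane labels in manifest: {sorted(unknown)}")
    if not set(df["Train"].astype(int)) <= {0, 1}:
        raise ManifestFormatError("Train flag must be 0 or 1")
    df = df.copy()
    df["Train"] = df["Train"].astype(int)
    return df


def write_dataset(samples: list[ImageSample], directory: str | os.PathLike) -> Path:
    """Write PNG images plus a CSV manifest; returns the manifest path.

    Round-trips through :func:`read_manifest`/:func:`load_images`
    losslessly at 8-bit precision.
    """
    directory = Path(directory)
    img_dir = directory / "Images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        name = s.name or f"img_{i:05d}.png"
        arr = np.clip(np.round(s.pixels * 255.0), 0, 255).astype(np.uint8)
        try:
            Image.fromarray(arr, mode="L").save(img_dir / name)
        except OSError as exc:
            raise OSError(f"failed to write image {img_dir / name}: {exc}") from exc
        rows.append(
            {
                "Image_name": name,
                "Patient_num": s.patient_id,
                "Plane": CLASS_NAMES[s.label],
                "Train": 1 if s.split == "train" else 0,
            }
        )
    manifest_path = directory / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest_path, index=False)
    return manifest_path


def load_images(
    manifest: pd.DataFrame, directory: str | os.PathLike, *, image_size: tuple[int, int] | None = None
) -> list[ImageSample]:
    """Materialise a manifest into samples, reading PNGs from
    ``directory/Images``.  Missing files are collected and reported in a
    single error.  ``image_size`` optionally resizes on load (bilinear)."""
    directory = Path(directory)
    img_dir = directory / "Images"
    missing = [n for n in manifest["Image_name"] if not (img_dir / str(n)).exists()]
    if missing:
        shown = ", ".join(map(str, missing[:5]))
        raise FileNotFoundError(
            f"{len(missing)} image file(s) listed in the manifest are missing "
            f"under {img_dir} (first: {shown})"
        )
    label_of = {name: i for i, name in enumerate(CLASS_NAMES)}
    samples = []
    for _, row in manifest.iterrows():
        with Image.open(img_dir / str(row["Image_name"])) as im:
            im = im.convert("L")
            if image_size is not None:
                im = im.resize((image_size[1], image_size[0]), Image.BILINEAR)
            pixels = np.asarray(im, dtype=float) / 255.0
        samples.append(
            ImageSample(
                pixels=pixels,
                label=label_of[str(row["Plane"])],
                patient_id=str(row["Patient_num"]),
                split="train" if int(row["Train"]) == 1 else "test",
                name=str(row["Image_name"]),
            )
        )
    return samples


def samples_to_arrays(samples: list[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack uniform-size samples into (N,1,H,W) images and (N,) labels."""
    if not samples:
        return np.zeros((0, 1, 0, 0)), np.zeros(0, dtype=int)
    x = np.stack([s.pixels for s in samples])[:, None, :, :]
    y = np.array([s.label for s in samples], dtype=int)
    return x, y
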