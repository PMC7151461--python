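"""Synthetic labeled-volume generator.

Produces seeded cohorts of ~1 mm isotropic 3D volumes containing 16
bilateral ellipsoidal structures (8 mirrored pairs), with three classes
whose in-structure intensity statistics differ by configurable effect
sizes: a mean shift, a texture standard deviation, and a Gaussian
smoothing scale that controls texture coarseness.

The texture model is a stationary Gaussian random field: white noise
smoothed with a Gaussian filter of scale ``texture_smoothing`` and then
rescaled to standard deviation ``texture_sd``.  A single smoothing
parameter therefore maps directly onto coarseness-type texture features,
giving the downstream selection and classification stages a planted
signal.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GeometryError
from .volumes import ImageVolume, LabelMap

__all__ = [
    "CLASSES",
    "ClassParams",
    "Ellipsoid",
    "PhantomSpec",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
]

#: Canonical class names, in manifest order.
CLASSES = ("control", "prodromal", "pd")

#: Class counts of the emulated cohort, scaled down from 203/66/637.
DEFAULT_N_PER_CLASS = (20, 7, 64)


@dataclass(frozen=True)
class ClassParams:
    """Per-class intensity/texture effect parameters."""

    roi_mean_shift: float  # added to background_mean inside every structure
    texture_sd: float  # standard deviation of the in-structure texture field
    texture_smoothing: float  # Gaussian smoothing scale (voxels); 0 = white noise

    def __post_init__(self) -> None:
        if self.texture_sd < 0:
            raise ValueError("texture_sd must be >= 0")
        if self.texture_smoothing < 0:
            raise ValueError("texture_smoothing must be >= 0")


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: voxel-space center and semi-axes."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Digitized interior test for an (N, 3) array of voxel indices."""
        c = np.asarray(self.center, dtype=float)
        a = np.asarray(self.semi_axes, dtype=float)
        return np.sum(((coords - c) / a) ** 2, axis=1) <= 1.0


def _default_geometry() -> dict[int, Ellipsoid]:
    """8 mirrored ellipsoid pairs on a 64^3 grid.

    Odd labels sit in the low-x half, even labels are their mirror images
    about the grid midplane; each pair has distinct semi-axes so shape
    features have analytic references.
    """
    lefts = [
        ((12.0, 16.0, 16.0), (2.5, 3.0, 2.0)),
        ((12.0, 16.0, 44.0), (3.0, 2.5, 3.5)),
        ((12.0, 44.0, 16.0), (2.0, 4.0, 3.0)),
        ((12.0, 44.0, 44.0), (3.5, 5.0, 4.0)),
        ((22.0, 16.0, 16.0), (4.0, 5.5, 4.5)),
        ((22.0, 16.0, 44.0), (3.0, 3.5, 2.5)),
        ((22.0, 44.0, 16.0), (2.5, 2.0, 3.0)),
        ((22.0, 44.0, 44.0), (4.0, 6.0, 5.0)),
    ]
    geometry: dict[int, Ellipsoid] = {}
    for pair, (center, axes) in enumerate(lefts, start=1):
        cx, cy, cz = center
        geometry[2 * pair - 1] = Ellipsoid(center, axes)
        geometry[2 * pair] = Ellipsoid((63.0 - cx, cy, cz), axes)
    return geometry


def _default_class_params() -> dict[str, ClassParams]:
    return {
        "control": ClassParams(roi_mean_shift=0.0, texture_sd=5.0, texture_smoothing=0.5),
        "prodromal": ClassParams(roi_mean_shift=12.0, texture_sd=8.0, texture_smoothing=1.2),
        "pd": ClassParams(roi_mean_shift=28.0, texture_sd=12.0, texture_smoothing=2.0),
    }


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one synthetic labeled volume."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    structure_geometry: dict[int, Ellipsoid] = field(default_factory=_default_geometry)
    background_mean: float = 100.0
    background_sd: float = 5.0
    per_class_params: dict[str, ClassParams] = field(default_factory=_default_class_params)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_structures(self) -> int:
        return len(self.structure_geometry)

    def validate(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise GeometryError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        for label, ell in self.structure_geometry.items():
            if min(ell.semi_axes) < 2.0:
                raise GeometryError(f"label {label}: semi-axes must be >= 2 voxels")
            for c, a, n in zip(ell.center, ell.semi_axes, self.grid_shape):
                if c - a < 0 or c + a > n - 1:
                    raise GeometryError(
                        f"label {label} extends outside the {self.grid_shape} grid"
                    )
        missing = set(self.per_class_params) ^ set(CLASSES)
        if missing:
            raise ValueError(f"per_class_params must cover exactly {CLASSES}")
        # disjointness of the digitized interiors
        occupancy = np.zeros(self.grid_shape, dtype=np.int8)
        for label in self.structure_geometry:
            occupancy += self.label_mask(label)
        if occupancy.max() > 1:
            raise GeometryError("structure ellipsoids overlap on the voxel grid")

    def label_mask(self, label: int) -> np.ndarray:
        """Boolean mask of the digitized ellipsoid interior for one label."""
        ell = self.structure_geometry[label]
        mask = np.zeros(self.grid_shape, dtype=bool)
        # evaluate only inside the ellipsoid's bounding box
        lo = [max(0, int(np.floor(c - a))) for c, a in zip(ell.center, ell.semi_axes)]
        hi = [
            min(n - 1, int(np.ceil(c + a)))
            for c, a, n in zip(ell.center, ell.semi_axes, self.grid_shape)
        ]
        box = np.meshgrid(
            *(np.arange(a, b + 1) for a, b in zip(lo, hi)), indexing="ij"
        )
        coords = np.stack([g.ravel() for g in box], axis=1)
        inside = ell.contains(coords)
        mask[tuple(coords[inside].T)] = True
        return mask

    def build_labelmap(self) -> LabelMap:
        cached = getattr(self, "_labelmap_cache", None)
        if cached is None:
            data = np.zeros(self.grid_shape, dtype=np.int16)
            for label in sorted(self.structure_geometry):
                data[self.label_mask(label)] = label
            self._labelmap_cache = data
            cached = data
        return LabelMap(data=cached.copy(), spacing=self.spacing)

    def to_json(self) -> str:
        doc = {
            "grid_shape": list(self.grid_shape),
            "spacing": list(self.spacing),
            "background_mean": self.background_mean,
            "background_sd": self.background_sd,
            "structure_geometry": {
                str(k): {"center": list(e.center), "semi_axes": list(e.semi_axes)}
                for k, e in self.structure_geometry.items()
            },
            "per_class_params": {
                c: {
                    "roi_mean_shift": p.roi_mean_shift,
                    "texture_sd": p.texture_sd,
                    "texture_smoothing": p.texture_smoothing,
                }
                for c, p in self.per_class_params.items()
            },
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        doc = json.loads(text)
        return cls(
            grid_shape=tuple(doc["grid_shape"]),
            spacing=tuple(doc["spacing"]),
            background_mean=doc["background_mean"],
            background_sd=doc["background_sd"],
            structure_geometry={
                int(k): Ellipsoid(tuple(v["center"]), tuple(v["semi_axes"]))
                for k, v in doc["structure_geometry"].items()
            },
            per_class_params={
                c: ClassParams(**p) for c, p in doc["per_class_params"].items()
            },
        )


@dataclass
class CohortSpec:
    """A seeded cohort: class counts plus the shared phantom model."""

    n_per_class: tuple[int, int, int] = DEFAULT_N_PER_CLASS
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        if any(int(n) < 0 for n in self.n_per_class):
            raise ValueError("class counts must be nonnegative")
        if sum(n >= 2 for n in self.n_per_class) < 2:
            raise ValueError("at least 2 classes need n >= 2 for cross-validation")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_class))


def generate_phantom(
    spec: PhantomSpec, class_label: str, seed: int
) -> tuple[ImageVolume, LabelMap]:
    """Generate one labeled volume for the given class, deterministically.

    The volume is Gaussian background noise; inside each labeled structure
    the intensity is ``background_mean + roi_mean_shift`` plus a smoothed,
    sd-rescaled Gaussian texture field shared across the 16 structures.
    """
    if class_label not in spec.per_class_params:
        raise ValueError(f"unknown class {class_label!r}; expected one of {CLASSES}")
    params = spec.per_class_params[class_label]
    rng = np.random.default_rng(seed)

    vol = spec.background_mean + spec.background_sd * rng.standard_normal(spec.grid_shape)

    if params.texture_sd > 0:
        white = rng.standard_normal(spec.grid_shape)
        if params.texture_smoothing > 0:
            texture = gaussian_filter(white, sigma=params.texture_smoothing)
        else:
            texture = white
        sd = texture.std()
        texture = texture * (params.texture_sd / sd) if sd > 0 else texture * 0.0
    else:
        texture = np.zeros(spec.grid_shape)

    labelmap = spec.build_labelmap()
    roi = labelmap.data > 0
    vol[roi] = spec.background_mean + params.roi_mean_shift + texture[roi]

    return ImageVolume(data=vol, spacing=spec.spacing), labelmap


def _scan_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-scan seeds derived from one cohort seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n)]


def generate_cohort(cohort: CohortSpec, outdir: str | Path) -> Path:
    """Write all cohort volumes + label maps as NIfTI and a CSV manifest.

    Returns the manifest path. Manifest columns: scan_id, volume_path,
    labelmap_path, class. Paths are relative to the manifest's directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    seeds = _scan_seeds(cohort.seed, cohort.n_total)
    rows = []
    idx = 0
    for class_label, n in zip(CLASSES, cohort.n_per_class):
        for _ in range(int(n)):
            scan_id = f"scan_{idx:04d}"
            vol, lmap = generate_phantom(cohort.phantom, class_label, seeds[idx])
            vol_path = f"{scan_id}_volume.nii.gz"
            lab_path = f"{scan_id}_labels.nii.gz"
            vol.save(outdir / vol_path)
            lmap.save(outdir / lab_path)
            rows.append(
                {
                    "scan_id": scan_id,
                    "volume_path": vol_path,
                    "labelmap_path": lab_path,
                    "class": class_label,
                }
            )
            idx += 1

    (outdir / "phantom_spec.json").write_text(cohort.phantom.to_json())
    manifest_path = outdir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["scan_id", "volume_path", "labelmap_path", "class"]
        )
        writer.writeheader()
        writer.writerows(rows)
    return manifest_path
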