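"""Synthetic voxel phantoms: QA cylinder and parametric pregnant abdomen.

Coordinate convention (shared package-wide): patient supine, +x patient
left, +y posterior, +z cranial; the grid centre coincides with the scanner
isocenter and gantry angle 0 deg is anterior (-y).

The pregnant-abdomen phantom is deliberately schematic — labelled geometric
primitives, not anatomy.  It encodes the features that drive the dosimetry:
an elliptical water-equivalent torso sized by abdominal circumference, a
carbon-fibre-equivalent couch slab behind the posterior surface, a fetus
whose head sits centrally/inferiorly (in the pelvic cavity) while its
thoraco-abdominal region presses against the anterior wall, and maternal
abdominal organs (liver, kidneys, colon, uterus, bladder).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError, InvalidInputError
from .materials import MATERIAL_IDS

#: density thresholds (g/cm3) for material classification, upper edges
DEFAULT_MATERIAL_THRESHOLDS = (
    (0.05, MATERIAL_IDS["air"]),
    (0.95, MATERIAL_IDS["lung"]),
    (1.10, MATERIAL_IDS["soft_tissue"]),
    (1.25, MATERIAL_IDS["pmma"]),
    (np.inf, MATERIAL_IDS["bone"]),
)


def hu_to_density(hu):
    """Two-point linear CT-number conversion: 0 HU -> 1 g/cm3, -1000 HU -> 0."""
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise InvalidInputError("CT numbers must be finite")
    out = np.clip((hu + 1000.0) / 1000.0, 0.0, None)
    return float(out) if out.ndim == 0 else out


def density_to_hu(density):
    """Inverse of :func:`hu_to_density` on its unclipped branch."""
    d = np.asarray(density, dtype=float)
    out = d * 1000.0 - 1000.0
    return float(out) if out.ndim == 0 else out


@dataclass
class VoxelPhantom:
    """CT-number grid with density, material and organ-label maps."""

    ct_numbers: np.ndarray  # HU, shape (nx, ny, nz)
    voxel_size_mm: float
    organ_labels: np.ndarray | None = None
    organ_names: dict[int, str] = field(default_factory=dict)
    density: np.ndarray = field(default=None)  # type: ignore[assignment]
    material_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = "phantom"

    def __post_init__(self):
        self.ct_numbers = np.asarray(self.ct_numbers, dtype=np.float32)
        if self.ct_numbers.ndim != 3:
            raise InvalidInputError("phantom grid must be 3-D")
        if self.voxel_size_mm <= 0:
            raise InvalidInputError("voxel size must be positive")
        if self.density is None:
            self.density = hu_to_density(self.ct_numbers).astype(np.float32)
        if self.organ_labels is None:
            self.organ_labels = np.zeros(self.ct_numbers.shape, dtype=np.uint16)
        self.organ_labels = np.asarray(self.organ_labels)
        if self.organ_labels.shape != self.ct_numbers.shape:
            raise InvalidInputError("label map must match the CT grid shape")
        if self.material_id is None:
            self.material_id = assign_materials(self).material_id
        for lab in self.organ_names:
            if not np.any(self.organ_labels == lab):
                raise InvalidGeometryError(f"labelled organ {self.organ_names[lab]} is empty")

    @property
    def shape(self):
        return self.ct_numbers.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3

    def centers_mm(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along an axis (grid centre = isocenter)."""
        n = self.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size_mm

    def label_of(self, organ: str) -> int:
        for lab, name in self.organ_names.items():
            if name == organ:
                return lab
        raise KeyError(f"no organ named {organ!r}")

    def organ_mask(self, organ: str) -> np.ndarray:
        return self.organ_labels == self.label_of(organ)

    def organ_volume_cm3(self, organ: str) -> float:
        return float(self.organ_mask(organ).sum()) * self.voxel_volume_cm3


def assign_materials(phantom: VoxelPhantom, thresholds=DEFAULT_MATERIAL_THRESHOLDS) -> VoxelPhantom:
    """Classify voxels into transport materials by density thresholds."""
    mat = np.empty(phantom.density.shape, dtype=np.uint8)
    lower = -np.inf
    for upper, mid in thresholds:
        sel = (phantom.density > lower) & (phantom.density <= upper)
        mat[sel] = mid
        lower = upper
    mat[phantom.density <= thresholds[0][0]] = thresholds[0][1]
    phantom.material_id = mat
    return phantom


def _grid(extent_mm, voxel_size_mm):
    n = [int(np.ceil(e / voxel_size_mm)) for e in extent_mm]
    axes = [(np.arange(k) - (k - 1) / 2.0) * voxel_size_mm for k in n]
    return n, axes


def make_pmma_cylinder(
    diameter_mm: float = 320.0,
    insert: str = "detector_channel",
    voxel_size_mm: float = 4.0,
    length_mm: float = 200.0,
    margin_mm: float = 40.0,
) -> VoxelPhantom:
    """32-cm QA cylinder with a 10-mm central channel (air or PMMA rod)."""
    if insert not in ("detector_channel", "pmma_rod"):
        raise InvalidInputError("insert must be 'detector_channel' or 'pmma_rod'")
    if voxel_size_mm < 1.0:
        raise InvalidInputError("voxel size below 1 mm is not supported here")
    insert_diameter = 10.0
    if diameter_mm <= insert_diameter:
        raise InvalidGeometryError("cylinder smaller than its insert")
    side = diameter_mm + 2 * margin_mm
    (nx, ny, nz), (xs, ys, zs) = _grid((side, side, length_mm), voxel_size_mm)
    x, y = np.meshgrid(xs, ys, indexing="ij")
    r2 = x**2 + y**2
    hu = np.full((nx, ny, nz), -1000.0, dtype=np.float32)
    # PMMA at rho 1.19 maps to 190 HU under the two-point line (real PMMA
    # images nearer 120 HU; the density, not the HU, is what transport uses)
    hu[r2 <= (diameter_mm / 2.0) ** 2] = 190.0
    if insert == "detector_channel":
        hu[r2 <= (insert_diameter / 2.0) ** 2] = -1000.0
    return VoxelPhantom(hu, voxel_size_mm, name=f"pmma_cylinder_{insert}")


def _ellipse_semiaxes_for_circumference(circ_mm: float, aspect: float = 1.3):
    """Semi-axes (a lateral, b antero-posterior) with a = aspect * b whose
    Ramanujan perimeter matches the abdominal circumference."""

    def perimeter(b):
        a = aspect * b
        h3 = 3.0 * (a + b)
        return np.pi * (h3 - np.sqrt((h3 - 2 * b) * (h3 - 2 * a)))

    lo, hi = 10.0, 1000.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if perimeter(mid) < circ_mm:
            lo = mid
        else:
            hi = mid
    b = 0.5 * (lo + hi)
    return aspect * b, b


def _ellipsoid_mask(xs, ys, zs, center, semi):
    x, y, z = np.meshgrid(xs, ys, zs, indexing="ij")
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


# organ catalogue: name -> (kind, HU); marrow sites carry bone-like HU
MATERNAL_ORGANS = ("maternal_liver", "maternal_kidneys", "maternal_colon",
                   "maternal_uterus", "maternal_bladder")
FETAL_ORGANS = ("fetal_brain", "fetal_lungs", "fetal_breasts", "fetal_stomach",
                "fetal_colon", "fetal_gonads", "fetal_marrow_skull",
                "fetal_marrow_spine", "fetal_marrow_pelvis", "fetal_remainder")


def make_pregnant_phantom(
    abdominal_circumference_cm: float = 95.0,
    gestational_weeks: float = 32.0,
    voxel_size_mm: float = 4.0,
    seed: int = 0,
    include_couch: bool = True,
) -> VoxelPhantom:
    """Parametric pregnant-abdomen phantom with fetal and maternal labels.

    Deterministic for a fixed seed; the seed only jitters organ centres by a
    few millimetres to emulate case-to-case variation.  Organ sizes scale
    weakly with gestational age around the 32-week defaults.
    """
    if not 70.0 <= abdominal_circumference_cm <= 130.0:
        raise InvalidInputError("abdominal circumference must lie in [70, 130] cm")
    rng = np.random.default_rng(seed)
    a, b = _ellipse_semiaxes_for_circumference(abdominal_circumference_cm * 10.0)
    couch_gap, couch_thick = 4.0, 20.0
    extent_x = 2 * a + 80.0
    extent_y = 2 * b + 80.0 + (couch_gap + couch_thick if include_couch else 0.0)
    extent_z = 240.0
    (nx, ny, nz), (xs, ys, zs) = _grid((extent_x, extent_y, extent_z), voxel_size_mm)
    x, y, z = np.meshgrid(xs, ys, zs, indexing="ij")

    hu = np.full((nx, ny, nz), -1000.0, dtype=np.float32)
    labels = np.zeros((nx, ny, nz), dtype=np.uint16)
    torso = ((x / a) ** 2 + (y / b) ** 2) <= 1.0
    hu[torso] = 30.0  # water-equivalent soft tissue

    if include_couch:
        couch = (y >= b + couch_gap) & (y <= b + couch_gap + couch_thick) & (np.abs(x) <= a + 30.0)
        hu[couch & ~torso] = -760.0  # carbon-fibre-equivalent slab, rho 0.24

    scale = 1.0 + 0.03 * (gestational_weeks - 32.0)
    jit = lambda s=3.0: rng.normal(0.0, s)  # noqa: E731 - mm-level placement jitter

    def place(name, center, semi, hu_value):
        m = _ellipsoid_mask(xs, ys, zs, center, semi) & torso
        if not m.any():
            raise InvalidGeometryError(f"{name} fell outside the torso")
        hu[m] = hu_value
        labels[m] = label_ids[name]
        return m

    label_ids = {name: i + 1 for i, name in enumerate(FETAL_ORGANS + MATERNAL_ORGANS)}
    names = {i: n for n, i in label_ids.items()}

    # fetal envelope: head centrally/inferiorly, trunk against the anterior wall
    head_c = (jit(), 0.15 * b + jit(), -60.0 + jit())
    head_r = 42.0 * scale
    trunk_c = (jit(4.0), -(b - 58.0 * scale) + jit(), 30.0 + jit())
    trunk_semi = (52.0 * scale, 48.0 * scale, 80.0 * scale)
    if abs(trunk_c[1]) + trunk_semi[1] > b + 1e-6:
        raise InvalidGeometryError("fetal trunk exceeds the torso boundary")
    trunk = place("fetal_remainder", trunk_c, trunk_semi, 40.0)
    head = place("fetal_remainder", head_c, (head_r, head_r, head_r), 40.0)
    labels[trunk | head] = label_ids["fetal_remainder"]

    # uterus: maternal band around the fetal envelope
    grow = 14.0
    uterus_zone = (
        _ellipsoid_mask(xs, ys, zs, trunk_c, tuple(s + grow for s in trunk_semi))
        | _ellipsoid_mask(xs, ys, zs, head_c, (head_r + grow,) * 3)
    ) & torso & ~(trunk | head)
    hu[uterus_zone] = 35.0
    labels[uterus_zone] = label_ids["maternal_uterus"]

    # fetal skull: shell of the head; brain inside
    skull_outer = _ellipsoid_mask(xs, ys, zs, head_c, (head_r,) * 3)
    skull_inner = _ellipsoid_mask(xs, ys, zs, head_c, (head_r - 7.0,) * 3)
    shell = skull_outer & ~skull_inner
    hu[shell] = 300.0
    labels[shell] = label_ids["fetal_marrow_skull"]
    place("fetal_brain", head_c, (head_r - 9.0,) * 3, 35.0)

    tx, ty, tz = trunk_c
    sx, sy, sz = trunk_semi
    place("fetal_lungs", (tx - 0.45 * sx, ty, tz + 0.45 * sz), (0.32 * sx, 0.5 * sy, 0.35 * sz), 20.0)
    place("fetal_lungs", (tx + 0.45 * sx, ty, tz + 0.45 * sz), (0.32 * sx, 0.5 * sy, 0.35 * sz), 20.0)
    place("fetal_breasts", (tx, ty - 0.75 * sy, tz + 0.5 * sz), (0.45 * sx, 0.22 * sy, 0.2 * sz), 25.0)
    place("fetal_stomach", (tx - 0.25 * sx, ty - 0.2 * sy, tz), (0.28 * sx, 0.3 * sy, 0.2 * sz), 20.0)
    place("fetal_colon", (tx + 0.2 * sx, ty, tz - 0.35 * sz), (0.35 * sx, 0.4 * sy, 0.25 * sz), 25.0)
    place("fetal_gonads", (tx, ty + 0.1 * sy, tz - 0.75 * sz), (0.22 * sx, 0.25 * sy, 0.15 * sz), 30.0)
    # marrow sites: spine along the posterior of the trunk, pelvis near its base
    place("fetal_marrow_spine", (tx, ty + 0.7 * sy, tz), (0.16 * sx, 0.18 * sy, 0.8 * sz), 300.0)
    place("fetal_marrow_pelvis", (tx, ty + 0.35 * sy, tz - 0.8 * sz), (0.3 * sx, 0.3 * sy, 0.18 * sz), 300.0)

    # maternal organs away from the anterior wall
    place("maternal_liver", (-0.45 * a, 0.25 * b, 95.0), (0.35 * a, 0.4 * b, 45.0), 50.0)
    place("maternal_kidneys", (-0.55 * a, 0.6 * b, 20.0), (0.14 * a, 0.22 * b, 40.0), 35.0)
    place("maternal_kidneys", (0.55 * a, 0.6 * b, 20.0), (0.14 * a, 0.22 * b, 40.0), 35.0)
    place("maternal_colon", (0.62 * a, 0.15 * b, -10.0), (0.16 * a, 0.5 * b, 80.0), 25.0)
    place("maternal_bladder", (0.0, 0.45 * b, -100.0), (0.18 * a, 0.22 * b, 24.0), 15.0)

    phantom = VoxelPhantom(
        hu, voxel_size_mm, organ_labels=labels, organ_names=names,
        name=f"pregnant_abdomen_ac{abdominal_circumference_cm:g}_s{seed}",
    )
    return phantom
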