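"""Synthetic voxelized rodent-like phantoms.

Builds labelled 3-D grids from analytic solids (ellipsoids, capsules,
shells) standing in for a licensed NURBS mouse anatomy: a soft-tissue
body, hollow organs, a segmented skeleton with marrow cores, and
spherical shoulder tumours merged into an expanded matrix.

Conventions: 0-based voxel indices, axis order (x, y, z), isotropic
voxels, world position = voxel center (voxel (0,0,0) center at `origin`).
A voxel belongs to a solid iff its center lies inside.  Overlap between
organs of different classes resolves by class priority
(skeleton > marrow > soft > body); same-class overlaps require an
explicit priority, otherwise they raise.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .materials import MaterialSpec, builtin_materials

__all__ = [
    "Sphere", "Ellipsoid", "Capsule", "Box", "Shell",
    "OrganDef", "ResolutionSpec", "PhantomConfig", "TumourSpec",
    "VoxelPhantom", "ActivityImage", "OrganMask",
    "LR", "HR", "build_phantom", "insert_tumour", "organ_mass",
    "make_source_image", "mu_to_hu", "load_hu_curve", "mouse_config",
    "shoulder_site", "attenuation_image",
]

CLASS_PRIORITY = {"body": 1, "soft": 2, "lung": 2, "tumour": 2, "marrow": 3, "skeleton": 4}


# -- analytic solids --------------------------------------------------------

class Solid:
    def contains(self, x, y, z):  # pragma: no cover - interface
        raise NotImplementedError

    def scaled(self, s: float, about) -> "Solid":  # pragma: no cover - interface
        raise NotImplementedError


def _scale_point(p, s, about):
    return tuple(a + s * (pi - a) for pi, a in zip(p, about))


@dataclass(frozen=True)
class Sphere(Solid):
    center: tuple
    radius: float

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius**2

    def scaled(self, s, about):
        return Sphere(_scale_point(self.center, s, about), self.radius * s)


@dataclass(frozen=True)
class Ellipsoid(Solid):
    center: tuple
    radii: tuple

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        rx, ry, rz = self.radii
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0

    def scaled(self, s, about):
        return Ellipsoid(
            _scale_point(self.center, s, about), tuple(r * s for r in self.radii)
        )


@dataclass(frozen=True)
class Capsule(Solid):
    """Cylinder with hemispherical caps between p1 and p2 (bone rods)."""

    p1: tuple
    p2: tuple
    radius: float

    def contains(self, x, y, z):
        p1 = np.asarray(self.p1, dtype=float)
        d = np.asarray(self.p2, dtype=float) - p1
        L2 = float(d @ d)
        vx, vy, vz = x - p1[0], y - p1[1], z - p1[2]
        t = (vx * d[0] + vy * d[1] + vz * d[2]) / L2 if L2 > 0 else 0.0
        t = np.clip(t, 0.0, 1.0)
        qx = vx - t * d[0]
        qy = vy - t * d[1]
        qz = vz - t * d[2]
        return qx**2 + qy**2 + qz**2 <= self.radius**2

    def scaled(self, s, about):
        return Capsule(
            _scale_point(self.p1, s, about),
            _scale_point(self.p2, s, about),
            self.radius * s,
        )


@dataclass(frozen=True)
class Box(Solid):
    lo: tuple
    hi: tuple

    def contains(self, x, y, z):
        lx, ly, lz = self.lo
        hx, hy, hz = self.hi
        return (x >= lx) & (x <= hx) & (y >= ly) & (y <= hy) & (z >= lz) & (z <= hz)

    def scaled(self, s, about):
        return Box(_scale_point(self.lo, s, about), _scale_point(self.hi, s, about))


@dataclass(frozen=True)
class Shell(Solid):
    """Set difference outer minus inner (organ walls, skull)."""

    outer: Solid
    inner: Solid

    def contains(self, x, y, z):
        return self.outer.contains(x, y, z) & ~self.inner.contains(x, y, z)

    def scaled(self, s, about):
        return Shell(self.outer.scaled(s, about), self.inner.scaled(s, about))


# -- configuration ----------------------------------------------------------

@dataclass(frozen=True)
class OrganDef:
    name: str
    material: str
    solid: Solid
    organ_class: str = "soft"
    priority: int | None = None
    cavity: Solid | None = None  # hollow organs: interior repainted as body
    parent: str | None = None  # marrow shells: name of the enclosing bone

    def __post_init__(self):
        if self.organ_class not in CLASS_PRIORITY:
            raise ValueError(f"unknown organ class {self.organ_class!r}")
        if self.organ_class == "marrow" and self.parent is None:
            raise ValueError(f"marrow organ {self.name!r} needs a parent bone")


@dataclass(frozen=True)
class ResolutionSpec:
    shape: tuple
    voxel_size_mm: float
    expanded_shape: tuple | None = None


#: the two study resolutions; expanded shapes are the tumour-merged matrices
LR = ResolutionSpec(shape=(74, 74, 184), voxel_size_mm=0.625, expanded_shape=(80, 80, 175))
HR = ResolutionSpec(shape=(128, 128, 400), voxel_size_mm=0.29, expanded_shape=(140, 140, 355))
_PRESETS = {"lr": LR, "hr": HR}


@dataclass(frozen=True)
class PhantomConfig:
    resolution: ResolutionSpec
    body: OrganDef
    organs: tuple = ()
    target_mass_g: float | None = None
    materials: dict = field(default_factory=builtin_materials)

    @staticmethod
    def resolution_from(res) -> ResolutionSpec:
        if isinstance(res, ResolutionSpec):
            return res
        return _PRESETS[str(res).lower()]


@dataclass(frozen=True)
class TumourSpec:
    """Spherical unit-density xenograft, parameterized by mass."""

    mass_g: float
    center_mm: tuple
    density: float = 1.0
    label: int | None = None

    def __post_init__(self):
        if self.mass_g <= 0:
            raise ValueError("tumour mass must be > 0")
        if self.density <= 0:
            raise ValueError("tumour density must be > 0")

    @property
    def diameter_mm(self) -> float:
        # d = (6 m / (pi rho))^(1/3); mass in g, density g/cm^3 -> cm -> mm
        return (6.0 * self.mass_g / (np.pi * self.density)) ** (1.0 / 3.0) * 10.0


# -- core data types --------------------------------------------------------

@dataclass(frozen=True)
class LabelInfo:
    name: str
    material: MaterialSpec
    organ_class: str


@dataclass
class VoxelPhantom:
    """Labelled 3-D grid with a label table and isotropic voxel size."""

    label_grid: np.ndarray  # int16, shape (nx, ny, nz); 0 = outside-body air
    voxel_size_mm: float
    label_table: dict  # label -> LabelInfo
    origin_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        present = set(np.unique(self.label_grid).tolist()) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label table")

    # geometry ------------------------------------------------------------
    @property
    def shape(self):
        return self.label_grid.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3

    def voxel_centers(self):
        h, o = self.voxel_size_mm, self.origin_mm
        nx, ny, nz = self.shape
        return (
            (o[0] + h * np.arange(nx))[:, None, None],
            (o[1] + h * np.arange(ny))[None, :, None],
            (o[2] + h * np.arange(nz))[None, None, :],
        )

    # bookkeeping ---------------------------------------------------------
    def label_for(self, name: str) -> int:
        for lab, info in self.label_table.items():
            if info.name == name:
                return lab
        raise KeyError(name)

    def labels_by_class(self, *classes: str) -> list:
        return [l for l, i in self.label_table.items() if i.organ_class in classes]

    def mask(self, label: int) -> np.ndarray:
        if label not in self.label_table:
            raise KeyError(f"unknown label {label}")
        return self.label_grid == label

    def voxel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.mask(label)))

    def masses(self) -> dict:
        out = {}
        labels, counts = np.unique(self.label_grid, return_counts=True)
        for lab, v in zip(labels.tolist(), counts.tolist()):
            if lab == 0:
                continue
            info = self.label_table[lab]
            out[info.name] = v * self.voxel_volume_cm3 * info.material.density
        return out

    @property
    def total_mass_g(self) -> float:
        return float(sum(self.masses().values()))

    def density_grid(self) -> np.ndarray:
        rho = np.full(self.shape, builtin_materials()["air"].density, dtype=np.float64)
        for lab, info in self.label_table.items():
            rho[self.label_grid == lab] = info.material.density
        return rho

    def write_label_table_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "name", "material", "density_g_cm3", "organ_class"])
            for lab in sorted(self.label_table):
                info = self.label_table[lab]
                w.writerow([lab, info.name, info.material.name, info.material.density,
                            info.organ_class])


@dataclass(frozen=True)
class ActivityImage:
    """Normalized per-voxel emission probabilities for one source label."""

    grid: np.ndarray
    source_label: int

    def __post_init__(self):
        if np.any(self.grid < 0):
            raise ValueError("activity values must be non-negative")
        total = float(self.grid.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"activity image sums to {total}, expected 1")


@dataclass(frozen=True)
class OrganMask:
    """Flat voxel-index set for one label (or a union of labels)."""

    flat_indices: np.ndarray
    shape: tuple

    def __post_init__(self):
        if self.v < 1:
            raise ValueError("organ mask must contain at least one voxel")

    @property
    def v(self) -> int:
        return int(self.flat_indices.size)

    def dense(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m.reshape(-1)[self.flat_indices] = True
        return m

    @classmethod
    def from_labels(cls, phantom: VoxelPhantom, labels) -> "OrganMask":
        labels = [labels] if np.isscalar(labels) else list(labels)
        for lab in labels:
            if lab not in phantom.label_table:
                raise KeyError(f"unknown label {lab}")
        m = np.isin(phantom.label_grid, labels)
        return cls(np.flatnonzero(m.reshape(-1)), phantom.shape)


# -- phantom construction ---------------------------------------------------

def _voxelize(solid: Solid, xs, ys, zs) -> np.ndarray:
    return solid.contains(xs, ys, zs)


def _paint(config: PhantomConfig, scale: float) -> VoxelPhantom:
    res = config.resolution
    nx, ny, nz = res.shape
    h = res.voxel_size_mm
    origin = (0.0, 0.0, 0.0)
    xs = (origin[0] + h * np.arange(nx))[:, None, None]
    ys = (origin[1] + h * np.arange(ny))[None, :, None]
    zs = (origin[2] + h * np.arange(nz))[None, None, :]
    about = tuple(h * (n - 1) / 2.0 for n in (nx, ny, nz))

    grid = np.zeros((nx, ny, nz), dtype=np.int16)
    table: dict[int, LabelInfo] = {}
    materials = config.materials

    def solid_of(organ: OrganDef) -> Solid:
        return organ.solid if scale == 1.0 else organ.solid.scaled(scale, about)

    # body first
    body_mask = _voxelize(solid_of(config.body), xs, ys, zs)
    grid[body_mask] = 1
    table[1] = LabelInfo(config.body.name, materials[config.body.material], "body")

    # paint rank differs from conflict priority: marrow is painted after its
    # parent bone so that it carves the bone's cavity
    paint_rank = {"body": 1, "soft": 2, "lung": 2, "tumour": 2, "skeleton": 3, "marrow": 4}
    order = sorted(
        enumerate(config.organs),
        key=lambda t: (paint_rank[t[1].organ_class], t[1].priority or 0, t[0]),
    )
    next_label = 2
    name_to_label: dict[str, int] = {config.body.name: 1}
    bone_masks: dict[str, np.ndarray] = {}
    painted_priority: dict[int, int | None] = {}
    for _, organ in order:
        mask = _voxelize(solid_of(organ), xs, ys, zs)
        if organ.organ_class == "marrow":
            if organ.parent not in bone_masks:
                raise ValueError(
                    f"marrow {organ.name!r}: parent bone {organ.parent!r} not painted"
                )
            mask &= bone_masks[organ.parent]
        if not mask.any():
            warnings.warn(
                f"organ {organ.name!r} thinner than one voxel at this resolution; dropped",
                stacklevel=2,
            )
            continue
        # same-class overlap needs a declared priority
        clash = mask & (grid > 1)
        if clash.any():
            for lab in np.unique(grid[clash]).tolist():
                info = table[lab]
                same_class = CLASS_PRIORITY[info.organ_class] == CLASS_PRIORITY[organ.organ_class]
                undeclared = organ.priority is None and painted_priority.get(lab) is None
                if same_class and undeclared and organ.parent is None:
                    raise ValueError(
                        f"organs {organ.name!r} and {info.name!r} overlap without a "
                        "declared priority"
                    )
        lab = next_label
        next_label += 1
        painted_priority[lab] = organ.priority
        grid[mask] = lab
        table[lab] = LabelInfo(organ.name, materials[organ.material], organ.organ_class)
        name_to_label[organ.name] = lab
        if organ.organ_class == "skeleton":
            bone_masks[organ.name] = mask
        if organ.cavity is not None:
            cav = _voxelize(
                organ.cavity if scale == 1.0 else organ.cavity.scaled(scale, about),
                xs, ys, zs,
            )
            grid[cav & (grid == lab)] = 1  # unlabeled interior -> body

    return VoxelPhantom(grid, h, table, origin)


def build_phantom(config: PhantomConfig) -> VoxelPhantom:
    """Voxelize a phantom configuration.

    If `target_mass_g` is set, every solid is scaled isotropically about
    the grid center (no per-organ scaling) until the voxelized whole-body
    mass is within 10% of the target.
    """
    phantom = _paint(config, 1.0)
    if config.target_mass_g is not None:
        scale = 1.0
        for _ in range(3):
            m = phantom.total_mass_g
            if abs(m - config.target_mass_g) / config.target_mass_g <= 0.02:
                break
            scale *= (config.target_mass_g / m) ** (1.0 / 3.0)
            phantom = _paint(config, scale)
        m = phantom.total_mass_g
        if abs(m - config.target_mass_g) / config.target_mass_g > 0.10:
            raise ValueError(
                f"could not reach target mass {config.target_mass_g} g "
                f"(achieved {m:.2f} g)"
            )
    return phantom


def insert_tumour(
    phantom: VoxelPhantom,
    spec: TumourSpec,
    expanded_shape: tuple | None = None,
    material: MaterialSpec | None = None,
) -> VoxelPhantom:
    """Merge a spherical tumour into a zero-padded enlarged matrix.

    The output grid is resized to `expanded_shape` (padding with air at the
    high end of each axis; cropping only empty slices).  Tumour voxels
    override soft/body voxels but never skeleton or marrow voxels, which
    raise instead (the xenografts are subcutaneous).
    """
    h = phantom.voxel_size_mm
    if spec.diameter_mm <= 2.0 * h:
        raise ValueError(
            f"tumour diameter {spec.diameter_mm:.2f} mm must exceed two voxels "
            f"({2 * h:.2f} mm)"
        )
    if expanded_shape is None:
        for res in (LR, HR):
            if phantom.shape == res.shape and res.expanded_shape:
                expanded_shape = res.expanded_shape
                break
        else:
            expanded_shape = phantom.shape

    grid = phantom.label_grid
    new = np.zeros(expanded_shape, dtype=grid.dtype)
    take = tuple(min(a, b) for a, b in zip(grid.shape, expanded_shape))
    cropped = grid[: take[0], : take[1], : take[2]]
    if np.count_nonzero(cropped) != np.count_nonzero(grid):
        raise ValueError("expanded shape would crop labelled voxels")
    new[: take[0], : take[1], : take[2]] = cropped

    out = VoxelPhantom(new, h, dict(phantom.label_table), phantom.origin_mm)
    cx, cy, cz = spec.center_mm
    xs, ys, zs = out.voxel_centers()
    mask = Sphere((cx, cy, cz), spec.diameter_mm / 2.0).contains(xs, ys, zs)
    if not (0 <= mask.nonzero()[0].min() and mask.any()):
        raise ValueError("tumour sphere does not intersect the expanded matrix")
    bone_labels = out.labels_by_class("skeleton", "marrow")
    if bone_labels and np.isin(out.label_grid[mask], bone_labels).any():
        raise ValueError("tumour overlaps skeleton labels; xenografts are subcutaneous")

    if material is None:
        material = MaterialSpec("tumour", spec.density)
    label = spec.label if spec.label is not None else max(out.label_table) + 1
    if label in out.label_table:
        raise ValueError(f"tumour label {label} already in use")
    out.label_grid[mask] = label
    out.label_table[label] = LabelInfo("tumour", material, "tumour")

    voxelized = mask.sum() * out.voxel_volume_cm3 * spec.density
    if abs(voxelized - spec.mass_g) / spec.mass_g > 0.05:
        raise ValueError(
            f"voxelized tumour mass {voxelized:.4f} g deviates >5% from "
            f"{spec.mass_g} g"
        )
    return out


def organ_mass(phantom: VoxelPhantom, label: int) -> float:
    """Mass of one label in grams: v * voxel volume * material density."""
    if label not in phantom.label_table:
        raise KeyError(f"unknown label {label}")
    v = phantom.voxel_count(label)
    if v == 0:
        raise ValueError(f"label {label} has no voxels")
    return v * phantom.voxel_volume_cm3 * phantom.label_table[label].material.density


def make_source_image(phantom: VoxelPhantom, label: int) -> ActivityImage:
    """Uniform emission probability across the label's voxels (sums to 1)."""
    mask = phantom.mask(label)
    v = int(np.count_nonzero(mask))
    if v < 1:
        raise ValueError(f"label {label} has no voxels")
    grid = np.zeros(phantom.shape, dtype=np.float64)
    grid[mask] = 1.0 / v
    return ActivityImage(grid=grid, source_label=label)


# -- attenuation / HU -------------------------------------------------------

def load_hu_curve(path=None) -> np.ndarray:
    """HU <-> mu calibration nodes as an (n, 2) array of (hu, mu_1/cm)."""
    if path is None:
        path = resources.files("voxdose.data").joinpath("hu_curve.csv")
        fh = path.open()
    else:
        fh = open(path)
    with fh:
        rows = [
            (float(r["hu"]), float(r["mu"]))
            for r in csv.DictReader(l for l in fh if not l.startswith("#"))
        ]
    curve = np.asarray(rows, dtype=float)
    if np.any(np.diff(curve[:, 1]) <= 0):
        raise ValueError("HU curve must be strictly monotone in mu")
    return curve


def mu_to_hu(mu_map: np.ndarray, voxel_size_mm: float, curve: np.ndarray | None = None) -> np.ndarray:
    """Convert a per-pixel attenuation grid to Hounsfield units.

    Per-pixel values are divided by the voxel size in cm to give 1/cm,
    then inverse-interpolated (piecewise linear) through the calibration
    curve.  Values outside the curve are clamped to its endpoints with a
    warning.
    """
    if curve is None:
        curve = load_hu_curve()
    mu_cm = np.asarray(mu_map, dtype=float) / (voxel_size_mm / 10.0)
    lo, hi = curve[0, 1], curve[-1, 1]
    if np.any(mu_cm < lo) or np.any(mu_cm > hi):
        warnings.warn("attenuation values outside calibration curve; clamped", stacklevel=2)
        mu_cm = np.clip(mu_cm, lo, hi)
    return np.interp(mu_cm, curve[:, 1], curve[:, 0])


def attenuation_image(phantom: VoxelPhantom, energy_kev: float = 140.0, per_pixel: bool = True) -> np.ndarray:
    """Linear attenuation map of the phantom at `energy_kev`.

    With `per_pixel` the values are mu * voxel_size_cm (1/pixel), matching
    the raw image convention expected by :func:`mu_to_hu`.
    """
    mu = np.full(phantom.shape, builtin_materials()["air"].mu(energy_kev), dtype=float)
    for lab, info in phantom.label_table.items():
        mu[phantom.label_grid == lab] = info.material.mu(energy_kev)
    if per_pixel:
        mu = mu * (phantom.voxel_size_mm / 10.0)
    return mu


# -- default mouse-like configuration ---------------------------------------

def mouse_config(resolution="lr", target_mass_g: float = 25.0) -> PhantomConfig:
    """A documented analytic mouse-like anatomy (~25 g).

    Positions are in world mm on the LR/HR grid extents: a soft-tissue
    body capsule along z; brain in a skull shell; spine, humeri and femora
    as bone capsules with marrow cores; hollow heart and stomach walls;
    lungs, liver, kidneys, spleen, bladder, testes as soft solids.  The
    left shoulder (tumour site) is the +x side near the top of the spine.
    """
    res = PhantomConfig.resolution_from(resolution)
    # transverse centers track the grid; axial coordinates are absolute and
    # fit both study grids (LR 115 mm, HR 116 mm along z)
    c = (res.shape[0] - 1) * res.voxel_size_mm / 2.0
    d = (res.shape[1] - 1) * res.voxel_size_mm / 2.0
    body = OrganDef("body", "soft", Capsule((c, d, 18.0), (c, d, 95.0), 11.0),
                    organ_class="body")
    organs = [
        OrganDef("brain", "soft", Sphere((c, d, 88.0), 5.0)),
        OrganDef("heart", "soft",
                 Shell(Sphere((c, d - 3.1, 70.0), 3.5), Sphere((c, d - 3.1, 70.0), 2.2)),
                 cavity=Sphere((c, d - 3.1, 70.0), 2.2)),
        OrganDef("lung_left", "lung", Ellipsoid((c - 7.1, d + 1.4, 72.0), (3.0, 3.5, 5.5))),
        OrganDef("lung_right", "lung", Ellipsoid((c + 7.1, d + 1.4, 72.0), (3.0, 3.5, 5.5))),
        OrganDef("liver", "soft", Ellipsoid((c, d, 55.0), (8.0, 7.0, 7.0))),
        OrganDef("stomach_wall", "soft",
                 Shell(Sphere((c - 6.1, d - 3.1, 47.0), 3.2), Sphere((c - 6.1, d - 3.1, 47.0), 2.4)),
                 cavity=Sphere((c - 6.1, d - 3.1, 47.0), 2.4)),
        OrganDef("kidney_left", "soft", Ellipsoid((c - 6.1, d + 3.9, 40.0), (2.4, 2.0, 3.0))),
        OrganDef("kidney_right", "soft", Ellipsoid((c + 6.1, d + 3.9, 40.0), (2.4, 2.0, 3.0))),
        OrganDef("spleen", "soft", Ellipsoid((c + 7.4, d - 5.1, 50.0), (1.6, 1.2, 4.0))),
        OrganDef("bladder", "soft", Sphere((c, d + 4.4, 24.0), 2.0)),
        OrganDef("testes", "soft", Sphere((c, d - 3.6, 13.5), 2.2)),
        # skeleton with marrow cores
        OrganDef("skull", "bone",
                 Shell(Sphere((c, d, 88.0), 6.3), Sphere((c, d, 88.0), 5.0)),
                 organ_class="skeleton"),
        OrganDef("skull_marrow", "marrow",
                 Shell(Sphere((c, d, 88.0), 5.9), Sphere((c, d, 88.0), 5.0)),
                 organ_class="marrow", parent="skull"),
        OrganDef("spine", "bone", Capsule((c, d, 20.0), (c, d, 79.0), 1.7),
                 organ_class="skeleton"),
        OrganDef("spine_marrow", "marrow",
                 Capsule((c, d, 21.0), (c, d, 78.0), 0.85),
                 organ_class="marrow", parent="spine"),
        OrganDef("humerus_left", "bone", Capsule((c + 10.4, d, 77.0), (c + 13.4, d, 63.0), 1.2),
                 organ_class="skeleton"),
        OrganDef("humerus_left_marrow", "marrow",
                 Capsule((c + 10.6, d, 76.0), (c + 13.1, d, 64.0), 0.6),
                 organ_class="marrow", parent="humerus_left"),
        OrganDef("humerus_right", "bone", Capsule((c - 10.4, d, 77.0), (c - 13.4, d, 63.0), 1.2),
                 organ_class="skeleton"),
        OrganDef("humerus_right_marrow", "marrow",
                 Capsule((c - 10.6, d, 76.0), (c - 13.1, d, 64.0), 0.6),
                 organ_class="marrow", parent="humerus_right"),
        OrganDef("femur_left", "bone", Capsule((c + 8.4, d, 25.0), (c + 10.9, d, 11.0), 1.3),
                 organ_class="skeleton"),
        OrganDef("femur_left_marrow", "marrow",
                 Capsule((c + 8.6, d, 24.0), (c + 10.7, d, 12.0), 0.65),
                 organ_class="marrow", parent="femur_left"),
        OrganDef("femur_right", "bone", Capsule((c - 8.4, d, 25.0), (c - 10.9, d, 11.0), 1.3),
                 organ_class="skeleton"),
        OrganDef("femur_right_marrow", "marrow",
                 Capsule((c - 8.6, d, 24.0), (c - 10.7, d, 12.0), 0.65),
                 organ_class="marrow", parent="femur_right"),
    ]
    return PhantomConfig(resolution=res, body=body, organs=tuple(organs),
                         target_mass_g=target_mass_g)


def shoulder_site(resolution="lr") -> tuple:
    """Default subcutaneous left-shoulder tumour site (world mm)."""
    res = PhantomConfig.resolution_from(resolution)
    c = (res.shape[0] - 1) * res.voxel_size_mm / 2.0
    d = (res.shape[1] - 1) * res.voxel_size_mm / 2.0
    return (c + 7.9, d - 10.1, 82.0)
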