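"""Synthetic 2D thorax phantoms for IMRT planning experiments.

A phantom is a voxelized axial cross-section with boolean masks for the
patient body, the planning target volume (PTV) and the organs at risk
(OARs) used by locally advanced non-small-cell lung cancer (LA-NSCLC)
planning: lungs, heart, esophagus, spinal canal and (optionally) the
brachial plexus.  Geometry is schematic — parameterized ellipses and
circles on a regular grid — not anatomical; its purpose is to exhibit the
lung/heart/esophagus trade-offs that drive beam-angle and fluence
optimization.

Conventions
-----------
Grids are ``(ny, nx)`` arrays.  The x axis points to the patient's left,
the y axis to anterior, with the origin at the grid center.  Row index
increases posteriorly, column index to the patient's left.  A "right"
tumor laterality therefore means the PTV centroid has negative x.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

REQUIRED_STRUCTURES = ("body", "PTV", "lungs", "heart", "esophagus", "spinal_canal")

#: Distances (mm) of the conformity shells used by the default wish-list.
DEFAULT_SHELL_DISTANCES_MM = (3.0, 10.0, 30.0, 70.0)


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration cannot produce a valid geometry."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry parameters for :func:`generate_phantom`.

    Lengths are millimetres in the phantom coordinate frame (x to
    patient-left, y anterior).  ``jitter_mm`` is the half-width of the
    uniform perturbation applied to organ centers and semi-axes so that
    seeded phantoms form a population rather than one fixed geometry.
    """

    grid_shape: tuple[int, int] = (96, 128)
    spacing_mm: tuple[float, float] = (2.5, 2.5)
    laterality: str = "left"
    prescription_Gy: float = 66.0
    tumor_radius_mm: float = 25.0
    #: Unsigned offsets of the tumor center from the grid origin; the x
    #: offset is mirrored for right-sided tumors.
    tumor_offset_mm: tuple[float, float] = (65.0, 10.0)
    body_semiaxes_mm: tuple[float, float] = (155.0, 105.0)
    lung_semiaxes_mm: tuple[float, float] = (48.0, 70.0)
    lung_offset_mm: tuple[float, float] = (78.0, 5.0)
    heart_center_mm: tuple[float, float] = (18.0, 8.0)
    heart_semiaxes_mm: tuple[float, float] = (40.0, 32.0)
    esophagus_center_mm: tuple[float, float] = (-4.0, -42.0)
    esophagus_radius_mm: float = 7.0
    canal_center_mm: tuple[float, float] = (0.0, -72.0)
    canal_radius_mm: float = 6.0
    jitter_mm: float = 4.0
    include_brachial_plexus: bool = False

    def validate(self) -> None:
        ny, nx = self.grid_shape
        if ny < 8 or nx < 8:
            raise PhantomConfigError(f"grid too small: {self.grid_shape}")
        if min(self.spacing_mm) <= 0:
            raise PhantomConfigError(f"non-positive spacing: {self.spacing_mm}")
        if self.laterality not in ("left", "right"):
            raise PhantomConfigError(f"unknown laterality: {self.laterality!r}")
        if self.prescription_Gy not in (60.0, 66.0, 70.0):
            raise PhantomConfigError(
                f"prescription must be 60, 66 or 70 Gy, got {self.prescription_Gy}"
            )
        if self.tumor_radius_mm <= 0:
            raise PhantomConfigError("tumor radius must be positive")
        ax, ay = self.body_semiaxes_mm
        ox, oy = self.tumor_offset_mm
        # Tumor (plus jitter headroom) must fit inside the body ellipse.
        r = self.tumor_radius_mm + self.jitter_mm
        if (abs(ox) + r) ** 2 / ax**2 + (abs(oy) + r) ** 2 / ay**2 > 1.0:
            raise PhantomConfigError("tumor does not fit inside the body outline")
        half_x = (nx - 1) / 2 * self.spacing_mm[1]
        half_y = (ny - 1) / 2 * self.spacing_mm[0]
        if ax >= half_x or ay >= half_y:
            raise PhantomConfigError("body ellipse exceeds the grid extent")


#: A compact configuration for fast experiments and test fixtures: 3 mm
#: voxels over a 23 x 34 cm field of view (3 mm is the coarsest spacing
#: that still resolves the innermost conformity shell).
SMALL_CONFIG = PhantomConfig(
    grid_shape=(76, 112),
    spacing_mm=(3.0, 3.0),
    tumor_radius_mm=22.0,
    body_semiaxes_mm=(155.0, 100.0),
)


@dataclass
class Phantom:
    """A voxelized cross-section with named structure masks."""

    grid_shape: tuple[int, int]
    spacing_mm: tuple[float, float]
    masks: dict[str, np.ndarray]
    laterality: str
    prescription_Gy: float

    @property
    def voxel_volume_mm2(self) -> float:
        return float(self.spacing_mm[0] * self.spacing_mm[1])

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-center coordinates ``(x_mm, y_mm)`` as 2D arrays."""
        ny, nx = self.grid_shape
        sy, sx = self.spacing_mm
        x = (np.arange(nx) - (nx - 1) / 2) * sx
        y = ((ny - 1) / 2 - np.arange(ny)) * sy
        xx, yy = np.meshgrid(x, y)
        return xx, yy

    def structure_names(self) -> list[str]:
        return list(self.masks)


@dataclass
class DerivedStructures:
    """Conformity helper structures derived from the phantom geometry.

    ``shells`` maps a distance in mm to the one-voxel-band mask of voxels
    at that distance from the PTV; ``external_ring`` is the 2 cm band
    inside the body surface with the 4 cm-dilated PTV removed.
    """

    shells: dict[float, np.ndarray] = field(default_factory=dict)
    external_ring: np.ndarray | None = None

    def as_masks(self) -> dict[str, np.ndarray]:
        """Flatten to a name -> mask map using wish-list structure names."""
        out: dict[str, np.ndarray] = {}
        for d, mask in self.shells.items():
            out[shell_name(d)] = mask
        if self.external_ring is not None:
            out["external_ring"] = self.external_ring
        return out


def shell_name(distance_mm: float) -> str:
    """Canonical structure name for a PTV shell, e.g. ``shell_3mm``, ``shell_1cm``."""
    if distance_mm % 10 == 0:
        return f"shell_{int(distance_mm) // 10}cm"
    return f"shell_{int(round(distance_mm))}mm"


def _ellipse(xx, yy, center, semiaxes) -> np.ndarray:
    cx, cy = center
    ax, ay = semiaxes
    return (xx - cx) ** 2 / ax**2 + (yy - cy) ** 2 / ay**2 <= 1.0


def generate_phantom(config: PhantomConfig | None = None, seed: int = 0) -> Phantom:
    """Generate a seeded synthetic thorax cross-section.

    The seed drives a uniform jitter of organ centers and semi-axes
    (half-width ``config.jitter_mm``), producing a reproducible population
    of geometries: identical ``(config, seed)`` pairs yield bit-identical
    masks.

    Raises
    ------
    PhantomConfigError
        If the configuration is geometrically infeasible (tumor outside
        the body, body outside the grid, ...).
    """
    config = config or PhantomConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    j = config.jitter_mm

    def jit(n: int = 1):
        return rng.uniform(-j, j, size=n)

    ph = Phantom(
        grid_shape=config.grid_shape,
        spacing_mm=config.spacing_mm,
        masks={},
        laterality=config.laterality,
        prescription_Gy=config.prescription_Gy,
    )
    xx, yy = ph.coordinates()

    body_ax = config.body_semiaxes_mm[0] + jit()[0] * 0.5
    body_ay = config.body_semiaxes_mm[1] + jit()[0] * 0.5
    body = _ellipse(xx, yy, (0.0, 0.0), (body_ax, body_ay))

    sign = 1.0 if config.laterality == "left" else -1.0
    lx, ly = config.lung_offset_mm
    lax, lay = config.lung_semiaxes_mm
    lungs = np.zeros_like(body)
    for s in (+1.0, -1.0):
        c = (s * lx + jit()[0] * 0.5, ly + jit()[0] * 0.5)
        a = (lax + jit()[0] * 0.5, lay + jit()[0] * 0.5)
        lungs |= _ellipse(xx, yy, c, a)

    hc = (config.heart_center_mm[0] + jit()[0], config.heart_center_mm[1] + jit()[0])
    heart = _ellipse(xx, yy, hc, config.heart_semiaxes_mm)

    ec = (
        config.esophagus_center_mm[0] + jit()[0] * 0.5,
        config.esophagus_center_mm[1] + jit()[0] * 0.5,
    )
    esophagus = _ellipse(
        xx, yy, ec, (config.esophagus_radius_mm, config.esophagus_radius_mm)
    )

    canal = _ellipse(
        xx, yy, config.canal_center_mm, (config.canal_radius_mm, config.canal_radius_mm)
    )

    tx = sign * config.tumor_offset_mm[0] + jit()[0]
    ty = config.tumor_offset_mm[1] + jit()[0]
    tr = config.tumor_radius_mm + rng.uniform(-0.5, 0.5) * j
    ptv = _ellipse(xx, yy, (tx, ty), (tr, tr))

    # Resolve overlaps: organs are mutually exclusive in priority order
    # canal > esophagus > heart > lungs; the PTV may overlap soft tissue
    # but never the spinal canal.
    esophagus &= ~canal
    heart &= ~(canal | esophagus)
    lungs &= ~(canal | esophagus | heart)
    ptv &= ~canal

    masks = {
        "body": body,
        "PTV": ptv & body,
        "lungs": lungs & body,
        "heart": heart & body,
        "esophagus": esophagus & body,
        "spinal_canal": canal & body,
    }
    if config.include_brachial_plexus:
        # Schematic plexus: small paravertebral disc on the tumor side,
        # placed relative to the body outline so it scales with geometry.
        pc = (sign * 0.22 * body_ax, -0.52 * body_ay)
        masks["brachial_plexus"] = _ellipse(xx, yy, pc, (6.0, 6.0)) & body
    ph.masks = masks

    problems = check_invariants(ph)
    if problems:
        raise PhantomConfigError(
            "generated phantom violates invariants: " + "; ".join(problems)
        )
    return ph


def check_invariants(phantom: Phantom) -> list[str]:
    """Return a list of violated phantom invariants (empty when valid)."""
    problems: list[str] = []
    masks = phantom.masks
    for name in REQUIRED_STRUCTURES:
        if name not in masks:
            problems.append(f"missing structure {name!r}")
    if problems:
        return problems
    body = masks["body"]
    for name, mask in masks.items():
        if name != "body" and np.any(mask & ~body):
            problems.append(f"{name} extends outside the body")
    if np.any(masks["PTV"] & masks["spinal_canal"]):
        problems.append("PTV overlaps the spinal canal")
    if not masks["PTV"].any():
        problems.append("PTV is empty")
    filled = ndimage.binary_fill_holes(body)
    n_components = ndimage.label(body)[1]
    if n_components != 1 or np.any(filled & ~body):
        problems.append("body is not simply connected")
    # Laterality must match the PTV centroid's side of the midline; a
    # centroid within one voxel of the midline has no side and passes.
    xx, _ = phantom.coordinates()
    cx = float(xx[masks["PTV"]].mean()) if masks["PTV"].any() else 0.0
    expected = "left" if cx > 0 else "right"
    on_midline = abs(cx) <= max(phantom.spacing_mm)
    if masks["PTV"].any() and not on_midline and expected != phantom.laterality:
        problems.append(
            f"laterality {phantom.laterality!r} inconsistent with PTV centroid x={cx:.1f} mm"
        )
    return problems


def distance_to_structure_mm(phantom: Phantom, mask: np.ndarray) -> np.ndarray:
    """Euclidean distance (mm) from each voxel to the given structure."""
    return ndimage.distance_transform_edt(~mask, sampling=phantom.spacing_mm)


def derive_shells(
    phantom: Phantom, distances_mm=DEFAULT_SHELL_DISTANCES_MM
) -> DerivedStructures:
    """Build one-voxel-band shells at the given distances from the PTV.

    ``shell(d)`` contains the voxels whose Euclidean distance to the PTV
    lies in ``[d, d + voxel diagonal)``, clipped to the body.  The band
    width of one voxel diagonal is the smallest that guarantees a
    non-empty connected ring on a discrete grid.
    """
    sy, sx = phantom.spacing_mm
    min_spacing = min(sy, sx)
    diag = float(np.hypot(sy, sx))
    dist = distance_to_structure_mm(phantom, phantom.masks["PTV"])
    body = phantom.masks["body"]
    shells: dict[float, np.ndarray] = {}
    for d in distances_mm:
        if d < min_spacing:
            raise ValueError(
                f"shell distance {d} mm is below the voxel resolution {min_spacing} mm"
            )
        band = (dist >= d) & (dist < d + diag) & body
        if not band.any():
            logger.warning("shell at %.1f mm from the PTV is empty", d)
        shells[float(d)] = band
    return DerivedStructures(shells=shells)


def derive_external_ring(
    phantom: Phantom, depth_mm: float = 20.0, ptv_margin_mm: float = 40.0
) -> DerivedStructures:
    """Ring extending ``depth_mm`` inside the body surface, with the PTV
    dilated by ``ptv_margin_mm`` subtracted.

    Used by the wish-list to cap entrance doses.  Defaults follow the
    2 cm / PTV + 4 cm construction of the planning protocol.
    """
    body = phantom.masks["body"]
    depth = ndimage.distance_transform_edt(body, sampling=phantom.spacing_mm)
    near_surface = body & (depth <= depth_mm)
    ptv_dist = distance_to_structure_mm(phantom, phantom.masks["PTV"])
    ring = near_surface & ~(ptv_dist <= ptv_margin_mm)
    if not ring.any():
        logger.warning("external ring is empty (PTV dilation covers the body rim)")
    return DerivedStructures(external_ring=ring)


def derive_structures(
    phantom: Phantom, distances_mm=DEFAULT_SHELL_DISTANCES_MM
) -> DerivedStructures:
    """Shells and external ring in one container."""
    out = derive_shells(phantom, distances_mm)
    out.external_ring = derive_external_ring(phantom).external_ring
    return out


# ---------------------------------------------------------------------------
# Serialization

def save_phantom(path, phantom: Phantom) -> None:
    """Write a phantom to HDF5 (masks as uint8 datasets, metadata as attrs)."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("masks")
        for name, mask in phantom.masks.items():
            g.create_dataset(name, data=mask.astype(np.uint8), track_times=False)
        f.attrs["spacing_mm"] = phantom.spacing_mm
        f.attrs["laterality"] = phantom.laterality
        f.attrs["prescription_Gy"] = phantom.prescription_Gy


def load_phantom(path) -> Phantom:
    import h5py

    with h5py.File(path, "r") as f:
        masks = {name: f["masks"][name][...].astype(bool) for name in f["masks"]}
        shape = next(iter(masks.values())).shape
        return Phantom(
            grid_shape=tuple(shape),
            spacing_mm=tuple(float(v) for v in f.attrs["spacing_mm"]),
            masks=masks,
            laterality=str(f.attrs["laterality"]),
            prescription_Gy=float(f.attrs["prescription_Gy"]),
        )


def config_to_dict(config: PhantomConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    for key in (
        "grid_shape",
        "spacing_mm",
        "tumor_offset_mm",
        "body_semiaxes_mm",
        "lung_semiaxes_mm",
        "lung_offset_mm",
        "heart_center_mm",
        "heart_semiaxes_mm",
        "esophagus_center_mm",
        "canal_center_mm",
    ):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return PhantomConfig(**d)
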