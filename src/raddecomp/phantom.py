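"""Synthetic 3-D musculoskeletal phantoms and unpaired training datasets.

A phantom is an ellipsoidal body envelope containing high-attenuation
"bone" structures (a midline capsule plus mirrored pairs), bilateral
ellipsoidal "muscle" structures of moderate attenuation, and a residual
background channel covering the rest of the body.  Muscles are mirrored
left/right; on the affected side one semi-axis is scaled by the asymmetry
factor, so the analytic affected/unaffected volume ratio equals the factor
directly (V is proportional to a*b*c for an ellipsoid).  Every structure's
HU is uniform, which makes the average-AC-times-volume identity behind the
projection-domain volume ratio exact.

Placement uses a jittered slot lattice inside the left half of the body
(bones and muscles live in disjoint anterior/posterior bands), so the
default 3-bone / 19-muscle layout is placeable at 64^3 without overlap;
masks remain mutually exclusive by construction, with later structures
carved out of earlier masks as a safety net.

The dataset builder emulates the unpaired training condition: the noisy
composite radiograph of each case is rendered at a randomly perturbed pose
("standing X-ray"), while the per-structure DRRs use the unperturbed pose
("supine CT"), and one intensity normalization — computed from the training
split only — is shared by all cases.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .projection import (
    Normalization,
    ProjectionGeometry,
    RigidTransform,
    add_poisson_noise,
    default_geometry_for,
    render,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "StructureLabel",
    "VolumePhantom",
    "PlacementError",
    "NoiseConfig",
    "CaseRecord",
    "DatasetManifest",
    "generate_phantom",
    "perturb_pose",
    "build_dataset",
]

AIR_THRESHOLD_HU = -200.0
AIR_HU = -1000.0


class PlacementError(RuntimeError):
    """A structure could not be placed without overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    Defaults mirror the clinical layout the package emulates: 3 bones and
    19 muscles (23 channels including background).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    n_bones: int = 3
    n_muscles: int = 19
    bone_hu_range: tuple[float, float] = (400.0, 800.0)
    muscle_hu_range: tuple[float, float] = (40.0, 80.0)
    background_hu: float = -30.0
    asymmetry_factor: float = 1.0
    affected_side: str = "left"
    seed: int = 0

    def __post_init__(self):
        if min(self.grid_shape) <= 0 or min(self.spacing) <= 0:
            raise ValueError("grid_shape and spacing must be strictly positive")
        if not 0.0 < self.asymmetry_factor <= 1.0:
            raise ValueError("asymmetry_factor must be in (0, 1]")
        if not (self.bone_hu_range[0] > self.muscle_hu_range[1]
                and self.muscle_hu_range[0] > self.background_hu):
            raise ValueError("need bone HU > muscle HU > background HU")
        if self.n_bones < 1 or self.n_muscles < 1:
            raise ValueError("need n_bones >= 1 and n_muscles >= 1")
        if self.affected_side not in ("left", "right"):
            raise ValueError("affected_side must be 'left' or 'right'")

    @property
    def n_structures(self) -> int:
        """Foreground structure count K (bones + muscles)."""
        return self.n_bones + self.n_muscles

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "spacing": list(self.spacing),
            "n_bones": self.n_bones,
            "n_muscles": self.n_muscles,
            "bone_hu_range": list(self.bone_hu_range),
            "muscle_hu_range": list(self.muscle_hu_range),
            "background_hu": self.background_hu,
            "asymmetry_factor": self.asymmetry_factor,
            "affected_side": self.affected_side,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(
            grid_shape=tuple(d["grid_shape"]),
            spacing=tuple(d["spacing"]),
            n_bones=int(d["n_bones"]),
            n_muscles=int(d["n_muscles"]),
            bone_hu_range=tuple(d["bone_hu_range"]),
            muscle_hu_range=tuple(d["muscle_hu_range"]),
            background_hu=float(d["background_hu"]),
            asymmetry_factor=float(d["asymmetry_factor"]),
            affected_side=d["affected_side"],
            seed=int(d["seed"]),
        )


@dataclass(frozen=True)
class StructureLabel:
    name: str
    group: str  # bone | hip muscle | thigh muscle | background
    side: str  # left | right | midline | bilateral


@dataclass
class VolumePhantom:
    """HU volume plus K+1 mutually exclusive structure masks."""

    hu_volume: np.ndarray
    masks: list[np.ndarray]  # boolean, background last
    spacing: tuple[float, float, float]
    labels: list[StructureLabel]
    true_side_volumes: dict[str, dict[str, float]]  # name -> {left, right} mm^3
    affected_side: str
    structure_hu: dict[str, float]
    spec: PhantomSpec | None = None
    #: analytic geometry of the placed muscles: name -> dict with the
    #: unaffected-side semi-axes (mm) and centre, for exact-volume oracles
    structure_geometry: dict[str, dict] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.masks)

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def side_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean volumes selecting the left (x<0) and right (x>0) halves."""
        nx = self.hu_volume.shape[0]
        xc = np.arange(nx) - (nx - 1) / 2.0
        left = np.zeros(self.hu_volume.shape, dtype=bool)
        left[xc < 0] = True
        return left, ~left


# ------------------------------------------------------------------ geometry
def _centered_coords(shape, spacing):
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _capsule_mask(coords, center, radius, half_len) -> np.ndarray:
    """Capsule along z: cylinder of ``radius`` with hemispherical caps."""
    x, y, z = coords
    dz = np.clip(z - center[2], -half_len, half_len)
    return (
        (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2] - dz) ** 2
    ) <= radius**2


def _slot_grid(n_slots: int, extents) -> tuple[int, int, int]:
    """Near-isotropic factorization: split the axis with the largest cell."""
    counts = [1, 1, 1]
    while counts[0] * counts[1] * counts[2] < n_slots:
        cells = [e / c for e, c in zip(extents, counts)]
        counts[int(np.argmax(cells))] += 1
    return tuple(counts)


def generate_phantom(spec: PhantomSpec) -> VolumePhantom:
    """Deterministically generate a phantom from its spec.

    Raises :class:`PlacementError` if a structure cannot be placed without
    overlap within the bounded slot-jitter retries.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    spacing = spec.spacing
    coords = _centered_coords(shape, spacing)
    half_extent = np.array([n * s / 2.0 for n, s in zip(shape, spacing)])
    body_semi = half_extent * np.array([0.88, 0.85, 0.92])
    body = _ellipsoid_mask(coords, (0.0, 0.0, 0.0), body_semi)
    bx, by, bz = body_semi

    occupied = np.zeros(shape, dtype=bool)
    masks: list[np.ndarray] = []
    labels: list[StructureLabel] = []
    structure_hu: dict[str, float] = {}
    structure_geometry: dict[str, dict] = {}

    def _place(mask: np.ndarray, name: str) -> np.ndarray:
        nonlocal occupied
        mask = mask & body
        if not mask.any():
            raise PlacementError(f"structure {name!r} has no voxels inside the body")
        if (mask & occupied).any():
            raise PlacementError(f"structure {name!r} overlaps a previous structure")
        occupied |= mask
        return mask

    # ---- bones: posterior band, midline capsule + mirrored capsule pairs
    bone_y = -0.435 * by
    n_pairs = spec.n_bones // 2
    bone_idx = 0
    if spec.n_bones % 2:
        bone_idx += 1
        name = f"bone_{bone_idx:02d}"
        hu = float(rng.uniform(*spec.bone_hu_range))
        m = _capsule_mask(coords, (0.0, bone_y, 0.0), 0.11 * min(bx, by),
                          0.32 * bz)
        masks.append(_place(m, name))
        labels.append(StructureLabel(name, "bone", "midline"))
        structure_hu[name] = hu
    for p in range(n_pairs):
        z0 = (p - (n_pairs - 1) / 2.0) * (1.1 * bz / max(n_pairs, 1))
        cx = -0.32 * bx
        radius = 0.085 * min(bx, by)
        half_len = min(0.24 * bz, 0.45 * bz / n_pairs)
        hu = float(rng.uniform(*spec.bone_hu_range))
        for side, sign in (("left", -1.0), ("right", 1.0)):
            bone_idx += 1
            name = f"bone_{bone_idx:02d}"
            m = _capsule_mask(coords, (sign * abs(cx), bone_y, z0), radius,
                              half_len)
            masks.append(_place(m, name))
            labels.append(StructureLabel(name, "bone", side))
            structure_hu[name] = hu

    # ---- muscles: anterior band, jittered slot lattice on the left,
    #      mirrored to the right; affected side's third semi-axis scaled.
    inner = body_semi / np.sqrt(3.0) * 0.98  # inscribed-box half sizes
    region_lo = np.array([-inner[0], -0.25 * inner[1] * 2.0, -inner[2]])
    region_hi = np.array([-0.10 * bx, inner[1], inner[2]])
    region_lo[1] = -0.20 * inner[1]
    extents = region_hi - region_lo
    if np.any(extents <= 0):
        raise PlacementError("muscle placement region is empty")
    counts = _slot_grid(spec.n_muscles, extents)
    cell = extents / np.array(counts)
    slot_centers = [
        region_lo + (np.array([i, j, k]) + 0.5) * cell
        for i in range(counts[0])
        for j in range(counts[1])
        for k in range(counts[2])
    ]
    order = rng.permutation(len(slot_centers))[: spec.n_muscles]
    left_scale = spec.asymmetry_factor if spec.affected_side == "left" else 1.0
    right_scale = spec.asymmetry_factor if spec.affected_side == "right" else 1.0
    for mi in range(spec.n_muscles):
        name = f"muscle_{mi + 1:02d}"
        hu = float(rng.uniform(*spec.muscle_hu_range))
        slot = slot_centers[order[mi]]
        placed = None
        for _ in range(50):
            semi = cell / 2.0 * 0.85 * rng.uniform(0.70, 0.95, size=3)
            jitter = rng.uniform(-1.0, 1.0, size=3) * (cell / 2.0 - semi) * 0.8
            center = slot + jitter
            m_left = _ellipsoid_mask(
                coords, center, (semi[0], semi[1], semi[2] * left_scale)
            )
            m_right = _ellipsoid_mask(
                coords, (-center[0], center[1], center[2]),
                (semi[0], semi[1], semi[2] * right_scale),
            )
            m = m_left | m_right
            if not (m & occupied).any():
                placed = _place(m, name)
                break
        if placed is None:
            raise PlacementError(
                f"structure {name!r} could not be placed after bounded retries"
            )
        masks.append(placed)
        structure_geometry[name] = {
            "semi_axes_mm": [float(v) for v in semi],
            "center_mm": [float(v) for v in center],
        }
        group = "hip muscle" if slot[2] >= 0 else "thigh muscle"
        labels.append(StructureLabel(name, group, "bilateral"))
        structure_hu[name] = hu

    # ---- background: the rest of the body
    bg = body & ~occupied
    masks.append(bg)
    labels.append(StructureLabel("background", "background", "midline"))
    structure_hu["background"] = float(spec.background_hu)

    hu_volume = np.full(shape, AIR_HU)
    hu_volume[bg] = spec.background_hu
    for m, lab in zip(masks[:-1], labels[:-1]):
        hu_volume[m] = structure_hu[lab.name]

    voxvol = float(np.prod(spacing))
    nx = shape[0]
    left_sel = (np.arange(nx) - (nx - 1) / 2.0) < 0
    true_side_volumes = {}
    for m, lab in zip(masks, labels):
        vleft = float(m[left_sel].sum()) * voxvol
        vright = float(m[~left_sel].sum()) * voxvol
        true_side_volumes[lab.name] = {"left": vleft, "right": vright}

    return VolumePhantom(
        hu_volume=hu_volume,
        masks=masks,
        spacing=spacing,
        labels=labels,
        true_side_volumes=true_side_volumes,
        affected_side=spec.affected_side,
        structure_hu=structure_hu,
        spec=spec,
        structure_geometry=structure_geometry,
    )


def perturb_pose(
    phantom: VolumePhantom,
    rotation_deg: float | tuple[float, float, float],
    translation_mm: float | tuple[float, float, float],
    seed: int,
) -> RigidTransform:
    """Draw a rigid pose perturbation uniformly within symmetric bounds.

    Emulates the supine-CT vs standing-radiograph pose mismatch that makes
    the training data unpaired.  Zero bounds give the identity transform;
    the draw is deterministic for a fixed seed.
    """
    rot = np.broadcast_to(np.asarray(rotation_deg, dtype=float), (3,))
    tra = np.broadcast_to(np.asarray(translation_mm, dtype=float), (3,))
    if not (np.all(np.isfinite(rot)) and np.all(np.isfinite(tra))):
        raise ValueError("pose bounds must be finite")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(-rot, rot)
    shifts = rng.uniform(-tra, tra)
    return RigidTransform(tuple(angles), tuple(shifts))


# ------------------------------------------------------------------- dataset
@dataclass(frozen=True)
class NoiseConfig:
    """Quantum-noise settings for the simulated radiographs."""

    i0: float = 1e4  # photons per unexposed detector pixel
    enabled: bool = True


@dataclass
class CaseRecord:
    case_id: str
    split: str
    radiograph_path: str
    drrs_path: str
    pose_xray: RigidTransform
    pose_drr: RigidTransform
    labels: list[StructureLabel]
    true_side_volumes: dict
    structure_hu: dict
    affected_side: str
    asymmetry_factor: float

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "split": self.split,
            "radiograph_path": self.radiograph_path,
            "drrs_path": self.drrs_path,
            "pose_xray": self.pose_xray.to_dict(),
            "pose_drr": self.pose_drr.to_dict(),
            "labels": [
                {"name": l.name, "group": l.group, "side": l.side}
                for l in self.labels
            ],
            "true_side_volumes": self.true_side_volumes,
            "structure_hu": self.structure_hu,
            "affected_side": self.affected_side,
            "asymmetry_factor": self.asymmetry_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CaseRecord":
        return cls(
            case_id=d["case_id"],
            split=d["split"],
            radiograph_path=d["radiograph_path"],
            drrs_path=d["drrs_path"],
            pose_xray=RigidTransform.from_dict(d["pose_xray"]),
            pose_drr=RigidTransform.from_dict(d["pose_drr"]),
            labels=[StructureLabel(**l) for l in d["labels"]],
            true_side_volumes=d["true_side_volumes"],
            structure_hu=d["structure_hu"],
            affected_side=d["affected_side"],
            asymmetry_factor=d["asymmetry_factor"],
        )


@dataclass
class DatasetManifest:
    """Case records plus the dataset-wide normalization constants."""

    cases: list[CaseRecord]
    normalization: Normalization
    geometry: ProjectionGeometry
    seed: int
    root: str = "."

    def split(self, name: str) -> list[CaseRecord]:
        return [c for c in self.cases if c.split == name]

    def validate(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("case ids are not unique")
        root = Path(self.root)
        for c in self.cases:
            for p in (c.radiograph_path, c.drrs_path):
                if not (root / p).exists():
                    raise FileNotFoundError(root / p)

    def save(self, path) -> None:
        payload = {
            "cases": [c.to_dict() for c in self.cases],
            "normalization": self.normalization.to_dict(),
            "geometry": self.geometry.to_dict(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            cases=[CaseRecord.from_dict(c) for c in d["cases"]],
            normalization=Normalization.from_dict(d["normalization"]),
            geometry=ProjectionGeometry.from_dict(d["geometry"]),
            seed=int(d["seed"]),
            root=str(Path(path).parent),
        )

    def load_radiograph(self, case: CaseRecord) -> np.ndarray:
        import tifffile

        return tifffile.imread(Path(self.root) / case.radiograph_path).astype(
            np.float64
        )

    def load_drrs(self, case: CaseRecord) -> np.ndarray:
        import tifffile

        return tifffile.imread(Path(self.root) / case.drrs_path).astype(
            np.float64
        )


def _split_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    raw = {k: n * f for k, f in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    rem = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:rem]:
        counts[k] += 1
    return counts


def build_dataset(
    specs: list[PhantomSpec],
    out_dir,
    geometry: ProjectionGeometry | None = None,
    noise: NoiseConfig | None = NoiseConfig(),
    splits: dict[str, float] | None = None,
    seed: int = 0,
    pose_rotation_deg: float = 5.0,
    pose_translation_mm: float = 6.0,
) -> DatasetManifest:
    """Render an unpaired training dataset and write it under ``out_dir``.

    For each case the composite radiograph is rendered at a perturbed pose
    (with optional quantum noise) while the per-structure DRRs use the
    unperturbed pose.  The shared normalization is computed from the
    training split only (raw_min = 0, raw_max = the split's composite
    maximum).
    """
    import tifffile

    if len(specs) < 2:
        raise ValueError("need at least 2 cases")
    splits = splits or {"train": 0.5, "val": 0.25, "test": 0.25}
    counts = _split_counts(len(specs), splits)
    if counts.get("train", 0) == 0:
        raise ValueError("training split is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(specs))
    assignment: dict[int, str] = {}
    cursor = 0
    for split_name in splits:
        for i in order[cursor : cursor + counts[split_name]]:
            assignment[int(i)] = split_name
        cursor += counts[split_name]

    records: list[CaseRecord] = []
    train_max = 0.0
    for i, spec in enumerate(specs):
        phantom = generate_phantom(spec)
        geo = geometry or default_geometry_for(spec.grid_shape, spec.spacing)
        pose = perturb_pose(
            phantom, pose_rotation_deg, pose_translation_mm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        drrs, _ = render(phantom, geo)
        geo_xray = replace(geo, volume_pose=pose)
        _, radiograph = render(phantom, geo_xray)
        if noise is not None and noise.enabled:
            radiograph = add_poisson_noise(
                radiograph, noise.i0, seed=int(rng.integers(0, 2**31 - 1))
            )
        case_id = f"case_{i:03d}"
        case_dir = out / case_id
        case_dir.mkdir(exist_ok=True)
        rad_path = f"{case_id}/radiograph_raw.tif"
        drr_path = f"{case_id}/drrs_raw.tif"
        tifffile.imwrite(out / rad_path, radiograph.pixels.astype(np.float32))
        tifffile.imwrite(out / drr_path, drrs.channels.astype(np.float32),
                         photometric="minisblack")
        split_name = assignment[i]
        if split_name == "train":
            train_max = max(train_max, float(radiograph.pixels.max()),
                            float(drrs.channel_sum().max()))
        records.append(
            CaseRecord(
                case_id=case_id,
                split=split_name,
                radiograph_path=rad_path,
                drrs_path=drr_path,
                pose_xray=pose,
                pose_drr=RigidTransform(),
                labels=phantom.labels,
                true_side_volumes=phantom.true_side_volumes,
                structure_hu=phantom.structure_hu,
                affected_side=phantom.affected_side,
                asymmetry_factor=spec.asymmetry_factor,
            )
        )
    if train_max <= 0.0:
        raise ValueError("degenerate normalization range (max = min)")
    manifest = DatasetManifest(
        cases=records,
        normalization=Normalization(0.0, train_max),
        geometry=geometry or default_geometry_for(specs[0].grid_shape,
                                                  specs[0].spacing),
        seed=seed,
        root=str(out),
    )
    manifest.save(out / "manifest.json")
    return manifest
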