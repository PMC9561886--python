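"""Synthetic knee phantoms: a bright ACL-like tube spanning two footprint blobs.

Each phantom is a 3D volume containing two spherical "footprint" blobs
(femoral and tibial attachment sites) joined by a bright cylindrical tube of
the ligament's nominal dimensions (~38 mm long, ~11 mm wide), with a signal
gap — the rupture — at a controllable fractional position along the
femoral-to-tibial chord, plus additive Gaussian noise.  Ground truth
(rupture point, footprint centers, side class) is known by construction, so
every downstream stage can be trained and tested without patient data.

The default grid (64 x 64 x 32 voxels at 1 x 1 x 3 mm) mimics the anisotropy
of a sagittal T2 knee series (3 mm slices, finer in-plane resolution) while
staying small enough for CPU training.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from aclloc import classify as _classify
from aclloc.volio import Geometry, LabelMap, LandmarkGT, Volume, write_labelmap, write_volume

LABEL_NAMES = {0: "background", 1: "femoral_footprint", 2: "tibial_footprint", 3: "acl"}

# Side proportions of the study population (43 femoral / 35 middle / 7 tibial of 85).
DEFAULT_SIDE_FRACTIONS = (43 / 85, 35 / 85, 7 / 85)

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "make_dataset",
    "simulate_reader",
    "write_dataset",
    "LABEL_NAMES",
    "DEFAULT_SIDE_FRACTIONS",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Stated world of one phantom; lengths in mm, intensities in arbitrary units."""

    grid_shape: tuple = (64, 64, 32)
    spacing: tuple = (1.0, 1.0, 3.0)
    acl_length: float = 38.0
    acl_width: float = 11.0
    footprint_radius: float = 6.0
    rupture_fraction: float = 0.5
    gap_halfwidth: float = 2.5
    noise_sd: float = 0.05
    tube_intensity: float = 1.0
    footprint_intensity: float = 0.8
    background_intensity: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.rupture_fraction < 1.0:
            raise ValueError("rupture_fraction must lie strictly in (0, 1)")
        if not self.acl_length > 2 * self.gap_halfwidth > 0:
            raise ValueError("need acl_length > 2*gap_halfwidth > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be three positive counts")
        if len(self.spacing) != 3 or min(self.spacing) <= 0:
            raise ValueError("spacing must be three positive mm values")

    @property
    def physical_extent(self) -> np.ndarray:
        """Physical span of voxel centers (mm) per axis."""
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing, dtype=float)


@dataclass
class PhantomCase:
    volume: Volume
    labels: LabelMap
    gt: LandmarkGT
    case_id: str = "phantom"
    seed: int | None = None


def _voxel_center_grid(spec: PhantomSpec) -> np.ndarray:
    """(3, nx, ny, nz) physical coordinates of all voxel centers (origin 0, identity)."""
    axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij")).astype(float)


def _sample_chord(spec: PhantomSpec, rng: np.random.Generator):
    """Random chord of length acl_length fitting inside the grid with footprint margin.

    The ligament always runs obliquely from the femur (superior) down to the
    tibia, never inverted, so the chord keeps a substantial slice-axis
    component with the femoral end at higher z.  Without this anatomical
    asymmetry the two footprints would be indistinguishable and the
    femoral/tibial labels unlearnable.
    """
    ext = spec.physical_extent
    margin = spec.footprint_radius
    half = spec.acl_length / 2.0
    for _ in range(500):
        v = rng.normal(size=3)
        u = v / np.linalg.norm(v)
        if abs(u[2]) < 0.3:
            continue
        if u[2] > 0:  # femoral end (center - u*half) is the superior one
            u = -u
        lo = np.abs(u) * half + margin
        hi = ext - lo
        if np.all(hi > lo):
            center = np.array([rng.uniform(l, h) for l, h in zip(lo, hi)])
            return center - u * half, center + u * half, u
    raise ValueError("tube does not fit in grid: acl_length + footprint_radius too large")


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Generate one phantom case; deterministic for fixed (spec, seed)."""
    rng = np.random.default_rng(seed)
    femoral, tibial, u = _sample_chord(spec, rng)

    grid = _voxel_center_grid(spec)
    rel = grid - femoral.reshape(3, 1, 1, 1)
    axial = np.einsum("c,cxyz->xyz", u, rel)  # signed mm along the chord
    axial_clamped = np.clip(axial, 0.0, spec.acl_length)
    closest = femoral.reshape(3, 1, 1, 1) + u.reshape(3, 1, 1, 1) * axial_clamped
    radial = np.linalg.norm(grid - closest, axis=0)

    tube = radial <= spec.acl_width / 2.0
    fem_mask = np.linalg.norm(rel, axis=0) <= spec.footprint_radius
    tib_mask = np.linalg.norm(grid - tibial.reshape(3, 1, 1, 1), axis=0) <= spec.footprint_radius

    rupture_mm = spec.rupture_fraction * spec.acl_length
    gap = tube & (np.abs(axial - rupture_mm) <= spec.gap_halfwidth)

    data = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float32)
    data[tube] = spec.tube_intensity
    data[fem_mask] = spec.footprint_intensity
    data[tib_mask] = spec.footprint_intensity
    # the gap is carved last: a rupture near an insertion site must stay
    # visible even where the footprint blob overlaps the tube
    data[gap] = spec.background_intensity
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, spec.grid_shape).astype(np.float32)

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[tube] = 3
    labels[fem_mask] = 1
    labels[tib_mask] = 2
    for lab, name in ((1, "femoral"), (2, "tibial"), (3, "acl")):
        if not np.any(labels == lab):
            raise ValueError(f"empty {name} label region; tube does not fit the grid")

    geom = Geometry(spacing=np.asarray(spec.spacing, dtype=float), origin=np.zeros(3))
    rupture_point = femoral + u * rupture_mm
    axis = _classify.AclAxis(femoral_center=femoral, tibial_center=tibial)
    side = _classify.classify_side(_classify.project_fraction(rupture_point, axis)).value
    gt = LandmarkGT(
        rupture_point=rupture_point, femoral_center=femoral, tibial_center=tibial, side=side
    )
    return PhantomCase(
        volume=Volume(data=data, geometry=geom),
        labels=LabelMap(data=labels, geometry=geom, label_names=dict(LABEL_NAMES)),
        gt=gt,
        seed=seed,
    )


def make_dataset(
    n: int,
    spec: PhantomSpec,
    seed: int,
    fraction_per_side=DEFAULT_SIDE_FRACTIONS,
) -> list[PhantomCase]:
    """Generate ``n`` phantoms with side counts set by largest-remainder rounding.

    Each case's rupture fraction is drawn uniformly within its side's third of
    the footprint line.  Deterministic for fixed (n, spec, seed).
    """
    props = np.asarray(fraction_per_side, dtype=float)
    if props.shape != (3,) or abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
        raise ValueError("fraction_per_side must be 3 non-negative proportions summing to 1")
    n_nonzero = int(np.count_nonzero(props))
    if n < n_nonzero:
        raise ValueError(f"n={n} too small for {n_nonzero} nonzero side proportions")

    ideal = props * n
    counts = np.floor(ideal).astype(int)
    for idx in np.argsort(-(ideal - counts), kind="stable")[: n - counts.sum()]:
        counts[idx] += 1

    thirds = {"femoral": (0.0, 1 / 3), "middle": (1 / 3, 2 / 3), "tibial": (2 / 3, 1.0)}
    rng = np.random.default_rng(seed)
    sides = [s for s, c in zip(_classify.SIDES, counts) for _ in range(c)]
    rng.shuffle(sides)

    cases = []
    for i, side in enumerate(sides):
        lo, hi = thirds[side]
        while True:
            frac = rng.uniform(lo, hi)
            # uniform() can land exactly on the closed-left boundary; redraw so
            # the derived class always matches the intended side
            if _classify.classify_side(frac).value == side:
                break
        case_seed = int(rng.integers(2**31))
        case = generate_phantom(replace(spec, rupture_fraction=frac), case_seed)
        case.case_id = f"case_{i:03d}"
        cases.append(case)
    return cases


def simulate_reader(
    gt: LandmarkGT,
    bias,
    sd: float,
    patch_halfwidth: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a clinical reader's annotated patch centroid (physical mm).

    A reader places a small image patch where they believe the rupture is;
    its centroid is the true rupture point displaced by a systematic ``bias``
    plus isotropic Gaussian jitter of ``sd`` mm per axis.  ``patch_halfwidth``
    documents the patch scale; the centroid of a symmetric patch is its
    center, so it does not enter the arithmetic.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, sd, 3) if sd > 0 else np.zeros(3)
    return gt.rupture_point + np.asarray(bias, dtype=float) + jitter


def read_dataset(directory) -> list[PhantomCase]:
    """Load a dataset written by :func:`write_dataset` back into PhantomCases."""
    from aclloc.volio import read_labelmap, read_landmarks, read_volume

    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv in {directory}")
    rupture = {cid: (pt, side) for cid, pt, side in read_landmarks(directory / "landmarks.tsv")}
    femoral = {cid: pt for cid, pt, _ in read_landmarks(directory / "femoral_centers.tsv")}
    tibial = {cid: pt for cid, pt, _ in read_landmarks(directory / "tibial_centers.tsv")}
    cases = []
    with open(manifest, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        next(r)
        for case_id, seed, vol_name, lab_name, _side in r:
            point, side = rupture[case_id]
            gt = LandmarkGT(
                rupture_point=point,
                femoral_center=femoral[case_id],
                tibial_center=tibial[case_id],
                side=side,
            )
            cases.append(
                PhantomCase(
                    volume=read_volume(directory / vol_name),
                    labels=read_labelmap(directory / lab_name, LABEL_NAMES),
                    gt=gt,
                    case_id=case_id,
                    seed=int(seed),
                )
            )
    return cases


def write_dataset(cases, directory) -> None:
    """Write per-case NIfTI volumes/labels, a gt landmark TSV and a manifest TSV."""
    from aclloc.volio import write_landmarks

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    with open(directory / "manifest.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["case_id", "seed", "volume", "labels", "side"])
        for case in cases:
            vol_name = f"{case.case_id}_vol.nii.gz"
            lab_name = f"{case.case_id}_lab.nii.gz"
            write_volume(case.volume, directory / vol_name)
            write_labelmap(case.labels, directory / lab_name)
            w.writerow([case.case_id, case.seed, vol_name, lab_name, case.gt.side])
            rows.append((case.case_id, case.gt.rupture_point, case.gt.side))
    write_landmarks(rows, directory / "landmarks.tsv")
    write_landmarks(
        [(c.case_id, c.gt.femoral_center, None) for c in cases], directory / "femoral_centers.tsv"
    )
    write_landmarks(
        [(c.case_id, c.gt.tibial_center, None) for c in cases], directory / "tibial_centers.tsv"
    )
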