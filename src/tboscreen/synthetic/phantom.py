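"""Organoid image phantoms with voxel-level ground truth.

The phantom emulates a cleared, whole-mount immunostained tumor-forebrain
organoid imaged as a confocal stack: a spherical organoid sampled
anisotropically in z (a circle per plane whose radius varies with depth),
containing spherical tumor foci. Two fluorescence channels are rendered:

* tumor channel — ``tumor_intensity * (1 - k_T)`` inside tumor foci, plus a
  constant autofluorescence background everywhere inside the organoid;
* neuronal channel — ``neuronal_intensity * (1 - k_N)`` in the organoid
  outside the foci (the neuronal microenvironment), plus the same constant
  background inside the organoid.

Outside the organoid the noiseless image is exactly zero. Additive Gaussian
noise (clipped at zero) is applied to both channels. The kill fractions
``k_T`` and ``k_N`` are the simulation stand-ins for a drug's anti-tumor
effect and neuronal toxicity: they scale the respective marker intensities.

Every phantom returns a :class:`VoxelTruth` carrying the exact masks and the
noiseless channel sums, so downstream segmentation and summed-brightness
measurements can be tested by parameter recovery.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ..types import NEURONAL, TUMOR, ImageStack


class GeometryError(RuntimeError):
    """Raised when tumor foci cannot be placed inside the organoid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and treatment effect of one synthetic organoid.

    The defaults mirror the imaging setup the pipeline targets: 29 confocal
    planes per organoid, one tumor and one neuronal marker channel, and a
    treatment encoded as tumor/neuronal kill fractions.

    Parameters
    ----------
    n_planes
        Number of confocal planes (z samples).
    plane_shape
        (height, width) of each plane in pixels.
    organoid_radius
        Equatorial (in-plane) organoid radius in pixels. Along z the sphere
        is compressed so that it spans the full plane range, i.e. planes are
        thicker than pixels, as in real confocal stacks.
    n_tumor_foci, focus_radius_range, tumor_fraction
        Tumor foci are spheres (in the same anisotropic metric). When
        ``tumor_fraction`` is set, a common focus radius is derived from it
        so the foci occupy that fraction of the organoid volume; otherwise
        radii are drawn uniformly from ``focus_radius_range``.
    tumor_intensity, neuronal_intensity, background_intensity
        Marker and autofluorescence levels, arbitrary fluorescence units.
    noise_sd
        SD of additive Gaussian noise (clipped at zero), same units.
    k_T, k_N
        Fraction of tumor / neuronal marker signal removed by treatment.
    """

    n_planes: int = 29
    plane_shape: tuple[int, int] = (96, 96)
    organoid_radius: float = 36.0
    n_tumor_foci: int = 12
    focus_radius_range: tuple[float, float] = (5.0, 9.0)
    tumor_fraction: float | None = 0.12
    tumor_intensity: float = 200.0
    neuronal_intensity: float = 150.0
    background_intensity: float = 10.0
    noise_sd: float = 10.0
    k_T: float = 0.0
    k_N: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.k_T <= 1.0 and 0.0 <= self.k_N <= 1.0):
            raise ValueError("kill fractions k_T, k_N must lie in [0, 1]")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if min(self.tumor_intensity, self.neuronal_intensity,
               self.background_intensity, self.noise_sd) < 0:
            raise ValueError("intensities and noise_sd must be >= 0")
        if self.tumor_fraction is not None and not (0.0 <= self.tumor_fraction < 1.0):
            raise ValueError("tumor_fraction must be in [0, 1)")
        if self.focus_radius_range[0] > self.focus_radius_range[1]:
            raise ValueError("focus_radius_range must be (low, high)")

    def with_treatment(self, k_T: float, k_N: float, seed: int | None = None) -> "PhantomSpec":
        """Copy of this spec with treatment effect (and optionally seed) replaced."""
        if seed is None:
            return replace(self, k_T=k_T, k_N=k_N)
        return replace(self, k_T=k_T, k_N=k_N, seed=seed)


#: Reduced-size phantom used for large simulation campaigns (same intensities,
#: noise and tumor fraction as the default; ~4x fewer voxels).
SMALL_PHANTOM = PhantomSpec(
    n_planes=15, plane_shape=(64, 64), organoid_radius=24.0, n_tumor_foci=8
)


@dataclass
class VoxelTruth:
    """Ground truth for one phantom: exact masks and noiseless sums."""

    organoid_mask: np.ndarray
    tumor_mask: np.ndarray
    #: noiseless whole-volume sum per channel
    noiseless_sum: dict[str, float]
    #: noiseless tumor-channel sum restricted to the tumor mask
    noiseless_tumor_in_focus_sum: float
    #: noiseless neuronal-channel sum restricted to the organoid mask
    noiseless_neuronal_in_organoid_sum: float
    focus_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    focus_radii: np.ndarray = field(default_factory=lambda: np.empty(0))


def _scaled_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coordinates scaled so the organoid is a sphere of radius R.

    z is stretched by R / (n_planes / 2): a unit step between planes spans
    more physical distance than a pixel, and the organoid touches both the
    first and last plane.
    """
    nz = spec.n_planes
    h, w = spec.plane_shape
    r = spec.organoid_radius
    z_scale = r / (nz / 2.0)
    z = (np.arange(nz) - (nz - 1) / 2.0) * z_scale
    y = np.arange(h) - (h - 1) / 2.0
    x = np.arange(w) - (w - 1) / 2.0
    return z[:, None, None], y[None, :, None], x[None, None, :]


def _focus_radii(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.tumor_fraction is not None:
        # n * (r/R)^3 = tumor_fraction in the scaled (isotropic) metric
        r = spec.organoid_radius * (spec.tumor_fraction / spec.n_tumor_foci) ** (1 / 3)
        return np.full(spec.n_tumor_foci, r)
    lo, hi = spec.focus_radius_range
    return rng.uniform(lo, hi, size=spec.n_tumor_foci)


def _place_foci(
    spec: PhantomSpec, radii: np.ndarray, rng: np.random.Generator,
    max_tries: int = 500, restarts: int = 20,
) -> np.ndarray:
    """Sample non-overlapping focus centers fully inside the organoid sphere.

    Works in the scaled metric where the organoid is a ball of radius R.
    Rejection sampling with bounded retries; raises GeometryError when the
    requested foci cannot be packed.
    """
    big = spec.organoid_radius
    for _ in range(restarts):
        centers: list[np.ndarray] = []
        ok = True
        for r in sorted(radii, reverse=True):
            limit = big - r - 0.5  # half-voxel guard against discretization
            if limit <= 0:
                raise GeometryError(
                    f"focus radius {r:.1f} does not fit inside organoid radius {big:.1f}"
                )
            for _ in range(max_tries):
                c = rng.uniform(-limit, limit, size=3)
                if c @ c > limit**2:
                    continue
                if all(np.linalg.norm(c - p[:3]) >= r + p[3] for p in centers):
                    centers.append(np.append(c, r))
                    break
            else:
                ok = False
                break
        if ok:
            return np.array(centers) if centers else np.empty((0, 4))
    raise GeometryError(
        f"could not place {spec.n_tumor_foci} foci (radii {radii.round(1)}) "
        f"inside organoid of radius {big:.1f} after {restarts} restarts"
    )


def generate_organoid_stack(spec: PhantomSpec) -> tuple[ImageStack, VoxelTruth]:
    """Render one two-channel organoid phantom plus its ground truth.

    Deterministic given ``spec.seed``. Raises :class:`GeometryError` when the
    tumor foci cannot be placed inside the organoid.
    """
    rng = np.random.default_rng(spec.seed)
    z, y, x = _scaled_grid(spec)
    r2 = z**2 + y**2 + x**2
    organoid = r2 <= spec.organoid_radius**2

    radii = _focus_radii(spec, rng)
    if spec.n_tumor_foci > 0:
        placed = _place_foci(spec, radii, rng)
    else:
        placed = np.empty((0, 4))
    tumor = np.zeros_like(organoid)
    for cz, cy, cx, r in placed:
        tumor |= (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r**2
    tumor &= organoid  # analytic containment; enforced exactly on the grid

    tme = organoid & ~tumor
    tumor_ch = np.zeros(organoid.shape, dtype=np.float64)
    neuronal_ch = np.zeros_like(tumor_ch)
    tumor_ch[tumor] = spec.tumor_intensity * (1.0 - spec.k_T)
    tumor_ch[organoid] += spec.background_intensity
    neuronal_ch[tme] = spec.neuronal_intensity * (1.0 - spec.k_N)
    neuronal_ch[organoid] += spec.background_intensity

    truth = VoxelTruth(
        organoid_mask=organoid,
        tumor_mask=tumor,
        noiseless_sum={TUMOR: float(tumor_ch.sum()), NEURONAL: float(neuronal_ch.sum())},
        noiseless_tumor_in_focus_sum=float(tumor_ch[tumor].sum()),
        noiseless_neuronal_in_organoid_sum=float(neuronal_ch[organoid].sum()),
        focus_centers=placed[:, :3] if len(placed) else np.empty((0, 3)),
        focus_radii=placed[:, 3] if len(placed) else np.empty(0),
    )

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=tumor_ch.shape + (2,))
        voxels = np.stack([tumor_ch, neuronal_ch], axis=-1) + noise
        np.clip(voxels, 0.0, None, out=voxels)
    else:
        voxels = np.stack([tumor_ch, neuronal_ch], axis=-1)
    stack = ImageStack(voxels=voxels.astype(np.float32), channel_names=(TUMOR, NEURONAL))
    return stack, truth


# ---------------------------------------------------------------------------
# screen / dose-course datasets


@dataclass(frozen=True)
class DrugTruth:
    """Ground-truth effect of one treatment group (one drug, one dose)."""

    name: str
    k_T: float = 0.0
    k_N: float = 0.0
    dose: float | None = None
    n_organoids: int = 4
    control: bool = False


@dataclass
class ScreenTruthTable:
    """Per-drug ground truth for a synthetic screen.

    Exactly one entry must be flagged as the (DMSO-like) control.
    """

    drugs: Sequence[DrugTruth]

    def __post_init__(self) -> None:
        n_ctrl = sum(d.control for d in self.drugs)
        if n_ctrl != 1:
            raise ValueError(f"exactly one control condition required, found {n_ctrl}")
        if any(d.n_organoids < 1 for d in self.drugs):
            raise ValueError("n_organoids must be >= 1 for every group")

    @property
    def control(self) -> DrugTruth:
        return next(d for d in self.drugs if d.control)


def derive_seed(master_seed: int, *identifiers) -> int:
    """Stable per-object seed from a master seed and string-able identifiers.

    Hash-based (not order-of-generation), so parallel or partial generation
    yields identical per-well streams.
    """
    key = "\x1f".join([str(master_seed), *map(str, identifiers)]).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") & 0x7FFFFFFF


def _well_id(drug: DrugTruth, replicate: int) -> str:
    dose_part = "" if drug.dose is None else f"@{drug.dose:g}"
    return f"{drug.name}{dose_part}#{replicate}"


def screen_layout(truth: ScreenTruthTable) -> pd.DataFrame:
    """Plate-layout table: well_id, drug, dose, role, replicate."""
    rows = []
    for drug in truth.drugs:
        for rep in range(1, drug.n_organoids + 1):
            rows.append(
                {
                    "well_id": _well_id(drug, rep),
                    "drug": drug.name,
                    "dose": drug.dose,
                    "role": "control" if drug.control else "treated",
                    "replicate": rep,
                }
            )
    layout = pd.DataFrame(rows)
    if layout["well_id"].duplicated().any():
        dupes = layout.loc[layout["well_id"].duplicated(), "well_id"].tolist()
        raise ValueError(f"duplicate well ids: {dupes}")
    return layout


def generate_screen_dataset(
    truth: ScreenTruthTable, spec: PhantomSpec
) -> Iterator[tuple[str, ImageStack, VoxelTruth]]:
    """Yield (well_id, stack, voxel_truth) for every organoid in the screen.

    One phantom per organoid per treatment group; per-well seeds are derived
    by stable hashing of (master seed, well id), so generation order is
    irrelevant and the dataset is reproducible well by well. Streams stacks
    one at a time (a full screen does not fit comfortably in memory).
    """
    layout = screen_layout(truth)  # validates duplicates up front
    del layout
    for drug in truth.drugs:
        for rep in range(1, drug.n_organoids + 1):
            wid = _well_id(drug, rep)
            well_spec = spec.with_treatment(
                drug.k_T, drug.k_N, seed=derive_seed(spec.seed, wid)
            )
            stack, vtruth = generate_organoid_stack(well_spec)
            yield wid, stack, vtruth


def dose_truth_table(
    drug: str,
    doses: Sequence[float],
    k_T: Sequence[float],
    k_N: Sequence[float],
    n_organoids: int = 4,
    control_name: str = "DMSO",
) -> ScreenTruthTable:
    """Truth table for a dose course: one group per dose plus a dose-0 control."""
    if len(doses) != len(k_T) or len(doses) != len(k_N):
        raise ValueError("doses, k_T and k_N must have equal length")
    if sorted(doses) != list(doses) or len(set(doses)) != len(doses):
        raise ValueError("doses must be strictly increasing")
    groups = [DrugTruth(control_name, 0.0, 0.0, dose=0.0, n_organoids=n_organoids, control=True)]
    groups += [
        DrugTruth(drug, kt, kn, dose=d, n_organoids=n_organoids)
        for d, kt, kn in zip(doses, k_T, k_N)
    ]
    return ScreenTruthTable(groups)


def hill_kill(dose: np.ndarray | float, emax: float, ec50: float, hill: float = 2.0) -> np.ndarray:
    """Hill-shaped kill fraction, 0 at dose 0 rising to ``emax``."""
    d = np.asarray(dose, dtype=float)
    return emax * d**hill / (ec50**hill + d**hill)
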