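"""Synthetic 3D refractive-index tomograms of cells.

A phantom is a voxel grid of refractive-index (RI) values built from a
background medium and an ordered list of ellipsoidal compartments
(cytoplasm, nucleoplasm, nucleoli, sub-nucleolar shells).  Later
compartments overwrite earlier ones, so nested anatomy is expressed by
listing shells outside-in.  Voxel membership is decided by a
voxel-center test, which keeps ground-truth masks exact and makes the
phantoms usable as oracles for segmentation and volume quantification.

Conventions
-----------
* axis order is ``(z, y, x)``; coordinates are in micrometres measured
  from the grid corner; a voxel with index ``i`` has its center at
  ``(i + 0.5) * voxel_size``.
* RI values are dimensionless; live-cell tomograms fall in
  ``[1.30, 1.45]`` (medium ~1.337, cytoplasm/nucleoplasm ~1.349,
  nucleoli ~1.363).
* noise is additive i.i.d. Gaussian per voxel, seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

RI_MIN = 1.30
RI_MAX = 1.45

#: default anisotropic voxel size (dz, dy, dx) in um, matching the lateral /
#: axial optical resolution scale of a typical ODT instrument.
DEFAULT_VOXEL_SIZE = (0.356, 0.11, 0.11)

#: reference RI of standard culture medium (refractometer value).
DEFAULT_MEDIUM_RI = 1.337

#: mean RI reported for nucleoli vs cytoplasm/nucleoplasm under normal culture.
NUCLEOLUS_RI = 1.363
CYTOPLASM_RI = 1.349


@dataclass
class RITomogram:
    """A 3D refractive-index map plus acquisition metadata.

    Parameters
    ----------
    values
        3D array of RI per voxel, axis order ``(z, y, x)``.
    voxel_size
        ``(dz, dy, dx)`` in micrometres, all strictly positive.
    medium_ri
        Reference RI of the surrounding medium.
    masks
        Optional ground-truth boolean masks per compartment label
        (present on generated phantoms, absent on loaded data).
    """

    values: np.ndarray
    voxel_size: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    medium_ri: float = DEFAULT_MEDIUM_RI
    masks: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"tomogram must be 3D, got shape {self.values.shape}")
        if len(self.voxel_size) != 3 or any(d <= 0 for d in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        self.voxel_size = tuple(float(d) for d in self.voxel_size)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tomogram contains non-finite RI values")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < RI_MIN or hi > RI_MAX:
            raise ValueError(
                f"RI values outside physical range [{RI_MIN}, {RI_MAX}]: min={lo}, max={hi}"
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass(frozen=True)
class CompartmentSpec:
    """An ellipsoidal (or spherical) compartment painted at a target RI.

    ``center`` and ``semi_axes`` are ``(z, y, x)`` in micrometres from the
    grid corner.  A sphere is an ellipsoid with equal semi-axes; use
    :meth:`sphere` for convenience.
    """

    label: str
    center: Tuple[float, float, float]
    semi_axes: Tuple[float, float, float]
    ri: float

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        if not (RI_MIN <= self.ri <= RI_MAX):
            raise ValueError(f"compartment RI {self.ri} outside [{RI_MIN}, {RI_MAX}]")

    @classmethod
    def sphere(cls, label: str, center: Sequence[float], radius: float, ri: float) -> "CompartmentSpec":
        return cls(label=label, center=tuple(center), semi_axes=(radius, radius, radius), ri=ri)

    @property
    def radius(self) -> float:
        """Radius if spherical; raises otherwise."""
        a, b, c = self.semi_axes
        if not (a == b == c):
            raise ValueError("compartment is not a sphere")
        return a


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic tomogram.

    Compartments are painted in list order: a voxel's noiseless RI is the
    RI of the *last* compartment whose ellipsoid contains its center, or
    ``medium_ri`` if none does.
    """

    grid_shape: Tuple[int, int, int]
    voxel_size: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    medium_ri: float = DEFAULT_MEDIUM_RI
    compartments: Tuple[CompartmentSpec, ...] = field(default_factory=tuple)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive counts, got {self.grid_shape}")
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "compartments", tuple(self.compartments))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _center_coords(grid_shape, voxel_size):
    """Per-axis voxel-center coordinate vectors in um."""
    return [
        (np.arange(n, dtype=np.float64) + 0.5) * d
        for n, d in zip(grid_shape, voxel_size)
    ]


def _inside(comp: CompartmentSpec, coords) -> np.ndarray:
    """Boolean mask of voxels whose center lies inside the ellipsoid."""
    zz = ((coords[0] - comp.center[0]) / comp.semi_axes[0]) ** 2
    yy = ((coords[1] - comp.center[1]) / comp.semi_axes[1]) ** 2
    xx = ((coords[2] - comp.center[2]) / comp.semi_axes[2]) ** 2
    return (
        zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
    ) <= 1.0


def generate_phantom(spec: PhantomSpec) -> RITomogram:
    """Render a :class:`PhantomSpec` into an :class:`RITomogram`.

    Deterministic for a fixed ``spec.seed``.  The returned tomogram
    carries ground-truth masks: for each compartment label, the set of
    voxels whose final (post-overwrite) assignment is that label; masks
    of compartments sharing a label are unioned.
    """
    coords = _center_coords(spec.grid_shape, spec.voxel_size)
    values = np.full(spec.grid_shape, spec.medium_ri, dtype=np.float64)
    # owner[v] = index of last compartment containing voxel v, -1 = medium
    owner = np.full(spec.grid_shape, -1, dtype=np.int32)
    for i, comp in enumerate(spec.compartments):
        m = _inside(comp, coords)
        values[m] = comp.ri
        owner[m] = i

    masks: Dict[str, np.ndarray] = {}
    for i, comp in enumerate(spec.compartments):
        m = owner == i
        if comp.label in masks:
            masks[comp.label] |= m
        else:
            masks[comp.label] = m

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        # noise is small by construction; clip to the physical range so the
        # tomogram invariant cannot be violated by an extreme tail draw
        np.clip(values, RI_MIN, RI_MAX, out=values)

    return RITomogram(
        values=values.astype(np.float32),
        voxel_size=spec.voxel_size,
        medium_ri=spec.medium_ri,
        masks=masks,
    )


def five_nucleoli_spec(noise_sd: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Spec for the reference cell phantom: an ellipsoidal cell
    (cytoplasm, RI 1.349) containing a nucleus (nucleoplasm, same RI),
    five spherical nucleoli (RI 1.363) of diameter >= 2 um and one
    sub-threshold distractor sphere (diameter 1.5 um, same RI)."""
    cz, cy, cx = 8.5, 9.9, 9.9  # cell center, um
    comps = [
        CompartmentSpec("cytoplasm", (cz, cy, cx), (5.0, 9.0, 9.0), CYTOPLASM_RI),
        CompartmentSpec("nucleoplasm", (cz, cy, cx), (3.8, 6.0, 6.0), CYTOPLASM_RI),
    ]
    radii = (1.05, 1.15, 1.25, 1.35, 1.5)
    ring = 3.5
    for k, r in enumerate(radii):
        ang = 2.0 * np.pi * k / 5.0
        comps.append(
            CompartmentSpec.sphere(
                "nucleolus",
                (cz, cy + ring * np.sin(ang), cx + ring * np.cos(ang)),
                r,
                NUCLEOLUS_RI,
            )
        )
    comps.append(CompartmentSpec.sphere("distractor", (cz, cy, cx), 0.75, NUCLEOLUS_RI))
    return PhantomSpec(
        grid_shape=(48, 180, 180),
        voxel_size=DEFAULT_VOXEL_SIZE,
        medium_ri=DEFAULT_MEDIUM_RI,
        compartments=tuple(comps),
        noise_sd=noise_sd,
        seed=seed,
    )


def five_nucleoli_cell(seed: int = 0, noise_sd: float = 0.0) -> RITomogram:
    """Convenience fixture: render :func:`five_nucleoli_spec`.

    The nucleolus-RI voxel set forms six connected components (five true
    nucleoli plus the 1.5 um distractor); the >= 2 um size rule of
    nucleolus detection removes exactly the distractor.
    """
    return generate_phantom(five_nucleoli_spec(noise_sd=noise_sd, seed=seed))
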