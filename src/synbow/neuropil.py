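"""Synthetic neuropil: synapse geometry, connectivity, combinatorial labels.

Synapses in mammalian neuropil are small (150-300 nm) disk-shaped contacts
between axons and dendrites, scattered approximately uniformly at a density of
1-2 per cubic micron.  This module generates synthetic volumes that emulate
those statistics: a homogeneous Poisson point process of synapse centers,
truncated-exponential disk areas, random pre/post connectivity, stochastic
combinatorial ("Brainbow") fluorophore expression, and rasterization of the
labeled synaptic surfaces onto a voxel grid as per-channel surface-density
fields.

Units: all lengths are in micrometers (µm), areas in µm², densities in µm⁻³.
Voxel grids use 0-based indices, voxel centers at ``(i + 1/2) * voxel_size``,
and the half-open physical box ``[0, L)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VolumeSpec",
    "SynapseDisk",
    "SizeDistribution",
    "LabelAssignment",
    "SurfaceDensityField",
    "sample_synapse_centers",
    "sample_synapse_geometry",
    "assign_connectivity",
    "assign_brainbow_labels",
    "disk_surface_points",
    "rasterize_surfaces",
    "rasterize_synapse_map",
    "oblique_section_correction",
    "synapse_table",
    "synapse_table_from_csv",
    "label_table",
    "label_table_from_csv",
]

#: golden angle used for quasi-uniform ("sunflower") sampling of disk surfaces
_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeSpec:
    """A rectangular imaging volume with a regular voxel grid.

    Parameters
    ----------
    extents_um :
        Physical size (Lx, Ly, Lz) of the box in µm.
    voxel_size_um :
        Voxel edge lengths in µm (may be anisotropic, e.g. 0.008×0.008×0.05
        for typical serial-section EM geometry).
    """

    extents_um: tuple[float, float, float]
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self):
        ext = np.asarray(self.extents_um, dtype=float)
        vox = np.asarray(self.voxel_size_um, dtype=float)
        if ext.shape != (3,) or vox.shape != (3,):
            raise ValueError("extents and voxel size must be 3-vectors")
        if not (np.all(np.isfinite(ext)) and np.all(ext > 0)):
            raise ValueError(f"extents must be positive and finite, got {ext}")
        if not (np.all(np.isfinite(vox)) and np.all(vox > 0)):
            raise ValueError(f"voxel size must be positive and finite, got {vox}")
        if np.any(np.floor(ext / vox) < 1):
            raise ValueError("volume must contain at least one voxel per axis")
        object.__setattr__(self, "extents_um", tuple(ext))
        object.__setattr__(self, "voxel_size_um", tuple(vox))

    @property
    def shape(self) -> tuple[int, int, int]:
        """Number of voxels per axis, floor(extent / voxel size)."""
        ext = np.asarray(self.extents_um)
        vox = np.asarray(self.voxel_size_um)
        return tuple(int(n) for n in np.floor(ext / vox + 1e-9))

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.extents_um))

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    def voxel_of(self, points_um: np.ndarray) -> np.ndarray:
        """Map physical coordinates (N, 3) to voxel indices (N, 3), clipped
        to the grid so that boundary-touching points land in edge voxels."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        idx = np.floor(pts / np.asarray(self.voxel_size_um)).astype(np.int64)
        return np.clip(idx, 0, np.asarray(self.shape) - 1)


@dataclass
class SynapseDisk:
    """A disk-shaped synapse: flat contact between one axon and one dendrite.

    ``area`` is the contact area in µm² (a disk of diameter q has
    area π(q/2)²); ``normal`` is the unit normal of the disk plane.
    ``pre_neuron`` / ``post_neuron`` are integer ids into separate axon and
    dendrite pools (−1 when connectivity has not been assigned yet).
    """

    id: int
    center: np.ndarray
    normal: np.ndarray
    area: float
    pre_neuron: int = -1
    post_neuron: int = -1

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(self.normal)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"synapse normal must be a unit vector, |n|={norm}")
        if not self.area > 0:
            raise ValueError("synapse area must be positive")
        if self.pre_neuron >= 0 and self.pre_neuron == self.post_neuron:
            # pre pool (axons) and post pool (dendrites) are distinct
            # populations; equal ids are fine, equal *objects* are not — ids
            # index different pools, so no constraint is actually violated.
            pass

    @property
    def diameter(self) -> float:
        """Diameter q of the disk in µm."""
        return 2.0 * np.sqrt(self.area / np.pi)


@dataclass(frozen=True)
class SizeDistribution:
    """Truncated-exponential synapse-area distribution.

    Measured synapse areas are approximately exponential with most synapses
    below 0.05 µm².  ``mean_area_um2`` is the exponential scale; support is
    ``[min_area_um2 + Exp(scale)]`` truncated at ``max_area_um2``.
    """

    mean_area_um2: float = 0.05
    min_area_um2: float = 0.005
    max_area_um2: float = 0.4

    def __post_init__(self):
        if not 0 < self.min_area_um2 < self.mean_area_um2 < self.max_area_um2:
            raise ValueError("require 0 < min < mean < max synapse area")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        span = self.max_area_um2 - self.min_area_um2
        u = rng.random(n)
        # inverse CDF of exponential truncated to [0, span]
        tail = 1.0 - np.exp(-span / self.mean_area_um2)
        return self.min_area_um2 - self.mean_area_um2 * np.log1p(-u * tail)

    def pdf(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        span = self.max_area_um2 - self.min_area_um2
        norm = self.mean_area_um2 * (1.0 - np.exp(-span / self.mean_area_um2))
        out = np.exp(-(a - self.min_area_um2) / self.mean_area_um2) / norm
        out = np.where((a < self.min_area_um2) | (a > self.max_area_um2), 0.0, out)
        return out

    def cdf(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        span = self.max_area_um2 - self.min_area_um2
        tail = 1.0 - np.exp(-span / self.mean_area_um2)
        x = np.clip(a - self.min_area_um2, 0.0, span)
        return (1.0 - np.exp(-x / self.mean_area_um2)) / tail

    def mean(self) -> float:
        """Mean of the truncated distribution (numerical)."""
        a = np.linspace(self.min_area_um2, self.max_area_um2, 4001)
        return float(np.trapezoid(a * self.pdf(a), a))

    def second_moment(self) -> float:
        a = np.linspace(self.min_area_um2, self.max_area_um2, 4001)
        return float(np.trapezoid(a**2 * self.pdf(a), a))


@dataclass
class LabelAssignment:
    """Combinatorial fluorophore expression for the pre and post neuron pools.

    Channels ``0 .. n_channels-1`` are each exclusively pre-side (axonal) or
    post-side (dendritic).  ``pre_expression[i, k]`` is True when pre-neuron i
    expresses channel k (always False for post-side channels), and vice versa.
    Each (neuron, same-side channel) pair is an independent Bernoulli draw at
    the Brainbow expression frequency f.
    """

    n_channels: int
    side_of_channel: np.ndarray  # array of "pre"/"post" strings
    pre_expression: np.ndarray   # (n_pre, n_channels) bool
    post_expression: np.ndarray  # (n_post, n_channels) bool
    expression_frequency: float

    def __post_init__(self):
        pre_side = self.side_of_channel == "pre"
        if np.any(self.pre_expression[:, ~pre_side]) or np.any(
            self.post_expression[:, pre_side]
        ):
            raise ValueError("a channel may only be expressed on its own side")

    @property
    def pre_channels(self) -> np.ndarray:
        return np.flatnonzero(self.side_of_channel == "pre")

    @property
    def post_channels(self) -> np.ndarray:
        return np.flatnonzero(self.side_of_channel == "post")

    def channels_of(self, neuron: int, side: str) -> np.ndarray:
        mat = self.pre_expression if side == "pre" else self.post_expression
        return np.flatnonzero(mat[neuron])

    def pattern_of(self, synapse: SynapseDisk) -> frozenset[int]:
        """Full fluorophore pattern of a synapse: the union of its pre
        neuron's axonal channels and its post neuron's dendritic channels."""
        pre = self.channels_of(synapse.pre_neuron, "pre")
        post = self.channels_of(synapse.post_neuron, "post")
        return frozenset(int(k) for k in np.concatenate([pre, post]))

    def pattern_masks(self, synapses: Sequence[SynapseDisk]) -> np.ndarray:
        """Bitmask of each synapse's full pattern (uint32, bit k = channel k)."""
        if self.n_channels > 32:
            raise ValueError("bitmask patterns support at most 32 channels")
        bits = (1 << np.arange(self.n_channels, dtype=np.uint64))
        pre_codes = (self.pre_expression * bits).sum(axis=1).astype(np.uint64)
        post_codes = (self.post_expression * bits).sum(axis=1).astype(np.uint64)
        pre_ids = np.array([s.pre_neuron for s in synapses], dtype=np.int64)
        post_ids = np.array([s.post_neuron for s in synapses], dtype=np.int64)
        return pre_codes[pre_ids] | post_codes[post_ids]


@dataclass
class SurfaceDensityField:
    """Per-voxel synaptic surface area s(r) for one fluorophore channel.

    ``values`` holds µm² of labeled synaptic surface per voxel; ``provenance``
    is a sparse record of which synapse deposited area where, as parallel
    arrays of flat voxel indices, synapse ids, and deposited areas.
    """

    channel: int
    grid: VolumeSpec
    values: np.ndarray
    provenance_voxels: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    provenance_synapses: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    provenance_areas: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=float))

    def total_area(self) -> float:
        return float(self.values.sum())


# ---------------------------------------------------------------------------
# sampling operations
# ---------------------------------------------------------------------------

def sample_synapse_centers(
    vol: VolumeSpec, density_per_um3: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson point process of synapse centers.

    The count is Poisson(ρ·V) and the coordinates are i.i.d. uniform in the
    box; this is the uniform-random placement observed for synapses in
    neuropil at ρ = 1–2 µm⁻³.

    Returns an (N, 3) array of centers in µm.
    """
    if not np.isfinite(density_per_um3) or density_per_um3 < 0:
        raise ValueError(f"density must be finite and >= 0, got {density_per_um3}")
    rng = np.random.default_rng(seed)
    n = rng.poisson(density_per_um3 * vol.volume_um3)
    return rng.random((n, 3)) * np.asarray(vol.extents_um)


def _isotropic_normals(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_synapse_geometry(
    centers: np.ndarray,
    size_dist: SizeDistribution | None = None,
    orientation_model: str = "isotropic3d",
    seed: int | np.random.Generator = 0,
) -> list[SynapseDisk]:
    """Draw disk areas and orientations for a set of synapse centers.

    ``orientation_model`` is ``"isotropic3d"`` (normals uniform on the sphere)
    or ``"in_plane"`` (normals confined to the x–z plane, the single-plane
    geometry used for analytic cross-checks).
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    if len(centers) == 0:
        return []
    size_dist = size_dist or SizeDistribution()
    rng = np.random.default_rng(seed)
    areas = size_dist.sample(len(centers), rng)
    if orientation_model == "isotropic3d":
        normals = _isotropic_normals(len(centers), rng)
    elif orientation_model == "in_plane":
        theta = rng.random(len(centers)) * np.pi
        normals = np.stack(
            [np.sin(theta), np.zeros_like(theta), np.cos(theta)], axis=1)
    else:
        raise ValueError(f"unknown orientation model {orientation_model!r}")
    return [
        SynapseDisk(id=i, center=c, normal=n, area=float(a))
        for i, (c, n, a) in enumerate(zip(centers, normals, areas))
    ]


def assign_connectivity(
    synapses: Sequence[SynapseDisk],
    n_pre_neurons: int,
    n_post_neurons: int,
    seed: int | np.random.Generator = 0,
) -> list[SynapseDisk]:
    """Assign each synapse a pre (axon) and post (dendrite) neuron id,
    uniformly over the respective pools.  Mutates and returns the list."""
    if n_pre_neurons < 1 or n_post_neurons < 1:
        raise ValueError("need at least one neuron in each pool")
    rng = np.random.default_rng(seed)
    pre = rng.integers(0, n_pre_neurons, size=len(synapses))
    post = rng.integers(0, n_post_neurons, size=len(synapses))
    for s, i, j in zip(synapses, pre, post):
        s.pre_neuron = int(i)
        s.post_neuron = int(j)
    return list(synapses)


def assign_brainbow_labels(
    n_pre: int,
    n_post: int,
    n_channels_pre: int,
    n_channels_post: int,
    f: float = 0.5,
    seed: int | np.random.Generator = 0,
    ensure_nonempty: bool = False,
) -> LabelAssignment:
    """Stochastic combinatorial expression: each neuron expresses each
    same-side channel independently with probability f (Brainbow).

    With ``ensure_nonempty`` every neuron is forced to express at least one
    channel on its side (useful for capacity studies); by default empty codes
    occur with probability (1−f)^{N_c} and such synapse sides are unlabeled.
    """
    if not 0 <= f <= 1:
        raise ValueError("expression frequency f must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_channels = n_channels_pre + n_channels_post
    side = np.array(["pre"] * n_channels_pre + ["post"] * n_channels_post)
    pre_expr = np.zeros((n_pre, n_channels), dtype=bool)
    post_expr = np.zeros((n_post, n_channels), dtype=bool)
    pre_expr[:, :n_channels_pre] = rng.random((n_pre, n_channels_pre)) < f
    post_expr[:, n_channels_pre:] = rng.random((n_post, n_channels_post)) < f
    if ensure_nonempty and f > 0:
        for expr, cols in ((pre_expr, np.arange(n_channels_pre)),
                           (post_expr, np.arange(n_channels_pre, n_channels))):
            if len(cols) == 0:
                continue
            empty = ~expr[:, cols].any(axis=1)
            expr[np.flatnonzero(empty), rng.choice(cols, size=int(empty.sum()))] = True
    return LabelAssignment(
        n_channels=n_channels,
        side_of_channel=side,
        pre_expression=pre_expr,
        post_expression=post_expr,
        expression_frequency=float(f),
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def disk_surface_points(synapse: SynapseDisk, n_points: int = 100) -> np.ndarray:
    """Quasi-uniform points on the disk surface (sunflower layout), each
    carrying area/n_points.  Returns an (n_points, 3) array in µm."""
    n = synapse.normal
    # any vector not parallel to n
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    radius = synapse.diameter / 2.0
    k = np.arange(n_points)
    r = radius * np.sqrt((k + 0.5) / n_points)
    phi = k * _GOLDEN_ANGLE
    return (
        synapse.center[None, :]
        + r[:, None] * np.cos(phi)[:, None] * e1[None, :]
        + r[:, None] * np.sin(phi)[:, None] * e2[None, :]
    )


def _deposit(
    synapses: Sequence[SynapseDisk],
    vol: VolumeSpec,
    n_points: int,
    area_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize each disk to (flat voxel idx, synapse id, area) triples."""
    shape = np.asarray(vol.shape)
    ext = np.asarray(vol.extents_um)
    vox_list, syn_list, area_list = [], [], []
    n_clipped = 0
    for s in synapses:
        pts = disk_surface_points(s, n_points)
        outside = np.any((pts < 0) | (pts >= ext), axis=1)
        if outside.any():
            n_clipped += 1
            pts = np.clip(pts, 0.0, ext * (1 - 1e-12))
        ijk = vol.voxel_of(pts)
        flat = np.ravel_multi_index((ijk[:, 0], ijk[:, 1], ijk[:, 2]), tuple(shape))
        # merge duplicate voxels for this synapse
        uniq, inv = np.unique(flat, return_inverse=True)
        per_vox = np.bincount(inv) * (s.area * area_scale / n_points)
        vox_list.append(uniq)
        syn_list.append(np.full(len(uniq), s.id, dtype=np.int64))
        area_list.append(per_vox)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} synapse(s) extend outside the volume; "
            "surface points clipped to the boundary", stacklevel=3)
    if not vox_list:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy(), np.empty(0, dtype=float)
    return (
        np.concatenate(vox_list),
        np.concatenate(syn_list),
        np.concatenate(area_list),
    )


def rasterize_surfaces(
    synapses: Sequence[SynapseDisk],
    labels: LabelAssignment,
    vol: VolumeSpec,
    n_points: int = 100,
    area_scale: float = 1.0,
) -> list[SurfaceDensityField]:
    """Deposit each labeled synapse's surface area onto the voxel grid, one
    field per channel.

    Pre- and post-synaptic fluorophores are placed on the *same* surface (the
    synaptic cleft thickness, ~10–50 nm, is negligible at optical
    resolutions).  A channel's field receives a synapse's area iff the
    corresponding-side neuron expresses that channel.  ``area_scale`` applies
    a global multiplicative correction (e.g. the π/2 oblique-section factor
    when emulating EM slab markup conventions).
    """
    fields = []
    for k in range(labels.n_channels):
        side = labels.side_of_channel[k]
        if side == "pre":
            sel = [s for s in synapses if labels.pre_expression[s.pre_neuron, k]]
        else:
            sel = [s for s in synapses if labels.post_expression[s.post_neuron, k]]
        vox, syn, area = _deposit(sel, vol, n_points, area_scale)
        values = np.zeros(vol.shape, dtype=float)
        np.add.at(values.ravel(), vox, area)
        fields.append(
            SurfaceDensityField(
                channel=k, grid=vol, values=values,
                provenance_voxels=vox, provenance_synapses=syn,
                provenance_areas=area,
            )
        )
    return fields


def rasterize_synapse_map(
    synapses: Sequence[SynapseDisk],
    vol: VolumeSpec,
    n_points: int = 100,
    area_scale: float = 1.0,
) -> SurfaceDensityField:
    """Single pooled surface field of *all* synapses (label-free), with
    provenance; the input to explicit-resolvability analysis."""
    vox, syn, area = _deposit(synapses, vol, n_points, area_scale)
    values = np.zeros(vol.shape, dtype=float)
    np.add.at(values.ravel(), vox, area)
    return SurfaceDensityField(
        channel=-1, grid=vol, values=values,
        provenance_voxels=vox, provenance_synapses=syn, provenance_areas=area,
    )


def oblique_section_correction(angles: np.ndarray | str = "uniform") -> float:
    """Area correction factor 1 / E[cos θ] for slab-represented sections.

    In serial-section markup a synapse crossing a section at tilt θ from the
    sectioning axis is represented by a fixed-thickness vertical slab, so its
    true cross-section (thickness / cos θ) is under-represented by cos θ.
    With tilt uniform on [0, π/2) the mean correction is exactly π/2.

    Parameters
    ----------
    angles :
        Either the string ``"uniform"`` (θ ~ U[0, π/2), closed form π/2) or an
        array of tilt angles in radians.
    """
    if isinstance(angles, str):
        if angles != "uniform":
            raise ValueError(f"unknown angle model {angles!r}")
        return float(np.pi / 2.0)
    ang = np.asarray(angles, dtype=float)
    mean_cos = float(np.mean(np.cos(ang)))
    if mean_cos <= 1e-12:
        raise ValueError(
            "degenerate tilt distribution concentrated at 90 degrees: "
            "the correction factor diverges")
    return 1.0 / mean_cos


# ---------------------------------------------------------------------------
# tables (external interfaces)
# ---------------------------------------------------------------------------

def synapse_table(synapses: Iterable[SynapseDisk]) -> pd.DataFrame:
    """Ground-truth table: id, x_um, y_um, z_um, nx, ny, nz, area_um2,
    pre_id, post_id."""
    rows = [
        {
            "id": s.id,
            "x_um": s.center[0], "y_um": s.center[1], "z_um": s.center[2],
            "nx": s.normal[0], "ny": s.normal[1], "nz": s.normal[2],
            "area_um2": s.area,
            "pre_id": s.pre_neuron, "post_id": s.post_neuron,
        }
        for s in synapses
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "x_um", "y_um", "z_um", "nx", "ny", "nz",
                 "area_um2", "pre_id", "post_id"],
    )


def synapse_table_from_csv(path) -> list[SynapseDisk]:
    df = pd.read_csv(path)
    return [
        SynapseDisk(
            id=int(r.id),
            center=np.array([r.x_um, r.y_um, r.z_um]),
            normal=np.array([r.nx, r.ny, r.nz]) /
            np.linalg.norm([r.nx, r.ny, r.nz]),
            area=float(r.area_um2),
            pre_neuron=int(r.pre_id),
            post_neuron=int(r.post_id),
        )
        for r in df.itertuples()
    ]


def label_table(labels: LabelAssignment) -> pd.DataFrame:
    """Label table: neuron_id, side, channels (semicolon-separated)."""
    rows = []
    for side, mat in (("pre", labels.pre_expression),
                      ("post", labels.post_expression)):
        for i in range(mat.shape[0]):
            chans = np.flatnonzero(mat[i])
            rows.append({"neuron_id": i, "side": side,
                         "channels": ";".join(str(int(c)) for c in chans)})
    return pd.DataFrame(rows, columns=["neuron_id", "side", "channels"])


def label_table_from_csv(path, n_channels: int, side_of_channel: np.ndarray
                         ) -> LabelAssignment:
    df = pd.read_csv(path, keep_default_na=False)
    pre = df[df.side == "pre"]
    post = df[df.side == "post"]
    pre_expr = np.zeros((len(pre), n_channels), dtype=bool)
    post_expr = np.zeros((len(post), n_channels), dtype=bool)
    for mat, sub in ((pre_expr, pre), (post_expr, post)):
        for r in sub.itertuples():
            if str(r.channels):
                for c in str(r.channels).split(";"):
                    mat[int(r.neuron_id), int(c)] = True
    return LabelAssignment(
        n_channels=n_channels,
        side_of_channel=np.asarray(side_of_channel),
        pre_expression=pre_expr,
        post_expression=post_expr,
        expression_frequency=float("nan"),
    )
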