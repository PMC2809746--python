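"""Fluorescence image formation: molecule statistics, PSF blur, photon noise.

The photon count in a voxel is a double-Poisson process: fluorophore
molecules bind to synaptic surfaces in a Poisson process (with an extra
variance term from stochastic Brainbow expression), and each bound molecule
emits photons into the detector in a second Poisson process, spread over the
image by the microscope point spread function (PSF).  Both processes are
approximated by Normal distributions with matched mean and variance:

    molecules at surface element r (marginal over expression):
        mean  n̄(r)   = f · c · s(r)
        var   Var n  = f · c · s(r) + f(1−f) · c² · s(r)²
    (conditioned on an expressed label, drop f from the mean and the
    Bernoulli term from the variance)

    photons at voxel v from element r:
        mean  h · K(v−r) · n̄(r)
        var   h · K(v−r) · n̄(r) + (h · K(v−r))² · Var n(r)

summed over all elements r, assuming independent emission.  Here s(r) is the
synaptic surface area in the voxel (µm²), c the fluorophore surface
concentration (µm⁻²), f the Brainbow expression frequency, h the photon
budget (detected photons per molecule), and K the unit-sum PSF kernel.

A diffuse background of unbound fluorophore at b µM (1 µM = 602.2 molecules
per µm³) adds a uniform Poisson photon floor at the optical-voxel stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, special

from .neuropil import (
    LabelAssignment,
    SurfaceDensityField,
    SynapseDisk,
    VolumeSpec,
    disk_surface_points,
)

__all__ = [
    "PSFSpec",
    "OperatingPoint",
    "PhotonField",
    "MICROMOLAR_TO_PER_UM3",
    "molecule_count_stats",
    "make_psf_kernel",
    "photon_field",
    "downsample_optical",
    "optical_grid",
    "sample_realization",
    "SynapseContribution",
    "synapse_photon_contributions",
    "background_photon_stats",
    "write_channel_tiff",
]

#: 1 µM in molecules per µm³ (Avogadro: 1e-6 mol/L × 6.022e23 / 1e15 µm³/L)
MICROMOLAR_TO_PER_UM3 = 602.2

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class PSFSpec:
    """Gaussian PSF with lateral resolution d_xy and axial resolution d_z (µm).

    ``width_convention`` sets how the resolution figures map to the Gaussian:
    ``"fwhm"`` (default, σ = d/2.3548), ``"sigma"`` (σ = d) or ``"e2"``
    (d is the 1/e² diameter, σ = d/4).
    """

    d_xy_um: float
    d_z_um: float
    width_convention: str = "fwhm"
    truncation_sigma: float = 4.0

    def __post_init__(self):
        if self.d_xy_um <= 0 or self.d_z_um <= 0:
            raise ValueError("PSF resolutions must be positive")
        if self.width_convention not in ("fwhm", "sigma", "e2"):
            raise ValueError(f"unknown width convention {self.width_convention!r}")
        if self.truncation_sigma < 2.0:
            raise ValueError(
                "kernel truncation below 2 sigma discards too much light")

    def _sigma(self, d: float) -> float:
        if self.width_convention == "fwhm":
            return d * _FWHM_TO_SIGMA
        if self.width_convention == "sigma":
            return d
        return d / 4.0

    @property
    def sigma_um(self) -> tuple[float, float, float]:
        sx = self._sigma(self.d_xy_um)
        return (sx, sx, self._sigma(self.d_z_um))


@dataclass(frozen=True)
class OperatingPoint:
    """Experimental operating point of a labeling + imaging run.

    f — Brainbow expression frequency; c — fluorophore concentration on the
    synaptic surface (µm⁻²); b — diffuse background concentration (µM);
    h — photon budget (detected photons per fluorophore molecule).
    """

    f: float = 0.5
    c_per_um2: float = 750.0
    b_uM: float = 0.1
    h_photons: float = 1000.0

    def __post_init__(self):
        if not 0 <= self.f <= 1:
            raise ValueError("f must be in [0, 1]")
        if min(self.c_per_um2, self.b_uM, self.h_photons) < 0:
            raise ValueError("c, b, h must be non-negative")


@dataclass
class PhotonField:
    """Per-voxel photon-count statistics for one channel on a voxel grid."""

    channel: int
    grid: VolumeSpec
    mean: np.ndarray
    variance: np.ndarray
    realization: np.ndarray | None = None


# ---------------------------------------------------------------------------
# molecule statistics (the first Poisson stage)
# ---------------------------------------------------------------------------

def molecule_count_stats(
    surface: SurfaceDensityField,
    op: OperatingPoint,
    mode: str = "conditional",
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the bound-molecule count per voxel.

    ``mode="conditional"`` conditions on the label being expressed (mean
    c·s, Poisson variance c·s) — appropriate when expression has already been
    realized per neuron.  ``mode="marginal"`` marginalizes over the Bernoulli
    expression: mean f·c·s, variance f·c·s + f(1−f)·c²·s².
    """
    s = surface.values
    if np.any(s < 0):
        raise ValueError("surface density must be non-negative")
    c = op.c_per_um2
    if mode == "conditional":
        mean = c * s
        var = c * s
    elif mode == "marginal":
        f = op.f
        mean = f * c * s
        var = f * c * s + f * (1.0 - f) * (c * s) ** 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return mean, var


# ---------------------------------------------------------------------------
# PSF kernel and image formation (the second Poisson stage)
# ---------------------------------------------------------------------------

def make_psf_kernel(psf: PSFSpec, grid: VolumeSpec) -> np.ndarray:
    """Discrete separable anisotropic Gaussian kernel, normalized to unit sum.

    Unit sum makes h the total number of photons detected per molecule over
    the whole image.  Warns when the grid undersamples the PSF (voxel larger
    than d/2 along any axis).
    """
    vox = np.asarray(grid.voxel_size_um)
    d = np.array([psf.d_xy_um, psf.d_xy_um, psf.d_z_um])
    if np.any(vox > d / 2.0):
        warnings.warn(
            f"voxel size {tuple(vox)} undersamples the PSF (d = {tuple(d)})",
            stacklevel=2)
    sigma = np.asarray(psf.sigma_um)
    half = np.maximum(np.ceil(psf.truncation_sigma * sigma / vox).astype(int), 1)
    axes = []
    for ax in range(3):
        x = np.arange(-half[ax], half[ax] + 1) * vox[ax]
        g = np.exp(-0.5 * (x / sigma[ax]) ** 2)
        axes.append(g)
    kernel = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return kernel / kernel.sum()


def photon_field(
    mol_mean: np.ndarray,
    mol_var: np.ndarray,
    kernel: np.ndarray,
    op: OperatingPoint,
    grid: VolumeSpec,
    channel: int = 0,
    background: bool = False,
) -> PhotonField:
    """Blur molecule statistics into per-voxel photon statistics.

    mean(v) = h · (K ∗ n̄)(v);  var(v) = h · (K ∗ n̄)(v) + h² · (K² ∗ Var n)(v).
    With ``background`` a uniform Poisson floor of h·b·602.2·voxel-volume
    photons is added to both mean and variance (background is normally added
    after optical down-sampling; this flag adds it at the current grid).
    """
    if mol_mean.shape != tuple(grid.shape):
        raise ValueError(
            f"molecule field shape {mol_mean.shape} does not match grid "
            f"{grid.shape}")
    if abs(kernel.sum() - 1.0) > 1e-6:
        raise ValueError("PSF kernel must be normalized to unit sum")
    h = op.h_photons
    blurred_mean = signal.fftconvolve(mol_mean, kernel, mode="same")
    blurred_mean = np.clip(blurred_mean, 0.0, None)
    amplified = signal.fftconvolve(mol_var, kernel**2, mode="same")
    amplified = np.clip(amplified, 0.0, None)
    mean = h * blurred_mean
    var = h * blurred_mean + h**2 * amplified
    if background:
        bg = h * op.b_uM * MICROMOLAR_TO_PER_UM3 * grid.voxel_volume_um3
        mean = mean + bg
        var = var + bg
    return PhotonField(channel=channel, grid=grid, mean=mean, variance=var)


def optical_grid(
    vol: VolumeSpec, psf: PSFSpec, per_axis: bool = False
) -> VolumeSpec:
    """The analysis grid: optical voxels of size resolution/4.

    Default uses the best (smallest) of d_xy, d_z on all axes; ``per_axis``
    uses d_xy/4 laterally and d_z/4 axially.
    """
    if per_axis:
        v = (psf.d_xy_um / 4, psf.d_xy_um / 4, psf.d_z_um / 4)
    else:
        o = min(psf.d_xy_um, psf.d_z_um) / 4.0
        v = (o, o, o)
    return VolumeSpec(extents_um=vol.extents_um, voxel_size_um=v)


def downsample_optical(
    field: PhotonField, psf: PSFSpec, per_axis: bool = False
) -> PhotonField:
    """Aggregate photon statistics onto optical voxels (resolution/4).

    Photons are counts, so means and variances are *summed* over the
    constituent fine voxels; the source volume is zero-padded up to a
    multiple of the integer binning factor so totals are conserved.
    """
    src_vox = np.asarray(field.grid.voxel_size_um)
    tgt = optical_grid(field.grid, psf, per_axis=per_axis)
    tgt_vox = np.asarray(tgt.voxel_size_um)
    factors = np.round(tgt_vox / src_vox).astype(int)
    if np.any(factors < 1):
        raise ValueError(
            f"optical voxel {tuple(tgt_vox)} smaller than source voxel "
            f"{tuple(src_vox)}")
    if not np.allclose(factors * src_vox, tgt_vox, rtol=1e-6):
        warnings.warn(
            "optical voxel is not an integer multiple of the source voxel; "
            f"using factors {tuple(factors)}", stacklevel=2)

    def binsum(a: np.ndarray) -> np.ndarray:
        shp = np.asarray(a.shape)
        out_shape = -(-shp // factors)  # ceil
        pad = out_shape * factors - shp
        a = np.pad(a, [(0, int(p)) for p in pad])
        return (
            a.reshape(out_shape[0], factors[0], out_shape[1], factors[1],
                      out_shape[2], factors[2])
            .sum(axis=(1, 3, 5))
        )

    mean = binsum(field.mean)
    var = binsum(field.variance)
    out_shape = mean.shape
    eff_vox = factors * src_vox
    grid = VolumeSpec(
        extents_um=tuple(np.asarray(out_shape) * eff_vox),
        voxel_size_um=tuple(eff_vox),
    )
    return PhotonField(channel=field.channel, grid=grid, mean=mean, variance=var)


def sample_realization(
    field: PhotonField, seed: int | np.random.Generator, mode: str = "normal"
) -> np.ndarray:
    """Draw a noisy image: per-voxel independent Normal(mean, variance),
    clipped at zero.  ``mode="poisson"`` draws exact Poisson(mean) instead
    (appropriate for small counts, ignores over-dispersion)."""
    if np.any(field.variance < 0):
        raise ValueError("variance must be non-negative")
    rng = np.random.default_rng(seed)
    if mode == "normal":
        img = rng.normal(field.mean, np.sqrt(field.variance))
        img = np.clip(img, 0.0, None)
    elif mode == "poisson":
        img = rng.poisson(field.mean).astype(float)
    else:
        raise ValueError(f"unknown realization mode {mode!r}")
    field.realization = img
    return img


# ---------------------------------------------------------------------------
# analytic per-synapse contributions on the optical grid
# ---------------------------------------------------------------------------

@dataclass
class SynapseContribution:
    """Sparse photon-count statistics contributed by one synapse: parallel
    arrays of flat optical-voxel indices, mean photons, and photon variance
    (the per-source double-Poisson variance h·K·n̄ + (hK)²·Var n)."""

    synapse_id: int
    voxels: np.ndarray
    mean: np.ndarray
    variance: np.ndarray


def _axis_weights(pos: np.ndarray, lo: int, hi: int, vox: float, sigma: float
                  ) -> np.ndarray:
    """Fraction of a Gaussian centred at each pos landing in voxels lo..hi-1
    along one axis (voxel-integrated, via erf).  Shape (npoints, hi-lo)."""
    edges = np.arange(lo, hi + 1) * vox
    z = (edges[None, :] - pos[:, None]) / (sigma * np.sqrt(2.0))
    cdf = 0.5 * (1.0 + special.erf(z))
    return np.diff(cdf, axis=1)


def synapse_photon_contributions(
    synapses: Sequence[SynapseDisk],
    grid: VolumeSpec,
    psf: PSFSpec,
    op: OperatingPoint,
    n_points: int = 100,
    marginal: bool = False,
    min_mean_photons: float = 1e-3,
) -> list[SynapseContribution]:
    """Photon mean/variance each synapse contributes to optical voxels.

    Evaluates the Gaussian PSF analytically (voxel-integrated) around
    ``n_points`` quasi-uniform surface elements per disk, avoiding any
    fine-grid convolution; sub-voxel synapse placement is preserved exactly.
    Molecule statistics are conditional on expression by default (expression
    is realized per neuron upstream); ``marginal`` applies the f-marginal
    statistics instead.  Voxels receiving a mean below ``min_mean_photons``
    are dropped from the sparse output.
    """
    sigma = np.asarray(psf.sigma_um)
    vox = np.asarray(grid.voxel_size_um)
    shape = np.asarray(grid.shape)
    h = op.h_photons
    out = []
    for s in synapses:
        pts = disk_surface_points(s, n_points)
        area_per_pt = s.area / n_points
        lam = op.c_per_um2 * area_per_pt  # molecules per surface point
        lo = np.maximum(
            np.floor((pts.min(axis=0) - psf.truncation_sigma * sigma) / vox
                     ).astype(int), 0)
        hi = np.minimum(
            np.ceil((pts.max(axis=0) + psf.truncation_sigma * sigma) / vox
                    ).astype(int), shape)
        if np.any(hi <= lo):
            out.append(SynapseContribution(
                s.id, np.empty(0, np.int64), np.empty(0), np.empty(0)))
            continue
        wx = _axis_weights(pts[:, 0], lo[0], hi[0], vox[0], sigma[0])
        wy = _axis_weights(pts[:, 1], lo[1], hi[1], vox[1], sigma[1])
        wz = _axis_weights(pts[:, 2], lo[2], hi[2], vox[2], sigma[2])
        # photon fraction of each surface point landing in each local voxel,
        # summed over points (frac) and summed squared (frac2)
        frac = np.einsum("pi,pj,pk->ijk", wx, wy, wz)
        frac2 = np.einsum("pi,pj,pk->ijk", wx**2, wy**2, wz**2)
        mean_cond = h * lam * frac
        var_cond = mean_cond + h**2 * lam * frac2  # double-Poisson, per point
        if marginal:
            # expression is one shared Bernoulli(f) for the whole synapse:
            # the Brainbow term couples all surface points coherently
            f = op.f
            mean = f * mean_cond
            var = f * var_cond + f * (1.0 - f) * mean_cond**2
        else:
            mean = mean_cond
            var = var_cond
        keep = mean.ravel() > min_mean_photons
        local_idx = np.flatnonzero(keep)
        li, lj, lk = np.unravel_index(local_idx, frac.shape)
        flat = np.ravel_multi_index(
            (li + lo[0], lj + lo[1], lk + lo[2]), tuple(shape))
        out.append(SynapseContribution(
            s.id, flat.astype(np.int64), mean.ravel()[keep], var.ravel()[keep]))
    return out


def background_photon_stats(op: OperatingPoint, grid: VolumeSpec
                            ) -> tuple[float, float]:
    """Uniform diffuse-background photon mean and variance per optical voxel
    (Poisson: variance = mean = h · b · 602.2 µm⁻³ · voxel volume)."""
    bg = op.h_photons * op.b_uM * MICROMOLAR_TO_PER_UM3 * grid.voxel_volume_um3
    return bg, bg


# ---------------------------------------------------------------------------
# TIFF output
# ---------------------------------------------------------------------------

def write_channel_tiff(field: PhotonField, path, sidecar: dict | None = None):
    """Write a channel as a 32-bit float TIFF stack with layers (mean,
    variance[, realization]) × z, plus a JSON sidecar with grid metadata."""
    import tifffile

    layers = [field.mean, field.variance]
    if field.realization is not None:
        layers.append(field.realization)
    stack = np.stack(layers).astype(np.float32)
    tifffile.imwrite(str(path), stack)
    meta = {
        "channel": field.channel,
        "extents_um": list(field.grid.extents_um),
        "voxel_size_um": list(field.grid.voxel_size_um),
        "layers": ["mean", "variance"] + (
            ["realization"] if field.realization is not None else []),
    }
    if sidecar:
        meta.update(sidecar)
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)
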