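"""Analytic predictions: resolvability, detection error rates, code capacity.

Resolvability.  For point-like ("spherical") synapses scattered as a Poisson
process at density ρ, two synapses blend when their center separation falls
inside the resolution ellipsoid (Δxy/d_xy)² + (Δz/d_z)² < 1, so the fraction
of synapses that cannot be isolated is 1 − exp(−ρV) with the excluded volume
V = (4π/3)·d_xy²·d_z.  For disk-shaped synapses of diameter q the excluded
volume is computed by integrating, over relative lateral/axial offsets (R, Z),
the fraction f(R, Z) of orientation pairs whose surfaces approach within the
resolution limit; the closest approach of two tilted synapses (modeled as
length-q segments rotating in the plane containing the optical axis) is a
box-constrained quadratic program solved exactly.

Error model.  Detecting one fluorophore on a synapse of area a against the
blended fluorescence of its neighbors is a two-hypothesis Normal decision
problem: signal step a·c, variance a·c + A(d)·c + E(d)·c² (Poisson binding on
the target, Poisson binding on neighbors within the resolution limit with
mean area A(d), and Brainbow expression fluctuations of that area with
variance E(d)).  With the decision threshold midway the error per synapse is
the two-tailed Normal tail 2Φ(−SNR/2), averaged over the synapse-size
distribution.  In the low-concentration regime SNR ≈ √(a·c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .neuropil import SizeDistribution

__all__ = [
    "ResolvabilityModel",
    "ErrorModelInputs",
    "p_unresolved_spherical",
    "p_resolved_spherical",
    "segment_min_distance",
    "f_RZ",
    "f_RZ_monte_carlo",
    "excluded_volume_disk",
    "p_unresolved_disk",
    "resolvability_curve",
    "snr_poisson",
    "neighbor_area_stats",
    "error_rate_analytic",
    "min_detectable_area",
    "effective_concentration",
    "code_capacity",
    "channels_required",
    "fluorophore_surface_density",
]


@dataclass(frozen=True)
class ResolvabilityModel:
    """Parameters of the excluded-volume resolvability calculation."""

    density_per_um3: float
    d_xy_um: float
    d_z_um: float
    q_um: float = 0.25
    exclusion_scale: float = 1.0

    def __post_init__(self):
        if min(self.density_per_um3, self.d_xy_um, self.d_z_um, self.q_um) <= 0:
            raise ValueError("all model parameters must be positive")
        if self.q_um >= 1.0:
            raise ValueError("synapse diameter must be below 1 µm")


# ---------------------------------------------------------------------------
# spherical (point-synapse) model
# ---------------------------------------------------------------------------

def p_unresolved_spherical(
    rho: float, d_xy: float, d_z: float | None = None,
    exclusion_scale: float = 1.0,
) -> float:
    """Probability that a synapse has a neighbor inside its resolution
    ellipsoid: 1 − exp(−ρ·(4π/3)·(s·d_xy)²·(s·d_z)).

    ``exclusion_scale`` rescales the exclusion radii (e.g. 2, or (d+q)/d to
    fold in the synapse extent); the default uses the resolution itself.
    """
    if rho < 0 or d_xy <= 0:
        raise ValueError("require rho >= 0 and positive resolutions")
    d_z = d_xy if d_z is None else d_z
    s = exclusion_scale
    v = (4.0 * np.pi / 3.0) * (s * d_xy) ** 2 * (s * d_z)
    return float(1.0 - np.exp(-rho * v))


def p_resolved_spherical(rho, d_xy, d_z=None, exclusion_scale=1.0) -> float:
    return 1.0 - p_unresolved_spherical(rho, d_xy, d_z, exclusion_scale)


# ---------------------------------------------------------------------------
# disk (segment) model: quadratic program + orientation quadrature
# ---------------------------------------------------------------------------

def segment_min_distance(
    R, Z, theta, theta_p, q: float, d_xy: float = 1.0, d_z: float = 1.0
) -> np.ndarray:
    """Minimal (optionally anisotropically scaled) distance between two
    length-q segments in the lateral/axial plane.

    Segment 1 is centred at the origin with orientation θ from the optical
    axis, segment 2 at (R, Z) with orientation θ′.  The squared scaled
    distance ((Δx/d_xy)² + (Δz/d_z)²) is a convex quadratic in the two
    arc-length parameters τ, τ′ ∈ [−q/2, q/2]; the box-constrained minimum is
    found exactly from the interior critical point and the four clamped
    edges.  Broadcasts over array arguments.
    """
    R, Z, theta, theta_p = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (R, Z, theta, theta_p)))
    half = q / 2.0
    # direction vectors in the (lateral, axial) plane, metric-scaled
    ax, az = np.sin(theta) / d_xy, np.cos(theta) / d_z
    bx, bz = -np.sin(theta_p) / d_xy, -np.cos(theta_p) / d_z
    cx, cz = -R / d_xy, -Z / d_z
    # minimize |tau*a + tau_p*b + c|^2 over the box
    aa = ax * ax + az * az
    bb = bx * bx + bz * bz
    ab = ax * bx + az * bz
    ac = ax * cx + az * cz
    bc = bx * cx + bz * cz

    def value(tau, tau_p):
        dx = tau * ax + tau_p * bx + cx
        dz_ = tau * az + tau_p * bz + cz
        return dx * dx + dz_ * dz_

    best = np.full(R.shape, np.inf)
    # interior critical point (where the 2x2 system is non-singular)
    det = aa * bb - ab * ab
    with np.errstate(divide="ignore", invalid="ignore"):
        tau0 = (-ac * bb + bc * ab) / det
        tau0_p = (-bc * aa + ac * ab) / det
    ok = (np.abs(det) > 1e-14) & (np.abs(tau0) <= half) & (np.abs(tau0_p) <= half)
    if np.any(ok):
        v = value(np.where(ok, tau0, 0.0), np.where(ok, tau0_p, 0.0))
        best = np.where(ok, v, best)
    # four edges, 1-D minimization clamped to the box
    with np.errstate(divide="ignore", invalid="ignore"):
        for tau in (-half, half):
            tp = np.clip(np.where(bb > 0, -(bc + tau * ab) / bb, 0.0),
                         -half, half)
            best = np.minimum(best, value(tau, tp))
        for tau_p in (-half, half):
            t = np.clip(np.where(aa > 0, -(ac + tau_p * ab) / aa, 0.0),
                        -half, half)
            best = np.minimum(best, value(t, tau_p))
    return np.sqrt(best)


def f_RZ(
    R: float, Z: float, q: float, d_xy: float, d_z: float,
    n_theta: int = 64, check_convergence: bool = False, tol: float = 1e-3,
) -> float:
    """Fraction of orientation pairs (θ, θ′ uniform on [0, π)) at relative
    position (R, Z) whose surfaces approach within the resolution limit
    (scaled distance < 1) — the unresolvable fraction for the single-plane
    segment model."""
    if R < 0 or Z < 0:
        raise ValueError("R and Z must be non-negative")

    def estimate(n):
        th = (np.arange(n) + 0.5) * np.pi / n
        t1, t2 = np.meshgrid(th, th, indexing="ij")
        d = segment_min_distance(R, Z, t1, t2, q, d_xy, d_z)
        return float(np.mean(d < 1.0))

    val = estimate(n_theta)
    if check_convergence:
        val2 = estimate(2 * n_theta)
        if abs(val2 - val) > tol:
            val3 = estimate(4 * n_theta)
            if abs(val3 - val2) > tol:
                warnings.warn(
                    f"f_RZ quadrature not converged at (R={R}, Z={Z}): "
                    f"change {abs(val3 - val2):.2e} > {tol}", stacklevel=2)
            return val3
        return val2
    return val


def f_RZ_monte_carlo(
    R, Z, q, d_xy, d_z, n_samples: int = 100_000, seed: int = 0
) -> float:
    """Monte Carlo oracle for :func:`f_RZ`: random orientation pairs."""
    rng = np.random.default_rng(seed)
    t1 = rng.random(n_samples) * np.pi
    t2 = rng.random(n_samples) * np.pi
    d = segment_min_distance(R, Z, t1, t2, q, d_xy, d_z)
    return float(np.mean(d < 1.0))


def excluded_volume_disk(
    q: float, d_xy: float, d_z: float,
    n_r: int = 40, n_z: int = 40, n_theta: int = 48,
) -> float:
    """Excluded volume for the disk model: V = 2·∫∫ f(R,Z)·2πR dR dZ over
    the lateral/axial quarter-plane (the factor 2 covers both axial
    half-spaces; f is symmetric in ±Z)."""
    r_max = d_xy + q
    z_max = d_z + q
    rs = np.linspace(0.0, r_max, n_r)
    zs = np.linspace(0.0, z_max, n_z)
    th = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    t1, t2 = np.meshgrid(th, th, indexing="ij")
    fvals = np.empty((n_r, n_z))
    for i, r in enumerate(rs):
        for j, z in enumerate(zs):
            d = segment_min_distance(r, z, t1, t2, q, d_xy, d_z)
            fvals[i, j] = np.mean(d < 1.0)
    inner = np.trapezoid(fvals * 2.0 * np.pi * rs[:, None], rs, axis=0)
    return float(2.0 * np.trapezoid(inner, zs))


def p_unresolved_disk(
    rho: float, q: float, d_xy: float, d_z: float | None = None, **quad_kwargs
) -> float:
    """Unresolved fraction for disk-shaped synapses: 1 − exp(−ρV) with the
    orientation-integrated excluded volume.  As q → 0 this recovers the
    spherical model; elongated shapes reduce the excluded volume, so the
    result is sandwiched between the spherical values at radii d and d+q."""
    if min(rho, q, d_xy) <= 0:
        raise ValueError("require positive rho, q, d_xy")
    d_z = d_xy if d_z is None else d_z
    v = excluded_volume_disk(q, d_xy, d_z, **quad_kwargs)
    return float(1.0 - np.exp(-rho * v))


def resolvability_curve(
    resolutions_um, rho: float, model: str = "spherical",
    q: float = 0.25, anisotropy: float = 1.0, **kwargs
) -> pd.DataFrame:
    """Tabulated unresolved fraction vs isotropic-equivalent resolution.

    ``anisotropy`` multiplies the axial resolution (d_z = anisotropy · d_xy).
    """
    rows = []
    for d in resolutions_um:
        dz = d * anisotropy
        if model == "spherical":
            p = p_unresolved_spherical(rho, d, dz)
        elif model == "disk":
            p = p_unresolved_disk(rho, q, d, dz, **kwargs)
        else:
            raise ValueError(f"unknown model {model!r}")
        rows.append({"d_xy_um": d, "d_z_um": dz, "p_unresolved": p,
                     "p_resolved": 1.0 - p, "model": model, "rho": rho})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# detection error model
# ---------------------------------------------------------------------------

def snr_poisson(a: float, c: float) -> float:
    """Poisson-limited SNR √(a·c) for a synapse of area a (µm²) binding an
    expected a·c fluorophore molecules at surface concentration c (µm⁻²)."""
    if a < 0 or c < 0:
        raise ValueError("area and concentration must be non-negative")
    return float(np.sqrt(a * c))


def neighbor_area_stats(
    rho: float, d_xy: float, d_z: float | None = None,
    size_dist: SizeDistribution | None = None, f: float = 0.5,
    exclusion_scale: float = 1.0,
) -> tuple[float, float]:
    """Mean A(d) and variance E(d) of the labeled synaptic area within the
    resolution ellipsoid, from the synapse density and size distribution.

    Neighbors form a Poisson process thinned by the expression frequency f,
    so the total co-labeled area has compound-Poisson moments
    A = ρVf·E[a] (µm²) and E = ρVf·E[a²] (µm⁴).
    """
    d_z = d_xy if d_z is None else d_z
    sd = size_dist or SizeDistribution()
    s = exclusion_scale
    v = (4.0 * np.pi / 3.0) * (s * d_xy) ** 2 * (s * d_z)
    lam = rho * v * f
    return lam * sd.mean(), lam * sd.second_moment()


@dataclass(frozen=True)
class ErrorModelInputs:
    """Inputs to the analytic error-rate model.

    Either ``size_dist`` (average over the synapse-size CDF) or ``area_um2``
    (a single synapse size) must be given.  ``A_um2`` / ``E_um4`` are the
    mean and variance of the nearby co-labeled synaptic area within the
    resolution limit; ``gradations`` K > 2 models reading an expression
    *level* out of K steps instead of binary presence.
    """

    c_per_um2: float
    A_um2: float = 0.0
    E_um4: float = 0.0
    size_dist: SizeDistribution | None = None
    area_um2: float | None = None
    h_photons: float = float("inf")
    gradations: int = 2

    def __post_init__(self):
        if self.c_per_um2 < 0 or self.A_um2 < 0 or self.E_um4 < 0:
            raise ValueError("c, A, E must be non-negative")
        if (self.size_dist is None) == (self.area_um2 is None):
            raise ValueError("give exactly one of size_dist or area_um2")


def _error_prob(a, inputs: ErrorModelInputs, shot_noise: bool) -> np.ndarray:
    c = inputs.c_per_um2
    step = a * c / (inputs.gradations - 1)
    var = a * c + inputs.A_um2 * c + inputs.E_um4 * c**2
    if shot_noise and np.isfinite(inputs.h_photons):
        var = var + (a + inputs.A_um2) * c / inputs.h_photons
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(var > 0, step / np.sqrt(var), np.inf)
    return 2.0 * norm.sf(snr / 2.0)


def error_rate_analytic(
    inputs: ErrorModelInputs, shot_noise: bool = False
) -> float:
    """Expected errors per true synapse for detecting one fluorophore.

    Two-hypothesis Normal decision with the threshold midway between the
    absent and present mean signals: per-synapse error 2Φ(−SNR/2) with
    SNR = a·c / √(a·c + A·c + E·c²), averaged over the size distribution.
    Decreases with c; increases with the neighbor-area moments A and E.
    """
    if inputs.area_um2 is not None:
        return float(_error_prob(inputs.area_um2, inputs, shot_noise))
    sd = inputs.size_dist
    a = np.linspace(sd.min_area_um2, sd.max_area_um2, 2001)
    return float(np.trapezoid(_error_prob(a, inputs, shot_noise) * sd.pdf(a), a))


def min_detectable_area(
    c: float, A_um2: float = 0.0, E_um4: float = 0.0, snr_min: float = 5.0
) -> float:
    """Smallest synapse area whose detection SNR reaches ``snr_min``:
    above this size the error probability 2Φ(−SNR/2) is negligible.

    Solves a·c = snr·√(a·c + A·c + E·c²) for a (the larger root).
    """
    if c <= 0:
        raise ValueError("concentration must be positive")
    s2 = snr_min**2
    disc = s2**2 * c**2 + 4.0 * c**2 * s2 * (A_um2 * c + E_um4 * c**2)
    return float((s2 * c + np.sqrt(disc)) / (2.0 * c**2))


def effective_concentration(c: float, K: int, kappa: float = 1.0) -> float:
    """Effective concentration when reading an expression level out of K
    gradations: the signal step shrinks to 1/(K−1) of the full swing, so the
    error behaves as if the concentration were reduced quadratically,
    c_eff = κ·c/(K−1)².  K = 2 (binary presence) leaves c unchanged."""
    if K < 2:
        raise ValueError("need at least K = 2 gradations")
    return kappa * c / (K - 1) ** 2


# ---------------------------------------------------------------------------
# fluorophore-code capacity
# ---------------------------------------------------------------------------

def code_capacity(n_channels_pre: int, n_channels_post: int
                  ) -> tuple[int, int, int]:
    """Number of distinct codes with pre/post-distinct fluorophore palettes:
    2^pre pre-synaptic codes × 2^post post-synaptic codes distinct
    connections."""
    if n_channels_pre < 0 or n_channels_post < 0:
        raise ValueError("channel counts must be non-negative")
    n_pre = 2 ** n_channels_pre
    n_post = 2 ** n_channels_post
    return n_pre, n_post, n_pre * n_post


def channels_required(n_neurons: int) -> int:
    """Fluorophores needed to give N neurons distinct pre and post codes:
    2·⌈log₂N⌉ — logarithmic growth in circuit size."""
    if n_neurons < 1:
        raise ValueError("need at least one neuron")
    return 2 * int(np.ceil(np.log2(n_neurons))) if n_neurons > 1 else 2


def fluorophore_surface_density(n_copies: float, diameter_um: float) -> float:
    """Surface concentration (µm⁻²) of n protein copies on a disk of the
    given diameter — e.g. 300 PSD-95 copies on a 360 nm disk ≈ 3000 µm⁻²."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return n_copies / (np.pi * (diameter_um / 2.0) ** 2)
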