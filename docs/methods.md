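# Methods

This note records the models implemented in `synbow`, the defaults and why,
the numerical choices, and the known limitations. Units: lengths in µm,
areas in µm², concentrations in µm⁻² (surface) or µM (volume,
1 µM = 602.2 molecules/µm³), photon budgets in photons per molecule.

## Synthetic neuropil

Synapse centers are a homogeneous Poisson point process in a rectangular
box; the default density ρ = 1.85 µm⁻³ matches dense mammalian neuropil
(the plausible range is 1–2 µm⁻³, both endpoints are used in resolvability
bounds). No minimum-separation (hard-core) constraint is applied by default:
measured synapse positions are consistent with uniformity except possibly at
contact-scale distances, and a hard-core option exists only implicitly by
filtering; the excluded-volume theory assumes pure Poisson statistics.

Each synapse is a flat disk: area drawn from an exponential of scale
0.05 µm² shifted to a minimum of 0.005 µm² and truncated at 0.4 µm²
(typical measured distributions are exponential-like with most contacts
below 0.05 µm²; the truncation bounds are our choice — an untruncated
exponential produces unphysical sub-molecular and multi-µm² contacts).
Orientations are isotropic on the sphere; an `in_plane` mode confines
normals to one plane for cross-checks against the single-plane segment
theory. Pre/post neuron identities are uniform over separate axon and
dendrite pools (defaults 256 axons, 30 dendrites, the fragment counts of a
typical EM-scale block).

Labeling is stochastic and combinatorial: each channel belongs exclusively
to the pre side (axonal marker, e.g. Munc-13-targeted) or the post side
(dendritic, e.g. PSD-95-targeted), and each neuron expresses each same-side
channel independently with probability f (default 0.5). Empty codes —
probability (1−f)^(N_c) per side — are allowed: such synapse sides are dark.
A synapse with an entirely empty pattern is undetectable by construction and
is excluded from the error-rate denominator (reported separately as
`n_unlabeled`); the detection metric measures marker-pattern recovery, not
label coverage. `ensure_nonempty` forces ≥ 1 channel per neuron for capacity
studies.

Both marker sides are rasterized onto the *same* surface: the 10–50 nm
synaptic cleft is negligible against ≥ 100 nm optical resolutions. Disks are
sampled with 100 quasi-uniform (sunflower-layout) surface points carrying
area/100 each, binned to voxels; total deposited area is exact by
construction, and the area-conservation tests bound the tolerance at 2%.
Disks extending past the box are clipped to the boundary with a warning
(area conserved). The `oblique_section_correction` helper exposes the
serial-section markup convention in which a tilted synapse is recorded as a
fixed-thickness vertical slab: under tilt uniform on [0, π/2) true
cross-sections are under-represented by exactly 1/E[cos θ] = π/2.

## Image formation

Photon counts are a double-Poisson process: molecules bind to surfaces as a
Poisson process, each molecule delivers Poisson-distributed photons spread
by the PSF. Both stages are approximated as Normals with matched mean and
variance. Per voxel, with surface area s, concentration c, budget h, and
unit-sum PSF kernel K:

- molecules (conditioned on an expressed label): mean c·s, variance c·s;
  marginalized over Bernoulli(f) expression: mean f·c·s, variance
  f·c·s + f(1−f)·(c·s)².
- photons: mean h·(K∗n̄), variance h·(K∗n̄) + h²·(K²∗Var n); the two terms
  are the photon shot noise and the molecule-number noise amplified by h.

The detection pipeline realizes expression explicitly per neuron and then
uses the conditional statistics; the marginal mode exists for analytic
comparisons. In the sparse per-synapse route the Brainbow variance term is
applied to the *whole-synapse* blurred mean (expression is one shared
Bernoulli across a synapse's surface, so it couples surface points
coherently) — the per-voxel marginal formula above is the single-element
special case.

Resolution figures are Gaussian FWHM by default (σ = d/2.3548; `sigma` and
1/e²-diameter conventions available). Kernels are separable, truncated at
4σ (a truncation below 2σ is rejected), and normalized to unit sum so that
h is the total detected photons per molecule. Diffuse background enters at
the optical-voxel stage as Poisson with mean h·b·602.2·voxel-volume and no
spatial structure.

Analysis runs on *optical voxels* of size min(d_xy, d_z)/4 (per-axis d/4
optional). Two equivalent routes produce photon statistics there: (a)
rasterize surfaces on the grid, convolve with the discrete kernel
(FFT-based), and bin-sum to optical voxels (zero-padded so photon totals are
conserved exactly); (b) evaluate the voxel-integrated Gaussian (erf
differences per axis) around each synapse's surface points directly on the
optical grid. Route (b) preserves sub-voxel placement exactly and yields the
sparse per-synapse contribution lists the detector needs; the two routes
agree to <1% relative RMS in tests. Noisy images are Normal(mean, variance)
clipped at zero (an exact Poisson mode exists for small counts); clipping is
negligible whenever mean ≳ 5·√variance.

## Explicit resolvability

The pooled intensity field is thresholded at 100 levels uniform on
(0, max I]; supra-threshold voxels are grouped into 26-connected components.
A synapse is resolved when, at some level, a component covers ≥ 1 of its
surface voxels and 0 voxels of any other synapse (`exclusive`, the default,
weakest reading — halo over unlabeled space is allowed). A `full` mode
additionally requires the component to cover *all* of the synapse's voxels;
it is the mode used when comparing against the point-process theory, since
it prevents a high threshold from "resolving" a synapse by shaving it down
to its brightest voxel.

Against the spherical excluded-volume prediction exp(−ρ·(4π/3)·d_xy²·d_z)
the simulation agrees within binomial error at resolutions that separate
most pairs (d ≤ 0.2 µm at ρ = 2). At coarser resolutions the threshold sweep
still isolates the *brighter* member of a blended pair (its peak survives
at levels where the dimmer one is sub-threshold), so the simulated resolved
fraction sits systematically above the theory, which counts both members of
a close pair as unresolved. The tests encode this as two-sided agreement at
d ∈ {0.1, 0.2} µm and one-sided dominance at d ∈ {0.4, 0.6} µm.

## Implicit (threshold co-localization) detection

Per optical voxel, the supra-threshold pattern is {k : I_k(v) > T_k}; a
pattern supported by ≥ T_v voxels calls a synapse. T_v defaults to 1 (no
figure for it is established in the literature this models; it is
configurable), and calls are additionally split into 26-connected clusters
so identical patterns at distant sites count separately (a global-count mode
implements the literal single-count rule).

Error accounting uses the precomputed per-synapse contributions rather than
realized images (a realized-image mode exists for end-to-end tests). One
frozen Gaussian measurement-noise draw per (channel, voxel), with the
analytic double-Poisson variance of that channel's total signal plus
background, is shared by all contributors at the voxel — it models the
single noisy measurement the instrument actually takes. At thresholds T_k:

- a synapse is *supra-threshold at a voxel* when its own contribution plus
  background and the voxel noise exceeds T_k for every channel of its
  pattern;
- a voxel with exactly one supra-threshold contributor detects it
  *correctly*; a synapse with fewer than T_v sole voxels anywhere is *lost*;
- a voxel with ≥ 2 contributors shows the union of their patterns; if that
  union differs from every contributor's own pattern it is a *false
  pattern* — a claimed synapse that does not exist (pre-only + post-only
  neighbors blending into a spurious connection). A blend whose union equals
  a contributor's pattern is indistinguishable from that real synapse and is
  not an error.

False patterns are deduplicated per distinct blended contributor set (one
error per spurious "synapse", not per voxel); since a given pair blends in
one contiguous region this matches per-26-connected-cluster counting, which
is also available (`fp_mode="clusters"`), as is raw per-voxel counting.
The threshold is a single relative level t ∈ (0, 1] scaling each channel's
intensity maximum, searched on a 100-point grid with ties broken toward the
higher level; per-channel absolute grids would square the search without
changing the optimum structure for channels with similar dynamic range.

The total error R = (lost + false patterns)/(labeled true synapses) is the
figure of merit throughout. Under the standard operating point (f = 0.5,
c = 750 µm⁻², b = 0.1 µM, h = 1000) on 8×8×4 µm blocks the 10-seed mean best
error is ≈ 1% for SIM-class resolution and ≈ 9% for high-end confocal
(0.2/0.6 µm); the benchmark problem size (≈ 470 synapses/block × 10 seeds)
was chosen so the seed-to-seed standard error is well below the margins the
bounds are tested against.

## Analytic theory

**Resolvability.** Two point synapses blend when their separation lies in
the ellipsoid (Δxy/d_xy)² + (Δz/d_z)² < 1; with Poisson placement the
unresolved fraction is 1 − exp(−ρV), V = (4π/3)·d_xy²·d_z. The criterion
radius is a convention — Rayleigh-style D < d here; an `exclusion_scale`
parameter exposes the D < 2d and D < d+q readings, which matter when
comparing against published qualitative statements (a high-end confocal
blends "most" synapses under the larger conventions, ≈ 18% under the
default).

For disk-shaped synapses, the excluded volume integrates over relative
lateral/axial positions the fraction f(R, Z) of orientation pairs whose
surfaces approach within the resolution limit. Synapses are modeled as
length-q segments rotating in the plane containing the optical axis
(orientations uniform on [0, π)); the closest approach is a box-constrained
convex quadratic program in the two arc-length parameters, solved exactly
via the interior critical point and the four clamped edges (verified against
dense brute-force grids to 1e-4). f(R, Z) is a midpoint rule over a 64×64
orientation grid (indicator integrand, O(1/n) convergence; a convergence
check refines to 256 and warns above 1e-3); V uses a 40×40 trapezoid over
(R, Z) with the shell measure 2πR dR dZ and both axial half-spaces. The
q → 0 limit recovers the spherical model to 1%, and the disk value is
sandwiched between the spherical values at radii d and d+q. Note the disk
model with the literal surfaces-within-d criterion predicts *more* blending
than the point model at equal d (surfaces extend beyond centers); the sense
in which elongation "helps" is relative to spheres of diameter q, i.e. the
d+q convention, and the tests state it that way.

**Error rate.** Detecting one fluorophore on a synapse of area a against
its blended neighborhood is a two-hypothesis Normal decision: signal step
a·c; variance a·c + A(d)·c + E(d)·c² (target-binding Poisson noise,
neighbor-binding Poisson noise, Brainbow fluctuation of the neighbor area).
A(d) = ρVf·E[a] and E(d) = ρVf·E[a²] follow from compound-Poisson moments
of the thinned neighbor process within the exclusion ellipsoid, and are
overridable. With the decision threshold midway between the absent/present
means and both tails weighted equally, the per-synapse error is 2Φ(−SNR/2),
SNR = a·c/√(variance); the reported rate averages this over the synapse-size
density (2001-point trapezoid). With A = E = 0 and a·c = 100 this is
2Φ(−5) ≈ 5.7·10⁻⁷ — the pure-Poisson √(a·c) regime that covers most
feasible operating points (a·c ≈ 50–100 molecules, SNR ≈ 7–10). An optional
shot-noise term adds (a + A)·c/h to the variance. `min_detectable_area`
inverts the SNR relation to give the size above which errors are negligible.

**Gradations and capacity.** Reading an expression *level* out of K steps
shrinks the decision step to 1/(K−1) of the swing, so the error behaves as
if the concentration were c_eff = κ·c/(K−1)² (κ = 1 by default; the
prefactor is not pinned down by the decision model alone — κ ≈ 0.4
reproduces the worked figure c_max ≈ 1000 → c_eff ≈ 100 at K = 3). With
pre- and post-distinct palettes, N_c channels split p/q encode 2^p × 2^q
connections; N neurons need 2·⌈log₂N⌉ channels. Shared-palette (unicolor)
code design is out of scope beyond noting its capacity cannot exceed the
split bound.

## Numerical and engineering choices

- All randomness flows through `numpy.random.Generator`; every public
  sampling function takes a seed or generator, and pipeline stages derive
  independent streams from one `SeedSequence`, so runs are bit-reproducible.
- Sparse contribution lists drop voxels below 10⁻³ expected photons
  (orders of magnitude below any threshold on the 100-level grid).
- Optical-voxel binning zero-pads to an integer multiple of the binning
  factor; totals are conserved exactly.
- Threshold ties break toward the higher threshold; a threshold equal to
  the channel maximum leaves no supra-threshold voxels (strict inequality).
- Degenerate inputs are signalled: empty ground truth, non-finite densities,
  tilt distributions concentrated at 90° (divergent area correction),
  kernels truncated below 2σ, optical voxels finer than the source grid.

## What the synthetic benchmark does and does not show

The generator reproduces the *statistics* used by the theory — uniform
placement, exponential-like sizes, isotropic orientations, independent
stochastic labeling — but not the spatial correlations of real tissue
(synapses along a shared axon are not clustered, dendritic shafts impose no
exclusion, orientation fields have no local coherence), nor optical
non-idealities (aberrations, depth-dependent PSF, spectral bleed-through,
bleaching kinetics). Passing benchmarks therefore demonstrate that the
detector and theory are correct under the stated statistical model, and
that resolution/operating-point trends (monotone improvement with c and h,
degradation with b and coarser d, the implicit method dominating explicit
resolvability) are as predicted; absolute error rates on real neuropil will
differ with the real geometry. The error-rate benchmarks use 8×8×4 µm
blocks; results at fixed density are insensitive to block size beyond
boundary effects of order (d+q)/L.
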