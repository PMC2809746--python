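"""Implicit synapse detection by co-localization thresholding.

A synapse tagged with fluorophores on its pre- and post-synaptic sides
produces tightly correlated fluorescence across channels at its location.
The detector thresholds each channel at T_i, assigns every optical voxel the
pattern of simultaneously supra-threshold fluorophores, and calls a synapse
for every pattern with at least T_v supporting voxels.  This detects synapses
even when they cannot be resolved into isolated puncta.

Error accounting follows the per-synapse-contribution bookkeeping: individual
fluorescence contributions from all synapses are precomputed per voxel; at a
given threshold a voxel where two or more synapses contribute supra-threshold
records a *false pattern* (their labels blend), a voxel where exactly one
synapse is supra-threshold detects that synapse *correctly*, and a synapse
that is supra-threshold nowhere is *lost*.  The total error rate
R = (lost + false patterns) / true synapses is minimized over a grid of 100
threshold levels spanning the intensity range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .neuropil import (
    LabelAssignment,
    SizeDistribution,
    SynapseDisk,
    VolumeSpec,
    assign_brainbow_labels,
    assign_connectivity,
    sample_synapse_centers,
    sample_synapse_geometry,
)
from .optics import (
    OperatingPoint,
    PSFSpec,
    background_photon_stats,
    optical_grid,
    synapse_photon_contributions,
)

__all__ = [
    "INSTRUMENTS",
    "PatternCall",
    "DetectionReport",
    "DetectionProblem",
    "voxel_patterns",
    "call_synapses",
    "build_detection_problem",
    "score_against_truth",
    "optimize_thresholds",
    "detection_experiment",
    "sweep_operating_point",
]

#: named instrument presets: lateral and axial resolution in µm
INSTRUMENTS: dict[str, PSFSpec] = {
    "SIM": PSFSpec(0.1, 0.1),
    "IDLM": PSFSpec(0.2, 0.2),
    "confocal_high": PSFSpec(0.2, 0.6),
    "confocal_low": PSFSpec(0.4, 1.25),
}

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PatternCall:
    """One detected synapse: a fluorophore pattern with supporting voxels."""

    pattern: frozenset[int]
    n_voxels: int
    location: tuple[int, int, int]

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("a pattern call must name at least one channel")


@dataclass
class DetectionReport:
    """Error bookkeeping for one threshold choice.

    Rates are per labeled true synapse: rate_fn = lost / n_true,
    rate_fp = false patterns / n_true, rate_total their sum.
    ``n_unlabeled`` counts ground-truth synapses with an empty fluorophore
    pattern (undetectable by construction); they are excluded from n_true.
    """

    n_true: int
    n_correct: int
    n_lost: int
    n_false_patterns: int
    thresholds: dict[int, float]
    t_v: int = 1
    level: float = float("nan")
    n_unlabeled: int = 0

    def __post_init__(self):
        assert self.n_correct + self.n_lost == self.n_true

    @property
    def rate_fn(self) -> float:
        return self.n_lost / self.n_true

    @property
    def rate_fp(self) -> float:
        return self.n_false_patterns / self.n_true

    @property
    def rate_total(self) -> float:
        return self.rate_fn + self.rate_fp

    def as_dict(self) -> dict:
        return {
            "n_true": self.n_true,
            "n_correct": self.n_correct,
            "n_lost": self.n_lost,
            "n_false_patterns": self.n_false_patterns,
            "n_unlabeled": self.n_unlabeled,
            "rate_fn": self.rate_fn,
            "rate_fp": self.rate_fp,
            "rate_total": self.rate_total,
            "thresholds": {int(k): float(v) for k, v in self.thresholds.items()},
            "t_v": self.t_v,
            "level": self.level,
        }


# ---------------------------------------------------------------------------
# pattern maps on image arrays (realized-image route)
# ---------------------------------------------------------------------------

def voxel_patterns(
    channel_images: Sequence[np.ndarray], thresholds: Sequence[float]
) -> np.ndarray:
    """Bitmask per voxel of the channels simultaneously above threshold:
    pattern(v) = {k : I_k(v) > T_k}; 0 where no channel is supra."""
    images = list(channel_images)
    if len(thresholds) != len(images):
        raise ValueError("need one threshold per channel")
    if len(images) > 32:
        raise ValueError("at most 32 channels supported")
    shape = images[0].shape
    out = np.zeros(shape, dtype=np.uint32)
    for k, (img, t) in enumerate(zip(images, thresholds)):
        if img.shape != shape:
            raise ValueError("channel images must share one optical grid")
        out |= (img > t).astype(np.uint32) << np.uint32(k)
    return out


def call_synapses(
    pattern_map: np.ndarray, t_v: int = 1, cluster: bool = True
) -> list[PatternCall]:
    """Emit one synapse call per supra-threshold pattern with ≥ T_v voxels.

    ``cluster`` additionally splits each pattern's voxels into 26-connected
    clusters so identical patterns at distant locations are counted as
    separate synapses; ``cluster=False`` counts each pattern's voxels
    globally (the literal single-count prescription).
    """
    if t_v < 1:
        raise ValueError("voxel-count threshold T_v must be >= 1")
    calls: list[PatternCall] = []
    for p in np.unique(pattern_map):
        if p == 0:
            continue
        pattern = frozenset(int(k) for k in range(32) if (int(p) >> k) & 1)
        mask = pattern_map == p
        if cluster:
            labels, n = ndimage.label(mask, structure=_STRUCT26)
            for lab in range(1, n + 1):
                idx = np.argwhere(labels == lab)
                if len(idx) >= t_v:
                    calls.append(PatternCall(
                        pattern, len(idx), tuple(int(x) for x in idx[0])))
        else:
            idx = np.argwhere(mask)
            if len(idx) >= t_v:
                calls.append(PatternCall(
                    pattern, len(idx), tuple(int(x) for x in idx[0])))
    return calls


# ---------------------------------------------------------------------------
# contribution-based scoring (the default, analytic-noise route)
# ---------------------------------------------------------------------------

@dataclass
class DetectionProblem:
    """Precomputed per-synapse supra-threshold bookkeeping on an optical grid.

    ``entry_*`` are parallel arrays over (synapse, voxel) contribution pairs:
    ``entry_voxel`` indexes the active-voxel list ``active_voxels`` (flat
    indices into the grid), ``entry_synapse`` indexes ``synapses``, and
    ``entry_mean`` is the mean photon contribution.  ``noise`` holds one
    frozen Gaussian measurement-noise draw per (channel, active voxel) with
    the analytic double-Poisson variance, or None in noiseless mode.
    """

    grid: VolumeSpec
    synapses: list[SynapseDisk]
    patterns: np.ndarray          # per-synapse channel bitmask (uint64)
    n_channels: int
    active_voxels: np.ndarray     # (U,) flat voxel indices
    entry_voxel: np.ndarray       # (E,) indices into active_voxels
    entry_synapse: np.ndarray     # (E,) indices into synapses
    entry_mean: np.ndarray        # (E,) mean photons
    channel_max: np.ndarray       # (K,) max total mean intensity per channel
    background_mean: float
    noise: np.ndarray | None      # (K, U) or None
    _blend_keys: np.ndarray = field(default=None, repr=False)

    @property
    def n_true(self) -> int:
        return int((self.patterns != 0).sum())

    @property
    def n_unlabeled(self) -> int:
        return int((self.patterns == 0).sum())


def build_detection_problem(
    synapses: Sequence[SynapseDisk],
    labels: LabelAssignment,
    grid: VolumeSpec,
    psf: PSFSpec,
    op: OperatingPoint,
    seed: int | np.random.Generator = 0,
    noise: bool = True,
    n_points: int = 100,
) -> DetectionProblem:
    """Precompute per-synapse photon contributions and the frozen noise map.

    Each labeled synapse contributes the same surface-bound molecule
    population to every channel in its pattern (pre and post markers share
    the cleft surface), so a single mean-contribution array serves all of its
    channels; the per-channel measurement noise differs.
    """
    synapses = list(synapses)
    patterns = labels.pattern_masks(synapses)
    labeled = np.flatnonzero(patterns != 0)
    contribs = synapse_photon_contributions(
        [synapses[i] for i in labeled], grid, psf, op, n_points=n_points)
    if labeled.size:
        all_vox = np.concatenate([c.voxels for c in contribs])
        syn_rep = np.concatenate([
            np.full(len(c.voxels), i, dtype=np.int64)
            for i, c in zip(labeled, contribs)])
        mean = np.concatenate([c.mean for c in contribs])
        var = np.concatenate([c.variance for c in contribs])
    else:
        all_vox = np.empty(0, dtype=np.int64)
        syn_rep = np.empty(0, dtype=np.int64)
        mean = var = np.empty(0)
    active = np.unique(all_vox)
    entry_voxel = np.searchsorted(active, all_vox).astype(np.int64)
    # keep entries sorted by voxel so supra-threshold subsets group by voxel
    order = np.argsort(entry_voxel, kind="stable")
    entry_voxel = entry_voxel[order]
    syn_rep = syn_rep[order]
    mean = mean[order]
    var = var[order]
    bg_mean, bg_var = background_photon_stats(op, grid)
    n_ch = labels.n_channels
    channel_max = np.full(n_ch, bg_mean)
    noise_arr = None
    if noise:
        noise_arr = np.zeros((n_ch, len(active)))
    rng = np.random.default_rng(seed)
    for k in range(n_ch):
        member = ((patterns[syn_rep] >> np.uint64(k)) & np.uint64(1)).astype(bool)
        tot_mean = np.bincount(
            entry_voxel[member], weights=mean[member], minlength=len(active))
        if len(tot_mean):
            channel_max[k] = tot_mean.max() + bg_mean
        if noise:
            tot_var = np.bincount(
                entry_voxel[member], weights=var[member], minlength=len(active))
            noise_arr[k] = rng.normal(0.0, np.sqrt(tot_var + bg_var))
    return DetectionProblem(
        grid=grid,
        synapses=synapses,
        patterns=patterns,
        n_channels=n_ch,
        active_voxels=active,
        entry_voxel=entry_voxel,
        entry_synapse=syn_rep,
        entry_mean=mean,
        channel_max=channel_max,
        background_mean=bg_mean,
        noise=noise_arr,
        _blend_keys=rng.random(len(synapses)),
    )


def score_against_truth(
    problem: DetectionProblem,
    thresholds: Sequence[float] | np.ndarray,
    t_v: int = 1,
    fp_mode: str = "blend_sets",
    level: float = float("nan"),
) -> DetectionReport:
    """Classify every labeled true synapse at the given per-channel thresholds.

    A synapse is supra-threshold at a voxel when its own contribution (plus
    background and the voxel's frozen measurement noise) exceeds the
    threshold in *every* channel of its pattern.  Sole-contributor voxels
    detect the synapse correctly; synapses with fewer than T_v sole voxels
    are lost.  A voxel with two or more supra-threshold contributors shows
    the *union* of their fluorophore patterns; when that blended pattern
    differs from every contributor's own pattern it claims a synapse that
    does not exist and records a false pattern (e.g. a pre-only and a
    post-only synapse blending into a nonexistent pre+post pattern); a blend
    indistinguishable from one of its contributors is not a false pattern.

    ``fp_mode`` counts false patterns per distinct blended contributor set
    (``"blend_sets"``, default), per 26-connected cluster of
    false-pattern voxels (``"clusters"``), or per voxel (``"voxels"``).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (problem.n_channels,):
        raise ValueError(
            f"need {problem.n_channels} thresholds, got {thresholds.shape}")
    if problem.n_true == 0:
        raise ValueError("no labeled true synapses; error rate undefined")
    n_u = len(problem.active_voxels)
    e_vox = problem.entry_voxel
    e_syn = problem.entry_synapse
    pat = problem.patterns[e_syn]
    # required contribution: max over the synapse's channels of T_k - noise_k
    req = np.full(len(e_vox), -np.inf)
    for k in range(problem.n_channels):
        m = ((pat >> np.uint64(k)) & np.uint64(1)).astype(bool)
        if not m.any():
            continue
        if problem.noise is not None:
            req[m] = np.maximum(req[m], thresholds[k] - problem.noise[k][e_vox[m]])
        else:
            req[m] = np.maximum(req[m], thresholds[k])
    supra = problem.entry_mean + problem.background_mean > req
    n_syn = len(problem.synapses)
    labeled = problem.patterns != 0
    supra_idx = np.flatnonzero(supra)
    if len(supra_idx) == 0:
        return DetectionReport(
            n_true=problem.n_true, n_correct=0, n_lost=problem.n_true,
            n_false_patterns=0,
            thresholds={k: float(t) for k, t in enumerate(thresholds)},
            t_v=t_v, level=level, n_unlabeled=problem.n_unlabeled)
    # entries are sorted by voxel: group supra entries per voxel
    sv = e_vox[supra_idx]
    starts = np.flatnonzero(np.r_[True, np.diff(sv) > 0])
    group_size = np.diff(np.r_[starts, len(sv)])
    # correct: synapses with >= T_v sole-contributor voxels
    sole_syn = e_syn[supra_idx[starts[group_size == 1]]]
    sole_per_syn = np.bincount(sole_syn, minlength=n_syn)
    correct = sole_per_syn >= t_v
    n_correct = int((correct & labeled).sum())
    # blended voxels: union pattern vs the contributors' own patterns
    pats = problem.patterns[e_syn[supra_idx]]
    union = np.bitwise_or.reduceat(pats, starts)
    is_own = (pats == np.repeat(union, group_size)).astype(np.int8)
    blend_has_owner = np.bitwise_or.reduceat(is_own, starts) > 0
    fp_group = (group_size >= 2) & ~blend_has_owner
    if fp_mode == "blend_sets":
        set_hash = np.add.reduceat(
            problem._blend_keys[e_syn[supra_idx]], starts)
        _, counts = np.unique(set_hash[fp_group], return_counts=True)
        n_fp = int((counts >= t_v).sum())
    elif fp_mode == "clusters":
        mask = np.zeros(problem.grid.shape, dtype=bool)
        mask.ravel()[problem.active_voxels[sv[starts[fp_group]]]] = True
        lab, n = ndimage.label(mask, structure=_STRUCT26)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            n_fp = int((sizes >= t_v).sum())
        else:
            n_fp = 0
    elif fp_mode == "voxels":
        n_fp = int(fp_group.sum())
    else:
        raise ValueError(f"unknown fp_mode {fp_mode!r}")
    return DetectionReport(
        n_true=problem.n_true,
        n_correct=n_correct,
        n_lost=problem.n_true - n_correct,
        n_false_patterns=n_fp,
        thresholds={k: float(t) for k, t in enumerate(thresholds)},
        t_v=t_v,
        level=level,
        n_unlabeled=problem.n_unlabeled,
    )


def optimize_thresholds(
    problem: DetectionProblem,
    n_levels: int = 100,
    t_v: int = 1,
    fp_mode: str = "blend_sets",
) -> DetectionReport:
    """Grid search over ``n_levels`` shared relative threshold levels.

    A single level t ∈ (0, 1] scales each channel's intensity maximum,
    spanning the full intensity range; the report with the lowest total error
    count wins, ties broken toward the higher threshold.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 threshold levels")
    best: DetectionReport | None = None
    for j in range(1, n_levels + 1):
        t = j / n_levels
        report = score_against_truth(
            problem, t * problem.channel_max, t_v=t_v, fp_mode=fp_mode,
            level=t)
        errors = report.n_lost + report.n_false_patterns
        if best is None or errors <= best.n_lost + best.n_false_patterns:
            best = report
    return best


# ---------------------------------------------------------------------------
# end-to-end experiments
# ---------------------------------------------------------------------------

def detection_experiment(
    psf: PSFSpec,
    op: OperatingPoint = OperatingPoint(),
    extents_um: tuple[float, float, float] = (8.0, 8.0, 4.0),
    density_per_um3: float = 1.85,
    size_dist: SizeDistribution | None = None,
    n_channels_pre: int = 1,
    n_channels_post: int = 1,
    n_pre_neurons: int = 256,
    n_post_neurons: int = 30,
    seed: int = 0,
    n_levels: int = 100,
    t_v: int = 1,
    noise: bool = True,
    fp_mode: str = "blend_sets",
    n_points: int = 100,
    per_axis_optical: bool = False,
) -> tuple[DetectionReport, DetectionProblem]:
    """Generate one synthetic neuropil block and run threshold detection.

    Builds the block (Poisson synapse placement, truncated-exponential areas,
    random connectivity, Brainbow labels at the operating point's f),
    computes photon statistics on the optical grid (resolution/4 voxels),
    and optimizes the detection threshold.  Returns the best report and the
    underlying problem.
    """
    ss = np.random.SeedSequence(seed)
    s_centers, s_geom, s_conn, s_labels, s_noise = ss.spawn(5)
    vol = VolumeSpec(extents_um=extents_um, voxel_size_um=(0.05, 0.05, 0.05))
    centers = sample_synapse_centers(
        vol, density_per_um3, np.random.default_rng(s_centers))
    synapses = sample_synapse_geometry(
        centers, size_dist or SizeDistribution(),
        seed=np.random.default_rng(s_geom))
    assign_connectivity(
        synapses, n_pre_neurons, n_post_neurons, np.random.default_rng(s_conn))
    labels = assign_brainbow_labels(
        n_pre_neurons, n_post_neurons, n_channels_pre, n_channels_post,
        f=op.f, seed=np.random.default_rng(s_labels))
    grid = optical_grid(vol, psf, per_axis=per_axis_optical)
    problem = build_detection_problem(
        synapses, labels, grid, psf, op,
        seed=np.random.default_rng(s_noise), noise=noise, n_points=n_points)
    report = optimize_thresholds(
        problem, n_levels=n_levels, t_v=t_v, fp_mode=fp_mode)
    return report, problem


def sweep_operating_point(
    axis: str,
    values: Sequence[float],
    base: OperatingPoint,
    instruments: dict[str, PSFSpec],
    n_seeds: int = 10,
    seed: int = 0,
    **experiment_kwargs,
) -> pd.DataFrame:
    """Best total error versus one swept parameter, per instrument.

    ``axis`` is one of ``"c"``, ``"h"``, ``"b"``, ``"f"`` (operating-point
    fields) or ``"resolution"`` (isotropic d in µm, overriding the instrument
    set with single-value presets).  Returns a tidy DataFrame with mean and
    standard error of the best total error over ``n_seeds`` replicates.
    """
    values = list(values)
    if sorted(values) != values:
        raise ValueError("sweep values must be sorted ascending")
    rows = []
    for v in values:
        if axis == "resolution":
            instr = {f"d={v}": PSFSpec(v, v)}
        else:
            instr = instruments
        for name, psf in instr.items():
            errs = []
            for i in range(n_seeds):
                op = base
                if axis == "c":
                    op = OperatingPoint(base.f, v, base.b_uM, base.h_photons)
                elif axis == "h":
                    op = OperatingPoint(base.f, base.c_per_um2, base.b_uM, v)
                elif axis == "b":
                    op = OperatingPoint(base.f, base.c_per_um2, v, base.h_photons)
                elif axis == "f":
                    op = OperatingPoint(v, base.c_per_um2, base.b_uM,
                                        base.h_photons)
                elif axis != "resolution":
                    raise ValueError(f"unknown sweep axis {axis!r}")
                report, _ = detection_experiment(
                    psf, op, seed=seed + i, **experiment_kwargs)
                errs.append(report.rate_total)
            errs = np.asarray(errs)
            rows.append({
                "axis": axis, "value": v, "instrument": name,
                "mean_error": float(errs.mean()),
                "se_error": float(errs.std(ddof=1) / np.sqrt(len(errs)))
                if len(errs) > 1 else 0.0,
                "n_seeds": n_seeds,
            })
    return pd.DataFrame(rows)
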