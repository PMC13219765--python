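"""Synthetic stance-phase gait trials with known ground truth.

The generator emulates the structure of an instrumented walking trial —
hip/knee/ankle flexion torques, a double-peaked vertical ground reaction
force, smooth muscle geometry for a reduced set of lower-limb muscles, and
EMG envelopes — without any motion-capture input.  The key construction
choice is that joint torques are *derived* from smooth ground-truth
activations (tau = R (a o f_max)) rather than the other way around, so the
truth is exactly feasible for the redundancy solver and parameter-recovery
experiments are well posed.  Smooth curves are sums of a few Gaussian bumps
and low-frequency sinusoids, which keeps peak locations closed-form.

Ground-truth activations are capped at 0.8 to leave headroom so EMG
tracking boxes never clip at the upper activation bound.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .model import (DEFAULT_GRAVITY, DEFAULT_WEIGHT_LEVELS, FrameGeometry,
                    LinkageModel, MuscleSpec, TrialData, scale_max_forces)
from .preprocessing import stance_window
from .solver import WeightVector

#: Muscle table of the default 12-muscle reduced lower limb: name, relative
#: strength, spanned DOFs (sign via the moment-arm draw), EMG channel flag.
#: Biarticular muscles (rectus femoris, hamstrings, gastrocnemius) couple
#: adjacent joints as in the real limb.
_DEFAULT_MUSCLES = [
    ("iliopsoas",      1500.0, ("hip_flexion",),                  False),
    ("glut_max",       1950.0, ("hip_flexion",),                  True),
    ("rect_fem",       1200.0, ("hip_flexion", "knee_flexion"),   True),
    ("hamstrings",     2000.0, ("hip_flexion", "knee_flexion"),   True),
    ("vas_lat",        2250.0, ("knee_flexion",),                 True),
    ("vas_med",        1450.0, ("knee_flexion",),                 True),
    ("bifem_sh",        800.0, ("knee_flexion",),                 False),
    ("gastroc",        1600.0, ("knee_flexion", "ankle_flexion"), True),
    ("soleus",         3550.0, ("ankle_flexion",),                True),
    ("tib_ant",        1100.0, ("ankle_flexion",),                True),
    ("tib_post",       1300.0, ("ankle_flexion",),                False),
    ("sartorius",       250.0, ("hip_flexion", "knee_flexion"),   False),
]

_DEFAULT_JOINTS = (("hip", ("hip_flexion",)),
                   ("knee", ("knee_flexion",)),
                   ("ankle", ("ankle_flexion",)))

#: Intersegmental load direction per joint (unit-ish, mostly compressive -y)
#: and its scale relative to the vertical GRF.
_INTERSEG = {"hip": (np.array([0.08, -1.0, 0.04]), 1.00),
             "knee": (np.array([0.05, -1.0, 0.03]), 1.05),
             "ankle": (np.array([0.03, -1.0, 0.02]), 1.10)}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic trial generator.

    GRF peak heights are in bodyweights and peak timings in %stance; EMG
    noise is additive Gaussian in activation units, applied to the measured
    channels before clamping to [0, 1].
    """

    n_frames: int = 151
    duration: float = 0.75             # s, one stance phase
    grf_peak_heights: tuple[float, float] = (1.1, 1.05)
    grf_peak_times: tuple[float, float] = (25.0, 75.0)  # %stance
    grf_peak_width: float = 12.0       # Gaussian sigma, %stance
    emg_noise_sd: float = 0.03
    activation_cap: float = 0.8
    seed: int = 0

    def __post_init__(self):
        t1, t2 = self.grf_peak_times
        if not (0.0 < t1 < t2 < 100.0):
            raise ParameterError(
                f"peak times must satisfy 0 < t1 < t2 < 100, got {t1}, {t2}")
        if min(self.grf_peak_heights) <= 0 or self.grf_peak_width <= 0:
            raise ParameterError("GRF peak heights and width must be > 0")
        if t2 - t1 < 3.2 * self.grf_peak_width:
            # guarantees the summed bumps keep their maxima at the
            # configured centers (the generator's closed-form-peak contract)
            raise ParameterError(
                f"peak separation {t2 - t1:.1f} %stance must be at least "
                f"3.2 x width ({3.2 * self.grf_peak_width:.1f})")
        if self.emg_noise_sd < 0:
            raise ParameterError("emg_noise_sd must be >= 0")
        if not (0 < self.activation_cap <= 1):
            raise ParameterError("activation_cap must be in (0, 1]")


@dataclass
class GroundTruth:
    """What the generator knows: the activations the torques came from."""

    activations: np.ndarray            # (n_frames, m) in [0, cap]
    weights: WeightVector              # all-ones generating strategy
    emg_noise_sd: float


def default_model(subject_mass: float = 75.0, template_mass: float = 75.0,
                  gravity: float = DEFAULT_GRAVITY,
                  weight_levels=DEFAULT_WEIGHT_LEVELS) -> LinkageModel:
    """The 12-muscle, 3-DOF (hip/knee/ankle flexion) reduced lower limb."""
    muscles = tuple(
        MuscleSpec(name, f_max, frozenset(dofs), emg)
        for name, f_max, dofs, emg in _DEFAULT_MUSCLES)
    return LinkageModel(muscles, _DEFAULT_JOINTS, subject_mass, template_mass,
                        gravity, tuple(weight_levels))


def generic_model(n_muscles: int, n_dofs: int = 3, subject_mass: float = 75.0,
                  template_mass: float = 75.0, emg_fraction: float = 2 / 3,
                  seed: int = 0) -> LinkageModel:
    """A structurally valid model of arbitrary size for scaling studies.

    Muscle i spans DOF ``i % n_dofs``; every third muscle is biarticular.
    Around ``emg_fraction`` of the muscles carry an EMG channel.
    """
    if n_muscles < 1 or n_dofs < 1:
        raise ParameterError("need n_muscles >= 1 and n_dofs >= 1")
    rng = np.random.default_rng(seed)
    joints = tuple((f"joint{d}", (f"dof{d}",)) for d in range(n_dofs))
    dofs = [f"dof{d}" for d in range(n_dofs)]
    muscles = []
    n_emg = int(round(emg_fraction * n_muscles))
    for i in range(n_muscles):
        span = {dofs[i % n_dofs]}
        if i % 3 == 0 and n_dofs > 1:
            span.add(dofs[(i + 1) % n_dofs])
        muscles.append(MuscleSpec(
            f"muscle{i:02d}", float(rng.uniform(600, 3000)), frozenset(span),
            emg_measured=i < n_emg))
    return LinkageModel(tuple(muscles), joints, subject_mass, template_mass)


def _gaussian(t, mu, sigma):
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _smooth_activations(rng, t_pct, m, cap):
    """Smooth per-muscle truth: baseline + 1-2 Gaussian bursts, in (0, cap]."""
    acts = np.zeros((t_pct.size, m))
    for i in range(m):
        a = np.full(t_pct.size, rng.uniform(0.02, 0.06))
        for _ in range(int(rng.integers(1, 3))):
            a = a + rng.uniform(0.15, 0.55) * _gaussian(
                t_pct, rng.uniform(10, 90), rng.uniform(8, 20))
        peak = a.max()
        if peak > cap:
            a *= cap / peak
        acts[:, i] = a
    return acts


def _geometry_frames(rng, model, t_pct):
    """Smooth sign-consistent moment arms and unit lines of action."""
    span = model.spanning_matrix()
    nd, m = span.shape
    n = t_pct.size
    # fixed sign per (dof, muscle): alternate so each DOF has both agonists
    # and antagonists among its spanning muscles
    signs = np.zeros((nd, m))
    for d in range(nd):
        idx = np.flatnonzero(span[d])
        for k, i in enumerate(idx):
            signs[d, i] = 1.0 if k % 2 == 0 else -1.0
    base = rng.uniform(0.030, 0.060, (nd, m))
    amp = base * rng.uniform(0.05, 0.25, (nd, m))
    phase = rng.uniform(0, 2 * np.pi, (nd, m))
    arms = np.zeros((n, nd, m))
    for k in range(n):
        osc = np.sin(2 * np.pi * t_pct[k] / 100.0 + phase)
        arms[k] = signs * (base + amp * osc) * span

    loa_base = {}
    for joint in model.joint_names:
        cross = model.crossing_mask(joint)
        dirs = np.zeros((m, 3))
        dirs[cross] = np.column_stack([
            rng.uniform(-0.3, 0.3, cross.sum()),
            -np.ones(cross.sum()),
            rng.uniform(-0.2, 0.2, cross.sum())])
        loa_base[joint] = (dirs, cross)

    frames = []
    for k in range(n):
        loa = {}
        for joint in model.joint_names:
            dirs, cross = loa_base[joint]
            d = dirs.copy()
            # small smooth wobble of the pull direction over stance
            d[cross, 0] += 0.05 * np.sin(2 * np.pi * t_pct[k] / 100.0)
            norm = np.linalg.norm(d[cross], axis=1, keepdims=True)
            d[cross] = d[cross] / norm
            loa[joint] = d
        frames.append((arms[k], loa))
    return frames


def make_gait_trial(config: SyntheticConfig | None = None,
                    model: LinkageModel | None = None
                    ) -> tuple[TrialData, GroundTruth]:
    """Generate one stance-phase trial with exactly feasible ground truth.

    Construction order: (1) smooth moment arms and lines of action; (2)
    smooth ground-truth activations; (3) torques computed as
    ``tau = R (a o f_max)``; (4) double-bump vertical GRF; (5)
    intersegmental forces proportional to the GRF; (6) EMG envelopes = true
    activations of the measured channels + Gaussian noise, clamped to [0, 1].
    """
    config = config or SyntheticConfig()
    model = model or default_model()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_frames, model.m
    time = np.linspace(0.0, config.duration, n)
    t_pct = np.linspace(0.0, 100.0, n)

    geo_raw = _geometry_frames(rng, model, t_pct)
    truth_a = _smooth_activations(rng, t_pct, m, config.activation_cap)
    f_max = model.f_max
    torques = np.einsum("kdm,km->kd",
                        np.stack([g[0] for g in geo_raw]), truth_a * f_max)

    bw = model.bodyweight
    h1, h2 = config.grf_peak_heights
    t1, t2 = config.grf_peak_times
    grf = bw * (h1 * _gaussian(t_pct, t1, config.grf_peak_width)
                + h2 * _gaussian(t_pct, t2, config.grf_peak_width))

    geometry = []
    for k in range(n):
        arms, loa = geo_raw[k]
        inter = {joint: dirv * (scale * grf[k] / np.linalg.norm(dirv))
                 for joint, (dirv, scale) in _INTERSEG.items()}
        geometry.append(FrameGeometry(arms, loa, inter))

    meas = model.emg_measured_indices
    emg = None
    if meas:
        emg = truth_a[:, list(meas)].copy()
        if config.emg_noise_sd > 0:
            emg = emg + rng.normal(0.0, config.emg_noise_sd, emg.shape)
        emg = np.clip(emg, 0.0, 1.0)

    trial = TrialData(
        time=time,
        stance_window=stance_window(grf, bw),
        torques=torques,
        geometry=geometry,
        grf_vertical=grf,
        bodyweight=bw,
        emg=emg,
    )
    truth = GroundTruth(truth_a, WeightVector.ones(m), config.emg_noise_sd)
    return trial, truth


@dataclass
class SubjectRecord:
    """One synthetic subject: scaled model, trial, ground truth, cohort tag."""

    model: LinkageModel
    trial: TrialData
    truth: GroundTruth
    tag: str
    seed: int


def make_population(n_subjects: int, seed: int = 0,
                    groups: tuple[tuple[str, int, tuple[float, float]], ...]
                    | None = None,
                    config: SyntheticConfig | None = None
                    ) -> list[SubjectRecord]:
    """Generate a cohort of independent synthetic subjects.

    ``groups`` lists ``(tag, count, (mass_lo, mass_hi))``; counts must sum
    to ``n_subjects``.  The default emulates a two-cohort walking study:
    two thirds "young", one third "older" adults.  Each subject gets an
    independent sub-seed derived from the master seed, a mass drawn from the
    group range, and strength scaled by subject/template mass.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    if groups is None:
        n_young = int(np.ceil(2 * n_subjects / 3))
        groups = (("young", n_young, (50.0, 85.0)),
                  ("older", n_subjects - n_young, (60.0, 85.0)))
    if sum(g[1] for g in groups) != n_subjects:
        raise ParameterError("group counts must sum to n_subjects")
    base = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    subseeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    out = []
    k = 0
    for tag, count, (mlo, mhi) in groups:
        for _ in range(count):
            sub_seed = int(subseeds[k])
            mass = float(np.random.default_rng(sub_seed).uniform(mlo, mhi))
            model = scale_max_forces(replace(default_model(), subject_mass=mass))
            cfg = replace(base, seed=sub_seed)
            trial, truth = make_gait_trial(cfg, model)
            out.append(SubjectRecord(model, trial, truth, tag, sub_seed))
            k += 1
    return out
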