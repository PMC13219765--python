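"""Domain types for the reduced musculoskeletal linkage model.

The model is deliberately minimal: muscles are ideal force generators
(force = activation x maximal isometric force, rigid tendon, no passive
component), geometry is supplied per frame as precomputed moment arms and
lines of action, and the skeleton enters only through the degrees of freedom
(DOFs) each muscle spans.  Sign convention: a positive moment arm means the
muscle produces a positive torque about that DOF; line-of-action vectors
point so that positive muscle force adds compressive load at the joint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidModelError

DEFAULT_GRAVITY = 9.81  # m/s^2
DEFAULT_WEIGHT_LEVELS = (1.0, 10.0, 100.0)


@dataclass(frozen=True)
class MuscleSpec:
    """One muscle: name, maximal isometric force [N], spanned DOFs.

    ``emg_measured`` marks muscles with a surface-EMG channel; only these
    receive tracking constraints in EMG-constrained solves.
    """

    name: str
    f_max: float
    spanned_dofs: frozenset[str]
    emg_measured: bool = False

    def __post_init__(self):
        if self.f_max <= 0:
            raise InvalidModelError(
                f"muscle {self.name!r}: f_max must be > 0, got {self.f_max}")
        if not self.spanned_dofs:
            raise InvalidModelError(
                f"muscle {self.name!r}: spanned_dofs must be non-empty")
        object.__setattr__(self, "spanned_dofs", frozenset(self.spanned_dofs))


@dataclass(frozen=True)
class LinkageModel:
    """The musculoskeletal system: muscles, joints/DOFs, subject mass.

    ``joints`` is an ordered list of ``(joint name, [DOF names])``; the
    concatenation of the DOF lists (in order) defines the global DOF axis
    used by torque and moment-arm matrices.  ``weight_levels`` are the
    discrete penalty levels a muscle may take in the weighted cost function.
    """

    muscles: tuple[MuscleSpec, ...]
    joints: tuple[tuple[str, tuple[str, ...]], ...]
    subject_mass: float
    template_mass: float
    gravity: float = DEFAULT_GRAVITY
    weight_levels: tuple[float, ...] = DEFAULT_WEIGHT_LEVELS

    def __post_init__(self):
        object.__setattr__(self, "muscles", tuple(self.muscles))
        object.__setattr__(
            self, "joints",
            tuple((name, tuple(dofs)) for name, dofs in self.joints))
        object.__setattr__(self, "weight_levels", tuple(self.weight_levels))
        if len(self.muscles) < 1:
            raise InvalidModelError("model must contain at least one muscle")
        if self.subject_mass <= 0 or self.template_mass <= 0:
            raise InvalidModelError(
                f"masses must be > 0 (subject={self.subject_mass}, "
                f"template={self.template_mass})")
        levels = np.asarray(self.weight_levels, dtype=float)
        if len(levels) < 1 or np.any(levels <= 0) or np.any(np.diff(levels) <= 0):
            raise InvalidModelError(
                "weight_levels must be strictly increasing and > 0, got "
                f"{self.weight_levels}")
        listed = set(self.dof_names)
        for mus in self.muscles:
            if not (mus.spanned_dofs & listed):
                raise InvalidModelError(
                    f"muscle {mus.name!r} spans no listed DOF "
                    f"(spans {sorted(mus.spanned_dofs)}, listed {sorted(listed)})")

    # -- derived views -----------------------------------------------------

    @property
    def m(self) -> int:
        """Number of muscles."""
        return len(self.muscles)

    @property
    def dof_names(self) -> tuple[str, ...]:
        return tuple(d for _, dofs in self.joints for d in dofs)

    @property
    def n_dof(self) -> int:
        return len(self.dof_names)

    @property
    def joint_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.joints)

    @property
    def f_max(self) -> np.ndarray:
        return np.array([mus.f_max for mus in self.muscles], dtype=float)

    @property
    def muscle_names(self) -> tuple[str, ...]:
        return tuple(mus.name for mus in self.muscles)

    @property
    def emg_measured_indices(self) -> tuple[int, ...]:
        return tuple(i for i, mus in enumerate(self.muscles) if mus.emg_measured)

    @property
    def bodyweight(self) -> float:
        """Subject bodyweight [N]."""
        return self.subject_mass * self.gravity

    def spanning_matrix(self) -> np.ndarray:
        """Boolean (n_dof x m) matrix: True where muscle i spans DOF d."""
        span = np.zeros((self.n_dof, self.m), dtype=bool)
        for d, dof in enumerate(self.dof_names):
            for i, mus in enumerate(self.muscles):
                span[d, i] = dof in mus.spanned_dofs
        return span

    def crossing_mask(self, joint: str) -> np.ndarray:
        """Boolean (m,) mask of muscles crossing *joint* (span any of its DOFs)."""
        for name, dofs in self.joints:
            if name == joint:
                dofset = set(dofs)
                return np.array(
                    [bool(mus.spanned_dofs & dofset) for mus in self.muscles])
        raise KeyError(f"unknown joint {joint!r}")


@dataclass(frozen=True)
class FrameGeometry:
    """Musculoskeletal geometry at one time frame.

    ``moment_arms``: (n_dof x m) signed moment arms [m], zero wherever the
    muscle does not span the DOF.  ``lines_of_action``: per joint an (m x 3)
    array of unit vectors (rows of non-crossing muscles are zero).
    ``intersegmental_force``: per joint the net 3-vector load [N] transmitted
    between adjacent segments before muscle contributions are added
    (quasi-static: segment inertial terms are folded in upstream).
    """

    moment_arms: np.ndarray
    lines_of_action: dict[str, np.ndarray]
    intersegmental_force: dict[str, np.ndarray]


@dataclass
class TrialData:
    """One stance-phase walking trial.

    All per-frame arrays share the first (time) axis.  ``stance_window`` is
    an inclusive ``(start, end)`` index pair into the frame axis.  ``emg``
    holds normalized envelopes (columns follow the model's EMG-measured
    muscles, in model order) and may be None for trials without EMG.
    """

    time: np.ndarray
    stance_window: tuple[int, int]
    torques: np.ndarray
    geometry: list[FrameGeometry]
    grf_vertical: np.ndarray
    bodyweight: float
    emg: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.time)


def scale_max_forces(model: LinkageModel) -> LinkageModel:
    """Scale every muscle's maximal isometric force by subject/template mass.

    Linear strength scaling: each ``f_max`` is multiplied by
    ``subject_mass / template_mass``; every other field is unchanged.
    """
    if model.subject_mass <= 0 or model.template_mass <= 0:
        raise InvalidModelError("masses must be > 0 to scale forces")
    ratio = model.subject_mass / model.template_mass
    scaled = tuple(replace(mus, f_max=mus.f_max * ratio) for mus in model.muscles)
    return replace(model, muscles=scaled)


def validate_model(model: LinkageModel, trial: TrialData) -> list[str]:
    """Check model/trial consistency; return a list of human-readable violations.

    An empty list means the pair satisfies every structural invariant and
    every downstream operation will accept it.  This is diagnostics, not an
    exception path.
    """
    out: list[str] = []
    n, m, nd = trial.n_frames, model.m, model.n_dof

    if trial.torques.shape != (n, nd):
        out.append(f"torques shape {trial.torques.shape} != ({n}, {nd})")
    if len(trial.geometry) != n:
        out.append(f"geometry has {len(trial.geometry)} frames, expected {n}")
    if trial.grf_vertical.shape != (n,):
        out.append(f"grf_vertical shape {trial.grf_vertical.shape} != ({n},)")
    if np.any(np.diff(trial.time) <= 0):
        out.append("time is not strictly increasing")
    s, e = trial.stance_window
    if not (0 <= s < e <= n - 1):
        out.append(f"stance_window {trial.stance_window} outside frames [0, {n - 1}]")

    expected_bw = model.subject_mass * model.gravity
    if abs(trial.bodyweight - expected_bw) > 1e-6 * expected_bw:
        out.append(
            f"bodyweight {trial.bodyweight} != subject_mass*gravity {expected_bw}")

    span = model.spanning_matrix()
    for t, geo in enumerate(trial.geometry):
        if geo.moment_arms.shape != (nd, m):
            out.append(f"frame {t}: moment_arms shape {geo.moment_arms.shape} "
                       f"!= ({nd}, {m})")
            continue
        bad = np.argwhere((geo.moment_arms != 0) & ~span)
        for d, i in bad:
            out.append(
                f"frame {t}: nonzero moment arm for non-spanning muscle "
                f"{model.muscle_names[i]!r} on DOF {model.dof_names[d]!r}")
        for joint in model.joint_names:
            loa = geo.lines_of_action.get(joint)
            if loa is None or loa.shape != (m, 3):
                out.append(f"frame {t}: lines_of_action[{joint!r}] missing or "
                           "mis-shaped")
                continue
            cross = model.crossing_mask(joint)
            norms = np.linalg.norm(loa[cross], axis=1)
            for k, nn in zip(np.flatnonzero(cross), norms):
                if abs(nn - 1.0) > 1e-9:
                    out.append(
                        f"frame {t}: line of action of {model.muscle_names[k]!r} "
                        f"at joint {joint!r} has norm {nn:.12g} != 1")
            if geo.intersegmental_force.get(joint) is None:
                out.append(f"frame {t}: intersegmental_force[{joint!r}] missing")

    if trial.emg is not None:
        n_meas = len(model.emg_measured_indices)
        if trial.emg.shape != (n, n_meas):
            out.append(f"emg shape {trial.emg.shape} != ({n}, {n_meas})")
        else:
            bad = np.argwhere((trial.emg < 0) | (trial.emg > 1))
            for t, c in bad:
                out.append(f"emg value {trial.emg[t, c]:.6g} out of [0,1] at "
                           f"frame {t}, channel {c}")
    return out
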