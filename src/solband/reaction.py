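"""Joint reaction analysis: contact force vectors and resultants.

Quasi-static free-body formulation: the contact force transmitted across a
joint is the intersegmental load (external forces plus segment dynamics,
supplied per frame) plus the sum of the force vectors of the muscles
crossing the joint.  Line-of-action vectors are oriented so that positive
muscle force adds compressive load; the analyzed scalar is the resultant
(Euclidean norm), reported in bodyweights (BW) on the 101-point stance grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FrameGeometry, LinkageModel, TrialData
from .preprocessing import resample_stance
from .solver import ActivationSolution


@dataclass
class JcfCurves:
    """Per-joint contact force over one trial.

    ``resultant`` maps joint name to the per-stance-frame resultant [N];
    ``vectors`` to the (n_frames x 3) force vectors [N]; ``normalized`` to
    the 101-point bodyweight-normalized curve.
    """

    joints: tuple[str, ...]
    vectors: dict[str, np.ndarray]
    resultant: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    bodyweight: float


def joint_reaction_frame(geometry: FrameGeometry, muscle_forces,
                         joint: str) -> np.ndarray:
    """Contact force 3-vector [N] at *joint* for one frame.

    ``muscle_forces`` is the length-m vector of scalar muscle forces;
    muscles not crossing the joint have zero line-of-action rows and drop
    out of the sum.
    """
    if joint not in geometry.lines_of_action:
        raise KeyError(f"unknown joint {joint!r}")
    f = np.asarray(muscle_forces, dtype=float)
    loa = geometry.lines_of_action[joint]          # (m, 3)
    return geometry.intersegmental_force[joint] + loa.T @ f


def jcf_trial(solution: ActivationSolution, trial: TrialData,
              model: LinkageModel) -> JcfCurves:
    """Joint contact force curves for a solved trial.

    Applies :func:`joint_reaction_frame` to every stance frame and joint,
    normalizes resultants to bodyweight and resamples onto 101 stance
    points.
    """
    s, e = solution.frame_window
    joints = model.joint_names
    n = e + 1 - s
    vectors = {j: np.zeros((n, 3)) for j in joints}
    for k, t in enumerate(range(s, e + 1)):
        geo = trial.geometry[t]
        for j in joints:
            vectors[j][k] = joint_reaction_frame(geo, solution.muscle_forces[k], j)
    resultant = {j: np.linalg.norm(vectors[j], axis=1) for j in joints}
    normalized = {
        j: resample_stance(resultant[j] / trial.bodyweight, (0, n - 1))
        for j in joints}
    return JcfCurves(joints, vectors, resultant, normalized, trial.bodyweight)
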