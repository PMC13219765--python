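"""Small hand-built models and geometry used across the test suite."""

from __future__ import annotations

import numpy as np

from solband.model import FrameGeometry, LinkageModel, MuscleSpec, TrialData


def one_dof_model(f_max=(1000.0, 1000.0), emg_measured=None,
                  subject_mass=75.0):
    """A single hinge driven by len(f_max) parallel muscles."""
    if emg_measured is None:
        emg_measured = (False,) * len(f_max)
    muscles = tuple(
        MuscleSpec(f"mus{i}", f, frozenset({"flexion"}), em)
        for i, (f, em) in enumerate(zip(f_max, emg_measured, strict=True)))
    return LinkageModel(muscles, (("hinge", ("flexion",)),),
                        subject_mass, subject_mass)


def simple_geometry(model, moment_arms, lines_of_action=None,
                    intersegmental=None):
    """FrameGeometry with constant arms and compressive unit pull lines."""
    arms = np.atleast_2d(np.asarray(moment_arms, dtype=float))
    m = model.m
    loa, inter = {}, {}
    for joint in model.joint_names:
        if lines_of_action is not None and joint in lines_of_action:
            loa[joint] = np.asarray(lines_of_action[joint], dtype=float)
        else:
            rows = np.zeros((m, 3))
            rows[model.crossing_mask(joint)] = [0.0, -1.0, 0.0]
            loa[joint] = rows
        if intersegmental is not None and joint in intersegmental:
            inter[joint] = np.asarray(intersegmental[joint], dtype=float)
        else:
            inter[joint] = np.zeros(3)
    return FrameGeometry(arms, loa, inter)


def constant_trial(model, torque_per_frame, n_frames=5, grf_bw=1.0,
                   emg=None, moment_arm=0.05):
    """A trial with identical frames and constant torques.

    ``torque_per_frame`` is a length-n_dof sequence; every muscle spanning a
    DOF gets moment arm ``+moment_arm``.
    """
    span = model.spanning_matrix().astype(float)
    geo = simple_geometry(model, span * moment_arm)
    torques = np.tile(np.asarray(torque_per_frame, dtype=float),
                      (n_frames, 1))
    bw = model.subject_mass * model.gravity
    return TrialData(
        time=np.linspace(0, 1, n_frames),
        stance_window=(0, n_frames - 1),
        torques=torques,
        geometry=[geo] * n_frames,
        grf_vertical=np.full(n_frames, grf_bw * bw),
        bodyweight=bw,
        emg=emg,
    )
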