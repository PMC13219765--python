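"""Markov-chain sampling of neural strategies and batch band generation.

Weight vectors live on the discrete lattice {levels}^m (default levels
1/10/100 — three orders of magnitude of per-muscle penalty).  The chain
starts at the all-ones vector (standard static optimization) and at each
step re-draws one uniformly chosen muscle's weight uniformly from the
levels.  The proposal is symmetric and always accepted, so the chain's
stationary distribution is uniform over the lattice; every visited state is
recorded, repeats included, preserving the "n combinations = n simulations"
semantics.  A fixed seed reproduces the chain bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bands import SolutionBand
from .errors import BandQualityError, InfeasibleTrialError, ParameterError
from .model import LinkageModel, TrialData
from .reaction import jcf_trial
from .solver import (ActivationSolution, SolverOptions, WeightVector,
                     solve_trial, solve_trial_emg_constrained)

log = logging.getLogger(__name__)

PROPOSAL_TAG = "single-site-uniform-redraw/always-accept"

MODES = ("unconstrained", "emg_constrained")


@dataclass
class WeightChain:
    """An ordered record of sampled weight vectors."""

    samples: list[WeightVector]
    seed: int
    levels: tuple[float, ...]
    proposal: str = PROPOSAL_TAG
    n_requested: int = 0

    def __post_init__(self):
        if self.n_requested == 0:
            self.n_requested = len(self.samples)
        if len(self.samples) != self.n_requested:
            raise ParameterError("chain length != n_requested")

    def __len__(self) -> int:
        return len(self.samples)

    def as_matrix(self) -> np.ndarray:
        return np.vstack([wv.w for wv in self.samples])

    def dedupe_report(self) -> dict:
        """How many distinct strategies the chain visited (repeats retained)."""
        uniq = {tuple(wv.w) for wv in self.samples}
        return {"n_samples": len(self.samples), "n_distinct": len(uniq)}


def sample_weight_chain(m: int, n: int, levels=(1.0, 10.0, 100.0),
                        seed: int = 0) -> WeightChain:
    """Run the single-site re-draw chain over {levels}^m for *n* states.

    The first recorded state is the all-ones vector (the reference static
    optimization); if 1 is not among the levels the chain starts at the
    lowest level instead.
    """
    if m < 1 or n < 1:
        raise ParameterError(f"m and n must be >= 1 (got m={m}, n={n})")
    lv = np.asarray(levels, dtype=float)
    if lv.size < 2 or np.any(lv <= 0) or np.any(np.diff(lv) <= 0):
        raise ParameterError(
            f"levels must be >= 2 strictly increasing positive values, "
            f"got {levels}")
    rng = np.random.default_rng(seed)
    state = np.ones(m) if 1.0 in lv else np.full(m, lv[0])
    samples = [WeightVector(state.copy())]
    for _ in range(n - 1):
        i = int(rng.integers(m))
        state[i] = lv[int(rng.integers(lv.size))]
        samples.append(WeightVector(state.copy()))
    return WeightChain(samples, seed=seed, levels=tuple(lv),
                       n_requested=n)


@dataclass
class BandResult:
    """Output of one batch band run.

    ``bands`` maps joint name to its :class:`SolutionBand` (failed samples
    excluded); ``total_costs`` holds the summed per-frame optimal cost of
    each successful sample, aligned with the band rows; ``failed_indices``
    lists chain positions that did not solve.
    """

    bands: dict[str, SolutionBand]
    total_costs: np.ndarray
    sample_indices: np.ndarray         # chain positions of the band rows
    failed_indices: list[int]
    mode: str
    chain: WeightChain
    solutions: list[ActivationSolution] | None = None

    @property
    def n_failed(self) -> int:
        return len(self.failed_indices)


def run_band(model: LinkageModel, trial: TrialData, chain: WeightChain,
             mode: str = "unconstrained",
             options: SolverOptions | None = None,
             max_failure_fraction: float = 0.05,
             keep_solutions: bool = False) -> BandResult:
    """Solve the trial for every chain sample and stack the JCF curves.

    For each weight vector: weighted static optimization (plain or
    EMG-constrained per ``mode``), joint reaction analysis, bodyweight
    normalization onto 101 stance points.  Samples are independent, so any
    execution order yields identical stacks; failures are recorded, excluded
    from the band, and raise :class:`BandQualityError` when they exceed
    ``max_failure_fraction`` of the chain.
    """
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}, got {mode!r}")
    options = options or SolverOptions()
    solve = solve_trial if mode == "unconstrained" else solve_trial_emg_constrained

    curves: dict[str, list[np.ndarray]] = {j: [] for j in model.joint_names}
    weights_kept: list[WeightVector] = []
    costs: list[float] = []
    kept: list[int] = []
    failed: list[int] = []
    solutions: list[ActivationSolution] = []
    for idx, wv in enumerate(chain.samples):
        try:
            sol = solve(trial, model, wv, options)
        except InfeasibleTrialError as err:
            log.warning("sample %d failed: %s", idx, err)
            failed.append(idx)
            continue
        jcf = jcf_trial(sol, trial, model)
        for j in model.joint_names:
            curves[j].append(jcf.normalized[j])
        weights_kept.append(wv)
        costs.append(sol.total_cost)
        kept.append(idx)
        if keep_solutions:
            solutions.append(sol)

    if len(failed) > max_failure_fraction * len(chain):
        raise BandQualityError(
            f"{len(failed)}/{len(chain)} samples failed "
            f"(> {max_failure_fraction:.0%} allowed): {failed[:10]}...")

    bands = {
        j: SolutionBand(np.vstack(curves[j]), list(weights_kept), j, mode)
        for j in model.joint_names}
    return BandResult(bands, np.asarray(costs), np.asarray(kept, dtype=int),
                      failed, mode, chain,
                      solutions=solutions if keep_solutions else None)
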