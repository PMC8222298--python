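"""Walking performance measures over trial ensembles.

Mechanical cost of transport (mCOT) is positive actuator work per body
weight per distance travelled.  It is reported both including falls (all
work over all forward progression, fall segments and their wasted work and
time included) and excluding falls (completed steps only).  Step-length
variability is the RMS deviation of completed step lengths about the
ensemble mean; steps interrupted by a fall are excluded.  Mean time between
falls (MTBF) is total walking time over fall count, censored at the total
observed time when no fall occurs.  Estimation RMSE pools the four
state-error components (two angles, two angular velocities, normalized
units) over time and trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import TrialResult


@dataclass(frozen=True)
class PerformanceSummary:
    mcot_incl_falls: float
    mcot_excl_falls: float
    step_length_mean: float
    step_length_rms_variability: float
    mtbf: float
    mtbf_steps: float
    mtbf_censored: bool
    estimation_rmse: float
    n_trials: int
    n_steps: int
    n_falls: int
    sd_mcot_incl: float
    sd_step_variability: float
    sd_rmse: float


def mcot(trials: list[TrialResult], include_falls: bool = True,
         total_mass: float = 1.0, gravity: float = 1.0) -> float:
    """Positive work per body weight per distance over the trial ensemble."""
    if include_falls:
        work = sum(t.work_pos for t in trials)
        dist = sum(t.distance for t in trials)
    else:
        work = sum(np.nansum(t.step_work_pos) for t in trials)
        dist = sum(np.nansum(t.step_lengths) for t in trials)
    if dist <= 0:
        raise ValueError("zero distance travelled; mCOT undefined")
    return float(work / (total_mass * gravity * dist))


def step_stats(trials: list[TrialResult]) -> tuple[float, float]:
    """(mean step length, RMS variability) pooled over completed steps."""
    lengths = np.concatenate([t.step_lengths for t in trials]) \
        if trials else np.empty(0)
    lengths = lengths[np.isfinite(lengths)]
    if len(lengths) < 2:
        raise ValueError("need at least two completed steps for step stats")
    mean = float(lengths.mean())
    return mean, float(np.sqrt(np.mean((lengths - mean) ** 2)))


def mtbf(trials: list[TrialResult]) -> tuple[float, float, bool]:
    """(time between falls, steps between falls, censored?).

    Censored means no fall was observed; the reported value is then the
    total observed time (a lower bound), not infinity.
    """
    total_time = sum(t.total_time for t in trials)
    total_steps = sum(t.n_steps for t in trials)
    falls = sum(t.n_falls for t in trials)
    if falls == 0:
        return float(total_time), float(total_steps), True
    return float(total_time / falls), float(total_steps / falls), False


def estimation_rmse(trials: list[TrialResult]) -> float:
    """RMS of the pooled 4-component state estimation error."""
    num = sum(t.err_sq_integral for t in trials)
    den = 4.0 * sum(t.total_time for t in trials)
    if den <= 0:
        raise ValueError("no simulated time; RMSE undefined")
    return float(np.sqrt(num / den))


def summarize(trials: list[TrialResult], total_mass: float = 1.0,
              gravity: float = 1.0) -> PerformanceSummary:
    """Ensemble PerformanceSummary with across-trial standard deviations."""
    mean_len, rms_var = step_stats(trials)
    tb, sb, censored = mtbf(trials)
    per_mcot = [mcot([t], True, total_mass, gravity) for t in trials]
    per_var = []
    for t in trials:
        ln = t.step_lengths[np.isfinite(t.step_lengths)]
        if len(ln) >= 2:
            per_var.append(np.sqrt(np.mean((ln - mean_len) ** 2)))
    per_rmse = [t.estimation_rmse for t in trials]
    return PerformanceSummary(
        mcot_incl_falls=mcot(trials, True, total_mass, gravity),
        mcot_excl_falls=mcot(trials, False, total_mass, gravity),
        step_length_mean=mean_len,
        step_length_rms_variability=rms_var,
        mtbf=tb,
        mtbf_steps=sb,
        mtbf_censored=censored,
        estimation_rmse=estimation_rmse(trials),
        n_trials=len(trials),
        n_steps=int(sum(t.n_steps for t in trials)),
        n_falls=int(sum(t.n_falls for t in trials)),
        sd_mcot_incl=float(np.std(per_mcot)),
        sd_step_variability=float(np.std(per_var)),
        sd_rmse=float(np.std(per_rmse)),
    )
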