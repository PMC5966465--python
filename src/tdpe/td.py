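"""Temporal-difference (TD) learning model of the conditioning task.

Each trial is discretised into short time bins (by default three 1-s
bins: CS onset, CS, US delivery).  Stimuli use a complete serial
compound representation: every CS carries a separate weight at every
within-trial bin, and the CS indicator stays on from its onset through
the US bin.  The predicted value is

    V(t) = sum_i w_i x_i(t)

and the prediction error at each bin is the discounted bootstrapped
difference

    delta(t) = r(t) + gamma * V(t+1) - V(t)

with V defined as 0 beyond the last bin.  Weights are updated once per
trial, in batch over bins:

    dw_i = alpha * sum_t x_i(t) * delta(t)

Rewards are 1 for sucrose delivery and 0 for no-solution and for the
neutral saliva control; saliva trials therefore carry identically zero
prediction error.  The per-trial regressor value is the absolute
prediction error at the US bin, |delta(US)|, reflecting response
strength without separating unexpected receipt from unexpected
omission.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedule import CS, US, Schedule

__all__ = [
    "TDParams",
    "TDTrace",
    "PESeries",
    "simulate_td",
    "pe_regressor",
    "select_learning_rate",
]

DEFAULT_REWARDS = {US.SUCROSE: 1.0, US.NO_SOLUTION: 0.0, US.SALIVA: 0.0}


@dataclass(frozen=True)
class TDParams:
    """TD model parameters.

    gamma : discount factor in (0, 1].
    alpha : learning rate in (0, 1].
    n_bins : within-trial time bins; the US occupies the last bin.
    reward_values : US identity -> scalar reward.
    initial_weight : starting value for every CS x bin weight.
    """

    gamma: float = 0.99
    alpha: float = 0.7
    n_bins: int = 3
    reward_values: dict = field(default_factory=lambda: dict(DEFAULT_REWARDS))
    initial_weight: float = 0.0
    candidate_alphas: tuple[float, ...] = (0.2, 0.5, 0.7)

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins (CS onset and US)")


@dataclass(frozen=True)
class TDTrace:
    """Per-trial, per-bin simulation record.

    v_hat, delta, reward : arrays of shape (n_trials, n_bins).
    weights : (n_trials, n_cs, n_bins) weight snapshots after each
        trial's batch update, indexed by ``cs_order``.
    """

    v_hat: np.ndarray
    delta: np.ndarray
    reward: np.ndarray
    weights: np.ndarray
    cs_order: tuple[CS, ...]
    gamma: float

    @property
    def n_trials(self) -> int:
        return self.delta.shape[0]

    @property
    def us_bin_delta(self) -> np.ndarray:
        return self.delta[:, -1]


@dataclass(frozen=True)
class PESeries:
    """Per-trial scalar prediction-error regressor with US onset times."""

    pe: np.ndarray
    onset_s: np.ndarray

    def __len__(self) -> int:
        return len(self.pe)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"onset_s": self.onset_s, "pe": self.pe})


def simulate_td(sched: Schedule, params: TDParams | None = None) -> TDTrace:
    """Run the TD model over a schedule; deterministic given inputs."""
    params = params or TDParams()
    if not len(sched):
        raise ValueError("schedule is empty")
    cs_order = tuple(CS)
    cs_index = {c: i for i, c in enumerate(cs_order)}
    nb = params.n_bins
    w = np.full((len(cs_order), nb), params.initial_weight, float)

    n = len(sched)
    v_hat = np.zeros((n, nb))
    delta = np.zeros((n, nb))
    reward = np.zeros((n, nb))
    weights = np.zeros((n, len(cs_order), nb))

    for k, trial in enumerate(sched):
        ci = cs_index[trial.condition.cs]
        try:
            r_us = params.reward_values[trial.condition.us]
        except KeyError:
            raise ValueError(f"no reward value for US {trial.condition.us}")
        # CS active at every bin from onset through the US bin
        v = w[ci, :].copy()
        r = np.zeros(nb)
        r[-1] = r_us
        v_next = np.append(v[1:], 0.0)
        d = r + params.gamma * v_next - v
        w[ci, :] += params.alpha * d  # batch update: x_i(t) = 1 at each bin
        v_hat[k] = v
        delta[k] = d
        reward[k] = r
        weights[k] = w
    return TDTrace(v_hat, delta, reward, weights, cs_order, params.gamma)


def pe_regressor(
    trace: TDTrace, sched: Schedule, mode: str = "absolute", us_delay_s: float = 2.0
) -> PESeries:
    """Per-trial scalar PE: |delta| at the US bin, aligned to US onsets."""
    if mode != "absolute":
        raise ValueError("only the absolute-value regressor is defined")
    if trace.n_trials != len(sched):
        raise ValueError("trace and schedule lengths differ")
    return PESeries(np.abs(trace.us_bin_delta), sched.us_onsets_s(us_delay_s))


def select_learning_rate(
    subjects: list[tuple[Schedule, np.ndarray]],
    candidates: tuple[float, ...] = (0.2, 0.5, 0.7),
    params: TDParams | None = None,
    acq=None,
):
    """Choose the learning rate whose regressor best fits the data.

    For every candidate alpha, the TD model is simulated on each
    subject's schedule, the |delta(US)| regressor is convolved into a
    first-level design, and the design is fitted to that subject's ROI
    time series by OLS.  The candidate maximising the mean R-squared
    across subjects wins.  Subjects with zero-variance series are
    flagged and excluded from the mean.

    Parameters
    ----------
    subjects
        List of (schedule, roi_time_series) pairs, one per subject.
    candidates
        Learning rates to compare.
    params
        Template TD parameters; alpha is swept over the candidates.
    acq
        Acquisition parameters for the first-level design (defaults
        apply when None).

    Returns
    -------
    (best_alpha, fit_table) where fit_table is a DataFrame with one row
    per (alpha, subject) holding the first-level R-squared.
    """
    import pandas as pd

    from .firstlevel import AcquisitionParams, FirstLevelModel, build_design

    if not candidates:
        raise ValueError("no candidate learning rates")
    if not subjects:
        raise ValueError("no subjects")
    params = params or TDParams()
    acq = acq or AcquisitionParams()

    rows = []
    for alpha in candidates:
        p = TDParams(
            gamma=params.gamma,
            alpha=alpha,
            n_bins=params.n_bins,
            reward_values=params.reward_values,
            initial_weight=params.initial_weight,
            candidate_alphas=params.candidate_alphas,
        )
        for si, (sched, ts) in enumerate(subjects):
            ts = np.asarray(ts, float)
            degenerate = np.ptp(ts) == 0.0
            if degenerate:
                r2 = np.nan
            else:
                pe = pe_regressor(simulate_td(sched, p), sched)
                design = build_design(pe, acq)
                r2 = FirstLevelModel(ts, design).fit().r_squared
            rows.append(
                {"alpha": alpha, "subject": si, "r_squared": r2, "degenerate": degenerate}
            )
    table = pd.DataFrame(rows)
    means = table.groupby("alpha")["r_squared"].mean()  # NaN (degenerate) excluded
    if means.isna().all():
        raise ValueError("all subjects degenerate: no learning rate can be selected")
    best = float(means.idxmax())
    return best, table
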