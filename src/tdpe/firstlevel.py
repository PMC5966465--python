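"""First-level ROI GLM: HRF-convolved prediction-error regressor.

The per-trial |PE| series is placed as amplitude-modulated impulses at
the US onsets, convolved with the canonical double-gamma haemodynamic
response function, and sampled at the volume acquisition times.  The
resulting design (intercept + PE column, optionally polynomial drift)
is fitted to a single ROI time series by ordinary least squares; the
PE-column coefficient is the subject's ROI PE parameter estimate.

OLS without prewhitening is used deliberately: serial correlation in
BOLD noise affects efficiency, not unbiasedness, and downstream group
inference is bootstrap-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import glover_hrf

from .td import PESeries

__all__ = [
    "AcquisitionParams",
    "build_design",
    "FirstLevelModel",
    "FirstLevelResults",
    "fit_first_level",
]

#: fine time grid (s) for impulse placement before HRF convolution;
#: chosen so that both a 6-s trial spacing and a 2.1-s TR are integer
#: multiples of it.
_DT = 0.05


@dataclass(frozen=True)
class AcquisitionParams:
    """fMRI acquisition timing: 2.1-s TR, 800 volumes covering 28 min."""

    tr_s: float = 2.1
    n_volumes: int = 800

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be positive")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s


def hrf_kernel(dt: float = _DT, time_length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds.

    Scaled to unit peak so that a unit-amplitude impulse produces a
    regressor with peak response 1, making PE parameter estimates
    directly comparable to event amplitudes regardless of the
    convolution grid.
    """
    h = glover_hrf(dt, oversampling=1, time_length=time_length_s)
    return h / h.max()


def build_design(
    pe: PESeries,
    acq: AcquisitionParams | None = None,
    drift_order: int = 0,
) -> pd.DataFrame:
    """HRF-convolved, PE-amplitude-modulated design sampled at the TR grid.

    Returns a DataFrame with columns ``intercept``, ``pe`` and optional
    Legendre drift columns ``drift_1..drift_k``.  The PE column is linear
    in the per-trial amplitudes (an all-zero series gives an all-zero
    column; doubling amplitudes doubles the column).
    """
    acq = acq or AcquisitionParams()
    duration_s = acq.n_volumes * acq.tr_s
    onsets = np.asarray(pe.onset_s, float)
    if len(onsets) and onsets.max() >= duration_s:
        raise ValueError(
            f"US onset {onsets.max():.1f}s beyond acquisition window {duration_s:.1f}s"
        )
    n_fine = int(np.ceil(duration_s / _DT)) + 1
    impulses = np.zeros(n_fine)
    idx = np.round(onsets / _DT).astype(int)
    np.add.at(impulses, idx, np.asarray(pe.pe, float))
    conv = np.convolve(impulses, hrf_kernel())[:n_fine]
    # sample the fine-grid convolution at the volume times
    vol_idx = np.round(acq.frame_times / _DT).astype(int)
    col = conv[vol_idx]

    design = pd.DataFrame({"intercept": np.ones(acq.n_volumes), "pe": col})
    if drift_order > 0:
        t = np.linspace(-1.0, 1.0, acq.n_volumes)
        for k in range(1, drift_order + 1):
            design[f"drift_{k}"] = np.polynomial.legendre.Legendre.basis(k)(t)
    return design


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy removal
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                bad.append(names[j])
            else:
                keep.append(j)
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear columns: {', '.join(bad)}"
        )


@dataclass(frozen=True)
class FirstLevelResults:
    """OLS fit of one ROI time series: the PE parameter estimate and fit stats."""

    beta_pe: float
    betas: pd.Series
    r_squared: float
    resid_sd: float
    n: int
    subject: str | None = None
    roi: str | None = None

    def summary(self) -> str:
        lines = [
            "First-level ROI GLM (OLS)",
            f"  subject: {self.subject}  roi: {self.roi}  n volumes: {self.n}",
            f"  beta_pe:   {self.beta_pe: .6g}",
            f"  R-squared: {self.r_squared:.4f}",
            f"  resid sd:  {self.resid_sd:.6g}",
        ]
        return "\n".join(lines)


class FirstLevelModel:
    """OLS model of a single ROI time series on a convolved design.

    Parameters
    ----------
    timeseries : array, one value per volume.
    design : DataFrame from :func:`build_design` (must contain a ``pe``
        column and an intercept).
    """

    def __init__(
        self,
        timeseries: np.ndarray,
        design: pd.DataFrame,
        subject: str | None = None,
        roi: str | None = None,
    ) -> None:
        ts = np.asarray(timeseries, float)
        if ts.ndim != 1:
            raise ValueError("timeseries must be one-dimensional")
        if len(ts) != len(design):
            raise ValueError(
                f"timeseries length {len(ts)} != design length {len(design)}"
            )
        if len(ts) < design.shape[1] + 1:
            raise ValueError("too few volumes for the number of regressors")
        self.timeseries = ts
        self.design = design
        self.subject = subject
        self.roi = roi

    def fit(self) -> FirstLevelResults:
        X = self.design.to_numpy(float)
        names = list(self.design.columns)
        _check_rank(X, names)
        y = self.timeseries
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid = y - fitted
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        dof = len(y) - X.shape[1]
        resid_sd = float(np.sqrt(ss_res / dof)) if dof > 0 else float("nan")
        betas = pd.Series(beta, index=names)
        return FirstLevelResults(
            beta_pe=float(betas["pe"]),
            betas=betas,
            r_squared=max(0.0, min(1.0, r2)),
            resid_sd=resid_sd,
            n=len(y),
            subject=self.subject,
            roi=self.roi,
        )


def fit_first_level(
    timeseries: np.ndarray,
    design: pd.DataFrame,
    subject: str | None = None,
    roi: str | None = None,
) -> FirstLevelResults:
    """Functional wrapper around :class:`FirstLevelModel`."""
    return FirstLevelModel(timeseries, design, subject, roi).fit()
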