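"""Synthetic cohort and ROI BOLD generation.

Emulates the statistical structure the analysis assumes, so that every
pipeline stage can be exercised without any imaging or genotype data:

* BMI and age drawn from truncated normals matching the cohort summary
  statistics (BMI mean 21.6, sd 1.4, range 18.1-24.2; age mean 24.3,
  sd 7.3, range 16-43; n = 33 by default).
* Genotypes drawn as two independent allele draws per locus, so
  Hardy-Weinberg equilibrium holds by construction.  Default minor-allele
  frequencies are literature-typical European-ancestry values.
* A linear ground truth: each subject's PE response slope in a signal
  ROI is intercept + sum_j effect_j * z(predictor_j) + noise, with the
  default effect pattern BMI negative, -141C Ins/Del positive, Taq1A
  negative, and all non-D2 predictors zero.
* ROI BOLD series equal to slope x HRF-convolved |PE| regressor plus
  stationary AR(1) noise.

Ground truth is written to a separate table that the analysis path
never reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .firstlevel import AcquisitionParams, FirstLevelModel, build_design
from .genetics import DEFAULT_LOCI, code_genotype_table, simulate_genotypes
from .regression import MODEL_SPECS, DEFAULT_ROIS, PERegression
from .schedule import Schedule, generate_schedule
from .td import TDParams, pe_regressor, simulate_td

__all__ = [
    "DEFAULT_MAFS",
    "DEFAULT_EFFECTS",
    "CohortConfig",
    "generate_cohort",
    "generate_subject_bold",
    "simulate_roi_estimates",
    "end_to_end_recovery",
    "RecoveryReport",
]

#: Literature-typical European-ancestry minor-allele / risk-repeat
#: frequencies (the study does not publish its allele counts).
DEFAULT_MAFS: dict[str, float] = {
    "rs1800497": 0.20,  # Taq1A A1
    "rs1799732": 0.11,  # -141C Del
    "rs686": 0.37,
    "rs4532": 0.30,
    "rs5326": 0.15,
    "rs4680": 0.48,  # COMT Met
    "DAT": 0.27,  # 9R
    "DRD4": 0.20,  # 7R
}

#: Ground-truth standardized effects on the signal-ROI PE slope:
#: higher BMI and higher Taq1A code (A2 dosage) lower the PE response,
#: higher -141C code (Ins dosage) raises it; all other loci are null.
DEFAULT_EFFECTS: dict[str, float] = {
    "bmi": -0.5,
    "code_rs1799732": 0.4,
    "code_rs1800497": -0.45,
}


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic-cohort parameters.

    noise_sd is the residual sd of the true slope around its linear
    predictor, on the same scale as the standardized effects.
    """

    n_subjects: int = 33
    bmi_mean: float = 21.6
    bmi_sd: float = 1.4
    bmi_bounds: tuple[float, float] = (18.1, 24.2)
    age_mean: float = 24.3
    age_sd: float = 7.3
    age_bounds: tuple[float, float] = (16.0, 43.0)
    mafs: dict = field(default_factory=lambda: dict(DEFAULT_MAFS))
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    signal_rois: tuple[str, ...] = ("putamen_left", "putamen_right")
    slope_intercept: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        for lo, hi in (self.bmi_bounds, self.age_bounds):
            if lo >= hi:
                raise ValueError("bounds must be ordered")


def _truncnorm(mean, sd, bounds, n, rng):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=1)
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort; returns (observed table, ground-truth table).

    The observed table holds subject_id, bmi, age, genotype calls,
    ordinal codes and the BMI+D2 summary score.  The truth table holds
    the per-ROI true PE slopes and is kept separate so the analysis can
    only consume the observed table.
    """
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    n = config.n_subjects
    obs = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "bmi": _truncnorm(
                config.bmi_mean, config.bmi_sd, config.bmi_bounds, n, rngs[0]
            ),
            "age": _truncnorm(
                config.age_mean, config.age_sd, config.age_bounds, n, rngs[0]
            ),
        }
    )
    for locus_name, maf in config.mafs.items():
        locus = DEFAULT_LOCI[locus_name]
        obs[locus_name] = simulate_genotypes(n, maf, locus, rngs[1]).to_numpy()
    codes = code_genotype_table(obs, DEFAULT_LOCI)
    obs = pd.concat([obs, codes], axis=1)
    obs["summary_score"] = (
        obs["bmi"] + obs["code_rs1799732"] + obs["code_rs1800497"]
    )

    # ground-truth slope per ROI: linear in z-scored predictors for the
    # signal ROIs, pure intercept + noise elsewhere
    truth = pd.DataFrame({"subject_id": obs["subject_id"]})
    zpred = {
        name: _zscore(obs[name].to_numpy(float)) for name in config.effects
    }
    for roi in DEFAULT_ROIS:
        lin = np.full(n, config.slope_intercept)
        if roi in config.signal_rois:
            for name, eff in config.effects.items():
                lin = lin + eff * zpred[name]
        truth[f"true_slope_{roi}"] = lin + rngs[2].normal(0.0, config.noise_sd, n)
    return obs, truth


def ar1_noise(
    n: int, rho: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) series with marginal sd ``sigma``."""
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    if sigma == 0.0:
        return np.zeros(n)
    from scipy.signal import lfilter

    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    eps = rng.normal(0.0, innov_sd, n)
    x0 = rng.normal(0.0, sigma)  # stationary start
    x, _ = lfilter([1.0], [1.0, -rho], eps, zi=np.array([rho * x0]))
    return x


def generate_subject_bold(
    true_slope: float,
    sched: Schedule,
    td: TDParams | None = None,
    acq: AcquisitionParams | None = None,
    rho: float = 0.3,
    sigma: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One ROI time series: slope x convolved |PE| regressor + AR(1) noise."""
    td = td or TDParams()
    acq = acq or AcquisitionParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pe = pe_regressor(simulate_td(sched, td), sched)
    design = build_design(pe, acq)
    signal = true_slope * design["pe"].to_numpy()
    return signal + ar1_noise(acq.n_volumes, rho, sigma, rng)


def simulate_roi_estimates(
    obs: pd.DataFrame,
    truth: pd.DataFrame,
    td: TDParams | None = None,
    acq: AcquisitionParams | None = None,
    rho: float = 0.3,
    sigma: float = 1.0,
    seed: int = 0,
    rois: list[str] | None = None,
    schedule_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Full forward + first-level pass: BOLD per subject/ROI -> pe_<roi>.

    Each subject gets their own randomized schedule (fixed initial block
    plus seed-shuffled remainder), the TD model produces the |PE|
    regressor, BOLD is synthesised from the true slope, and a first-level
    GLM recovers the per-subject ROI PE parameter estimate.  Returns the
    observed table augmented with ``pe_<roi>`` columns; the truth table
    is consumed only to synthesise BOLD, never in the fitting.
    """
    td = td or TDParams()
    acq = acq or AcquisitionParams()
    rois = rois or DEFAULT_ROIS
    ss = np.random.SeedSequence(seed)
    out = obs.copy()
    est = {roi: np.empty(len(obs)) for roi in rois}
    kwargs = schedule_kwargs or {}
    for i, (child, trow) in enumerate(zip(ss.spawn(len(obs)), truth.itertuples())):
        rng = np.random.default_rng(child)
        sched = generate_schedule(seed=int(rng.integers(2**31)), **kwargs)
        pe = pe_regressor(simulate_td(sched, td), sched)
        design = build_design(pe, acq)
        col = design["pe"].to_numpy()
        for roi in rois:
            slope = getattr(trow, f"true_slope_{roi}")
            ts = slope * col + ar1_noise(acq.n_volumes, rho, sigma, rng)
            est[roi][i] = FirstLevelModel(ts, design).fit().beta_pe
    for roi in rois:
        out[f"pe_{roi}"] = est[roi]
    return out


@dataclass(frozen=True)
class RecoveryReport:
    """Ground truth vs estimated standardized effects for the D2 model."""

    roi: str
    true_effects: dict
    estimated: pd.DataFrame  # per predictor: beta_std, p_boot, CI
    sign_agreement: int
    n_subjects: int
    null_max_abs_beta: float  # largest |beta| over D1/OTHER predictors

    def summary(self) -> str:
        lines = [
            f"Parameter recovery, {self.roi}, n = {self.n_subjects}",
            f"  D2 sign agreement: {self.sign_agreement}/{len(self.true_effects)}",
            f"  max |beta| over null (D1/OTHER) predictors: "
            f"{self.null_max_abs_beta:.3f}",
            self.estimated.to_string(float_format=lambda v: f"{v: .3f}"),
        ]
        return "\n".join(lines)


def end_to_end_recovery(
    config: CohortConfig | None = None,
    td: TDParams | None = None,
    acq: AcquisitionParams | None = None,
    rho: float = 0.3,
    sigma: float = 1.0,
    seed: int = 0,
    roi: str = "putamen_right",
    B: int = 1000,
) -> RecoveryReport:
    """Run schedule -> TD -> BOLD -> first level -> group fit and compare
    estimated standardized betas against the generating effects."""
    config = config or CohortConfig(seed=seed)
    obs, truth = generate_cohort(config)
    data = simulate_roi_estimates(
        obs, truth, td=td, acq=acq, rho=rho, sigma=sigma, seed=seed + 1
    )
    ycol = f"pe_{roi}"
    d2 = PERegression(
        data[ycol].to_numpy(), data[MODEL_SPECS["D2"]], dependent=ycol
    ).fit(bootstrap=B, seed=seed + 2)
    signs_true = {k: np.sign(v) for k, v in config.effects.items()}
    agree = sum(
        int(np.sign(d2.params.loc[k, "beta_std"]) == s)
        for k, s in signs_true.items()
        if k in d2.params.index
    )
    null_preds = [
        p
        for name in ("D1", "OTHER")
        for p in MODEL_SPECS[name]
        if p != "bmi"
    ]
    null_fit = PERegression(
        data[ycol].to_numpy(), data[null_preds], dependent=ycol
    ).fit(bootstrap=None)
    return RecoveryReport(
        roi=roi,
        true_effects=dict(config.effects),
        estimated=d2.params,
        sign_agreement=agree,
        n_subjects=len(data),
        null_max_abs_beta=float(null_fit.params["beta_std"].abs().max()),
    )
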