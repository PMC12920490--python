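"""Synthetic raw-level task data and cohort tables with known ground truth.

Every downstream stage of the pipeline has a parameter-recovery oracle here:

* ``simulate_rr_series`` — an R-peak train whose instantaneous RR interval is
  ``60/mean_hr + lf_amp*sin(2*pi*lf_freq*t) + hf_amp*sin(2*pi*hf_freq*t)``, so
  planted LF/HF oscillations land in known spectral bands.
* ``simulate_ecg_trace`` — a QRS-like Mexican-hat kernel (80 ms support) at
  each planted R time plus optional Gaussian noise; planted times travel in
  the signal metadata.
* ``simulate_psychometric_trials`` — binomial responses from a cumulative
  Gaussian or Gaussian bump with a lapse rate.
* ``simulate_rt_conditions`` — ex-Gaussian unimodal reaction times; bimodal
  trials are the minimum of two fresh independent unimodal draws (the race
  model holds exactly) minus an optional coactivation gain that forces a
  race-model violation.
* ``simulate_cohort`` — a full participant x variable table over the canonical
  registry, with outcomes built as a sparse linear combination of standardised
  predictors plus noise, affinely mapped to the 0-100 SF-36 scale; the planted
  coefficient map is stored alongside.

All randomness flows from one integer seed through ``numpy``'s SeedSequence
spawning, so sub-streams are independent and runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import registry
from .extero import RT_CONDITIONS, PsychometricTable, RtConditionTable
from .physio import RPeakSeries, SampledSignal

__all__ = [
    "EcgSimSpec",
    "PsychSimSpec",
    "CohortSpec",
    "CohortTable",
    "DEFAULT_PREDICTOR_DISTRIBUTIONS",
    "simulate_rr_series",
    "simulate_ecg_trace",
    "simulate_psychometric_trials",
    "simulate_rt_conditions",
    "simulate_cohort",
]


# --------------------------------------------------------------------------- #
# Specs
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class EcgSimSpec:
    duration: float  # s
    sampling_rate: float = 500.0  # Hz
    mean_hr: float = 60.0  # beats/min
    lf_amp: float = 0.0  # s, RR modulation depth at lf_freq
    hf_amp: float = 0.0  # s, RR modulation depth at hf_freq
    lf_freq: float = 0.10  # Hz
    hf_freq: float = 0.25  # Hz
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 30 < self.mean_hr < 200:
            raise ValueError("mean_hr must lie in (30, 200)")
        if self.lf_amp < 0 or self.hf_amp < 0:
            raise ValueError("modulation amplitudes must be >= 0")
        if 60.0 / self.mean_hr - self.lf_amp - self.hf_amp <= 0:
            raise ValueError("modulation amplitude too large: RR would go non-positive")


@dataclass(frozen=True)
class PsychSimSpec:
    stimulus_levels: tuple
    pse: float
    sigma: float
    n_per_level: int
    function_form: str = "cumulative_gaussian"  # or "gaussian_bump"
    lapse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        levels = np.asarray(self.stimulus_levels, dtype=float)
        if levels.size < 2 or np.any(np.diff(levels) <= 0):
            raise ValueError("stimulus_levels must be strictly increasing")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_per_level < 1:
            raise ValueError("n_per_level must be >= 1")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must lie in [0, 0.5)")
        if self.function_form not in ("cumulative_gaussian", "gaussian_bump"):
            raise ValueError(f"unknown function_form {self.function_form!r}")


@dataclass(frozen=True)
class CohortSpec:
    n_participants: int = 60
    seed: int = 0
    #: (outcome name, predictor name, standardised coefficient)
    latent_effects: tuple = ()
    #: outcome noise SD on the standardised latent scale; float applies to all
    noise_sd: float | dict = 1.0
    #: per-variable (mean, sd, lower bound, upper bound) overrides
    predictor_distributions: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_participants < 3:
            raise ValueError("n_participants must be >= 3")
        outcomes = set(registry.OUTCOMES)
        predictors = set(registry.STEP1_PREDICTORS) | set(registry.STEP2_EXTERO)
        for outcome, predictor, _beta in self.latent_effects:
            if outcome not in outcomes:
                raise KeyError(f"unknown outcome variable {outcome!r}")
            if predictor not in predictors:
                raise KeyError(f"unknown predictor variable {predictor!r}")
        for name in self.predictor_distributions:
            if name not in predictors:
                raise KeyError(f"unknown predictor variable {name!r}")
        sds = self.noise_sd.values() if isinstance(self.noise_sd, dict) else [self.noise_sd]
        if any(s < 0 for s in sds):
            raise ValueError("noise_sd must be >= 0")


#: Realistic marginal (mean, sd, lower, upper) per predictor, used unless
#: overridden in ``CohortSpec.predictor_distributions``.
DEFAULT_PREDICTOR_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    "acc_d": (0.55, 0.20, 0.0, 1.0),
    "acc_c": (0.65, 0.20, -0.5, 1.0),
    "con_d": (5.0, 1.5, 1.0, 9.0),
    "con_c": (5.5, 1.5, 1.0, 9.0),
    "aw_d": (0.30, 0.15, 0.0, 1.0),
    "aw_c": (0.30, 0.15, 0.0, 1.0),
    **{f"maia_m{i}": (3.0, 0.9, 0.0, 5.0) for i in range(1, 9)},
    "bpq_boa": (36.0, 10.0, 12.0, 60.0),
    "bpq_sup": (12.0, 4.0, 5.0, 25.0),
    "bpq_boa_sub": (12.0, 4.0, 5.0, 25.0),
    "mean_hr": (72.0, 10.0, 45.0, 110.0),
    "hf_log_power": (6.0, 1.2, 2.0, 10.0),
    "lf_hf": (1.8, 1.0, 0.1, 8.0),
    "breath_freq": (15.0, 3.0, 6.0, 30.0),
    "delta_ar": (0.5, 2.0, -8.0, 8.0),
    "c_che": (80.0, 12.0, 0.0, 100.0),
    "c_arm": (75.0, 12.0, 0.0, 100.0),
    "hit": (18.0, 3.0, 0.0, 24.0),
    "auc_av": (0.03, 0.03, 0.0, 0.5),
    "auc_at": (0.03, 0.03, 0.0, 0.5),
    "auc_vt": (0.03, 0.03, 0.0, 0.5),
    "jnd_sj": (120.0, 40.0, 20.0, 400.0),
    "pse_pps": (45.0, 15.0, 5.0, 120.0),
    "jnd_toju": (40.0, 15.0, 5.0, 200.0),
    "jnd_tojc": (90.0, 40.0, 10.0, 400.0),
    "sc": (8.0, 4.0, 0.0, 40.0),
    "mre_lh": (2.0, 0.8, 0.0, 6.0),
    "mre_rh": (2.0, 0.8, 0.0, 6.0),
}

#: Affine map from the standardised latent outcome to the 0-100 SF-36 scale.
OUTCOME_OFFSET = 50.0
OUTCOME_SCALE = 15.0

#: Planted effects of the reference recovery scenario: MAIA self-regulation /
#: trusting analogues drive the two role-limitation subscales, mean HR drives
#: energy/fatigue, and the body-image discrepancy is a purely exteroceptive
#: (step-2) contribution to role-physical.  With latent noise SD 0.8 each
#: planted outcome carries R^2 ~= 0.6.
DEMO_EFFECTS: tuple = (
    ("sf36_role_physical", "maia_m6", 0.8),
    ("sf36_role_physical", "delta_ar", 0.6),
    ("sf36_role_emotional", "maia_m6", 0.7),
    ("sf36_role_emotional", "maia_m8", 0.7),
    ("sf36_energy_fatigue", "mean_hr", 1.0),
)
DEMO_NOISE_SD = 0.8


def demo_cohort_spec(seed: int, n_participants: int = 60) -> "CohortSpec":
    """The reference planted-effect cohort used by recovery tests and examples."""
    return CohortSpec(
        n_participants=n_participants,
        seed=seed,
        latent_effects=DEMO_EFFECTS,
        noise_sd=DEMO_NOISE_SD,
    )


# --------------------------------------------------------------------------- #
# Physiological simulators
# --------------------------------------------------------------------------- #

def simulate_rr_series(spec: EcgSimSpec) -> RPeakSeries:
    """R-peak train with the planted instantaneous RR(t) modulation."""
    base = 60.0 / spec.mean_hr
    times = [0.0]
    while True:
        t = times[-1]
        rr = (
            base
            + spec.lf_amp * np.sin(2 * np.pi * spec.lf_freq * t)
            + spec.hf_amp * np.sin(2 * np.pi * spec.hf_freq * t)
        )
        if rr <= 0:
            raise ValueError("RR became non-positive (amplitude too large)")
        if t + rr > spec.duration:
            break
        times.append(t + rr)
    return RPeakSeries(np.asarray(times))


def _qrs_kernel(sampling_rate: float, width: float = 0.080) -> np.ndarray:
    """Mexican-hat (Ricker) kernel with ~*width* seconds of support."""
    a = width / 8.0  # characteristic scale; support ~ +/- 4a
    t = np.arange(-width / 2, width / 2 + 1.0 / sampling_rate, 1.0 / sampling_rate)
    k = (1 - (t / a) ** 2) * np.exp(-(t**2) / (2 * a**2))
    return k


def simulate_ecg_trace(
    rr: RPeakSeries,
    sampling_rate: float = 500.0,
    *,
    noise_sd: float = 0.0,
    duration: float | None = None,
    seed: int = 0,
    pad: float = 0.25,
) -> SampledSignal:
    """Synthetic ECG: a QRS-like kernel at each planted R time (+ noise).

    The beat train is shifted forward by *pad* seconds (and the trace extended
    accordingly) so a beat at t=0 keeps its full kernel.  The shifted planted
    R times are kept in ``signal.meta["r_times"]`` so detector tests can
    compare detections against ground truth.
    """
    if sampling_rate < 250:
        raise ValueError("sampling_rate must be >= 250 Hz")
    if duration is None:
        duration = (float(rr.times[-1]) + pad) if len(rr) else 2.0
    n = int(round((duration + 2 * pad) * sampling_rate))
    x = np.zeros(n)
    kernel = _qrs_kernel(sampling_rate)
    half = kernel.size // 2
    for t in rr.times:
        c = int(round((t + pad) * sampling_rate))
        lo, hi = c - half, c - half + kernel.size
        klo, khi = max(0, -lo), kernel.size - max(0, hi - n)
        lo, hi = max(0, lo), min(n, hi)
        if lo < hi:
            x[lo:hi] += kernel[klo:khi]
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        x = x + rng.normal(0.0, noise_sd, size=n)
    return SampledSignal(
        x, sampling_rate, meta={"r_times": np.asarray(rr.times) + pad}
    )


# --------------------------------------------------------------------------- #
# Psychophysics simulators
# --------------------------------------------------------------------------- #

def _psych_probability(spec: PsychSimSpec, levels: np.ndarray) -> np.ndarray:
    z = (levels - spec.pse) / spec.sigma
    if spec.function_form == "cumulative_gaussian":
        from scipy.stats import norm

        return spec.lapse_rate + (1 - 2 * spec.lapse_rate) * norm.cdf(z)
    return (1 - spec.lapse_rate) * np.exp(-(z**2) / 2)


def simulate_psychometric_trials(spec: PsychSimSpec) -> PsychometricTable:
    """Binomial trial counts per stimulus level from the planted function."""
    levels = np.asarray(spec.stimulus_levels, dtype=float)
    p = _psych_probability(spec, levels)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    k = rng.binomial(spec.n_per_level, p)
    return PsychometricTable(levels, np.full(levels.size, spec.n_per_level), k)


# --------------------------------------------------------------------------- #
# Reaction-time simulator
# --------------------------------------------------------------------------- #

def simulate_rt_conditions(
    unimodal_means: dict[str, float],
    coactivation_gain: float = 0.0,
    n_trials: int = 100,
    seed: int = 0,
    *,
    ex_gauss_sigma: float = 50.0,
    ex_gauss_tau: float = 80.0,
) -> RtConditionTable:
    """Six-condition RT table (A, T, V, AT, AV, VT) in ms.

    Unimodal RTs are ex-Gaussian with per-condition mean of the Gaussian part.
    Each bimodal RT is the minimum of two fresh independent unimodal draws, so
    with ``coactivation_gain=0`` the race-model inequality holds exactly (in
    expectation); a positive gain is subtracted from bimodal RTs to force a
    violation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    missing = {"A", "T", "V"} - set(unimodal_means)
    if missing:
        raise KeyError(f"unimodal_means missing conditions: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def ex_gauss(mu: float, size: int) -> np.ndarray:
        return rng.normal(mu, ex_gauss_sigma, size) + rng.exponential(ex_gauss_tau, size)

    rts: dict[str, np.ndarray] = {}
    for cond in ("A", "T", "V"):
        rts[cond] = np.maximum(ex_gauss(unimodal_means[cond], n_trials), 1.0)
    for pair, (u1, u2) in (("AT", ("A", "T")), ("AV", ("A", "V")), ("VT", ("V", "T"))):
        race = np.minimum(
            ex_gauss(unimodal_means[u1], n_trials), ex_gauss(unimodal_means[u2], n_trials)
        )
        rts[pair] = np.maximum(race - coactivation_gain, 1.0)
    assert set(rts) == set(RT_CONDITIONS)
    return RtConditionTable(rts)


# --------------------------------------------------------------------------- #
# Cohort simulator
# --------------------------------------------------------------------------- #

@dataclass
class CohortTable:
    """Participant x variable table plus the planted ground truth."""

    data: pd.DataFrame
    ground_truth: dict

    def to_csv(self, path) -> None:
        """Write the table as CSV with a ``<stem>.truth.json`` sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(json.dumps(self.ground_truth, indent=2, sort_keys=True))

    @classmethod
    def read_csv(cls, path) -> "CohortTable":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar = path.with_suffix(".truth.json")
        truth = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(data, truth)


def simulate_cohort(spec: CohortSpec) -> CohortTable:
    """Cohort table over the full variable registry with planted effects.

    Predictors are drawn from their marginal distributions (truncated normal
    by clipping), standardised internally, and each outcome is
    ``sum(beta * z_predictor) + N(0, noise_sd)`` on the latent scale, then
    affinely mapped to 0-100 and clipped to the SF-36 range.
    """
    n = spec.n_participants
    ss = np.random.SeedSequence(spec.seed)
    child = {name: s for name, s in zip(("predictors", "noise"), ss.spawn(2))}
    rng_x = np.random.default_rng(child["predictors"])
    rng_e = np.random.default_rng(child["noise"])

    cols: dict[str, np.ndarray] = {"participant_id": np.arange(1, n + 1)}
    zscores: dict[str, np.ndarray] = {}
    predictors = list(registry.STEP1_PREDICTORS) + list(registry.STEP2_EXTERO)
    for name in predictors:
        mean, sd, lo, hi = spec.predictor_distributions.get(
            name, DEFAULT_PREDICTOR_DISTRIBUTIONS[name]
        )
        x = np.clip(rng_x.normal(mean, sd, n), lo, hi)
        cols[name] = x
        x_sd = x.std()
        zscores[name] = (x - x.mean()) / x_sd if x_sd > 0 else np.zeros(n)

    effects: dict[str, dict[str, float]] = {}
    for outcome, predictor, beta in spec.latent_effects:
        effects.setdefault(outcome, {})[predictor] = float(beta)

    for outcome in registry.OUTCOMES:
        sd = (
            spec.noise_sd.get(outcome, 1.0)
            if isinstance(spec.noise_sd, dict)
            else spec.noise_sd
        )
        latent = rng_e.normal(0.0, sd, n)
        for predictor, beta in effects.get(outcome, {}).items():
            latent = latent + beta * zscores[predictor]
        cols[outcome] = np.clip(OUTCOME_OFFSET + OUTCOME_SCALE * latent, 0.0, 100.0)

    truth = {
        "effects": effects,
        "noise_sd": spec.noise_sd if isinstance(spec.noise_sd, dict) else float(spec.noise_sd),
        "outcome_offset": OUTCOME_OFFSET,
        "outcome_scale": OUTCOME_SCALE,
        "seed": spec.seed,
        "n_participants": n,
    }
    return CohortTable(pd.DataFrame(cols), truth)
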