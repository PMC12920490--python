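"""Canonical variable registry for the battery.

Every predictor and outcome the two-step models consume is declared here once,
with its role, unit and the module that produces it.  The pipeline refuses to
run when a registered variable is missing from the cohort table, so a predictor
can never be dropped silently.

Roles
-----
interoceptive
    Heartbeat-task accuracy/confidence/awareness scores and MAIA/BPQ subscales
    (step-1 predictors together with the physiological block).
physiological
    Resting-state cardiorespiratory features (mean HR, HF log power, LF/HF,
    breath frequency).
exteroceptive
    Body-representation and multisensory measures added in step 2.
outcome
    The eight SF-36 subscales (0-100).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Variable:
    name: str
    role: str  # interoceptive | physiological | exteroceptive | outcome
    unit: str
    source: str  # module that produces the value
    label: str = ""


_VARS: list[Variable] = [
    # -- interoceptive (heartbeat tasks + questionnaires) ---------------------
    Variable("acc_d", "interoceptive", "proportion", "intero", "heartbeat detection accuracy"),
    Variable("acc_c", "interoceptive", "proportion", "intero", "heartbeat counting accuracy"),
    Variable("con_d", "interoceptive", "1-9 rating", "intero", "detection confidence"),
    Variable("con_c", "interoceptive", "1-9 rating", "intero", "counting confidence"),
    Variable("aw_d", "interoceptive", "[0,1]", "intero", "detection awareness discrepancy"),
    Variable("aw_c", "interoceptive", "[0,1]", "intero", "counting awareness discrepancy"),
    Variable("maia_m1", "interoceptive", "0-5 mean", "intero", "MAIA Noticing"),
    Variable("maia_m2", "interoceptive", "0-5 mean", "intero", "MAIA Not-Distracting"),
    Variable("maia_m3", "interoceptive", "0-5 mean", "intero", "MAIA Not-Worrying"),
    Variable("maia_m4", "interoceptive", "0-5 mean", "intero", "MAIA Attention Regulation"),
    Variable("maia_m5", "interoceptive", "0-5 mean", "intero", "MAIA Emotional Awareness"),
    Variable("maia_m6", "interoceptive", "0-5 mean", "intero", "MAIA Self-Regulation"),
    Variable("maia_m7", "interoceptive", "0-5 mean", "intero", "MAIA Body Listening"),
    Variable("maia_m8", "interoceptive", "0-5 mean", "intero", "MAIA Trusting"),
    Variable("bpq_boa", "interoceptive", "sum", "intero", "BPQ body awareness"),
    Variable("bpq_sup", "interoceptive", "sum", "intero", "BPQ supradiaphragmatic"),
    Variable("bpq_boa_sub", "interoceptive", "sum", "intero", "BPQ subdiaphragmatic/body awareness"),
    # -- physiological --------------------------------------------------------
    Variable("mean_hr", "physiological", "beats/min", "physio", "resting mean heart rate"),
    Variable("hf_log_power", "physiological", "log ms^2", "physio", "HF (0.15-0.4 Hz) log power"),
    Variable("lf_hf", "physiological", "ratio", "physio", "LF/HF power ratio"),
    Variable("breath_freq", "physiological", "breaths/min", "physio", "breath frequency"),
    # -- exteroceptive --------------------------------------------------------
    Variable("delta_ar", "exteroceptive", "BMI units", "extero", "perceived-actual minus real BMI"),
    Variable("c_che", "exteroceptive", "% correct", "extero", "2PD chest accuracy"),
    Variable("c_arm", "exteroceptive", "% correct", "extero", "2PD arm accuracy"),
    Variable("hit", "exteroceptive", "count", "extero", "finger localisation hits"),
    Variable("auc_av", "exteroceptive", "prob x percentile", "extero", "race-model violation AUC, audio-visual"),
    Variable("auc_at", "exteroceptive", "prob x percentile", "extero", "race-model violation AUC, audio-tactile"),
    Variable("auc_vt", "exteroceptive", "prob x percentile", "extero", "race-model violation AUC, visuo-tactile"),
    Variable("jnd_sj", "exteroceptive", "ms", "extero", "simultaneity-judgment JND"),
    Variable("pse_pps", "exteroceptive", "stimulus units", "extero", "peripersonal-space PSE"),
    Variable("jnd_toju", "exteroceptive", "ms", "extero", "TOJ JND, uncrossed hands"),
    Variable("jnd_tojc", "exteroceptive", "ms", "extero", "TOJ JND, crossed hands"),
    Variable("sc", "exteroceptive", "dimensionless", "extero", "sum of confusion"),
    Variable("mre_lh", "exteroceptive", "ms/degree", "extero", "mental-rotation slope, left hand"),
    Variable("mre_rh", "exteroceptive", "ms/degree", "extero", "mental-rotation slope, right hand"),
    # -- outcomes (SF-36 subscales, consumed pre-scored 0-100) ----------------
    Variable("sf36_physical_functioning", "outcome", "0-100", "input", "Physical Functioning"),
    Variable("sf36_role_physical", "outcome", "0-100", "input", "Role Limitations (physical)"),
    Variable("sf36_role_emotional", "outcome", "0-100", "input", "Role Limitations (emotional)"),
    Variable("sf36_energy_fatigue", "outcome", "0-100", "input", "Energy/Fatigue"),
    Variable("sf36_emotional_wellbeing", "outcome", "0-100", "input", "Emotional Wellbeing"),
    Variable("sf36_social_functioning", "outcome", "0-100", "input", "Social Functioning"),
    Variable("sf36_bodily_pain", "outcome", "0-100", "input", "Bodily Pain"),
    Variable("sf36_general_health", "outcome", "0-100", "input", "General Health Perceptions"),
]

REGISTRY: dict[str, Variable] = {v.name: v for v in _VARS}
assert len(REGISTRY) == len(_VARS), "duplicate variable name in registry"


def variables(role: str | None = None) -> list[str]:
    """Canonical variable names, optionally filtered by role."""
    if role is None:
        return [v.name for v in _VARS]
    if role not in {"interoceptive", "physiological", "exteroceptive", "outcome"}:
        raise ValueError(f"unknown role {role!r}")
    return [v.name for v in _VARS if v.role == role]


#: Step-1 predictor set: all interoceptive scores plus the physiological block.
STEP1_PREDICTORS: tuple[str, ...] = tuple(
    variables("interoceptive") + variables("physiological")
)

#: Exteroceptive variables added in step 2.
STEP2_EXTERO: tuple[str, ...] = tuple(variables("exteroceptive"))

#: The eight SF-36 subscales modelled as outcomes.
OUTCOMES: tuple[str, ...] = tuple(variables("outcome"))


def check_columns(columns, need_extero: bool = True) -> None:
    """Raise ``KeyError`` naming the first registered variable missing from *columns*."""
    have = set(columns)
    needed = list(STEP1_PREDICTORS) + list(OUTCOMES)
    if need_extero:
        needed += list(STEP2_EXTERO)
    for name in needed:
        if name not in have:
            raise KeyError(f"cohort table is missing registered variable {name!r}")
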