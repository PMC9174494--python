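"""Generative cohort profiles for the synthetic plethysmography simulator.

A :class:`SimProfile` bundles the distributional parameters that define one
genotype/treatment condition: the regular (eupneic) cycle-duration
distribution, per-cycle apnea probabilities with their duration ranges, the
breath-hold plateau, click-emission probabilities per respiratory context,
vocal-bout rate, sensor noise and the audio/pressure clock-drift rating.

The registry shipped here is calibrated by inverting the closed-form apneic
time fraction (ATF) of the stationary cycle mixture, so that the expected
per-type ATF of each named profile equals the cohort mean it stands for
(e.g. the mutant profile has an expected breath-holding ATF of 22.6% and a
total ATF of 29.3%).  ``expected_summary`` is the closed-form twin of the
simulator and is what every downstream estimator is validated against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

from scipy import stats

__all__ = [
    "SimProfile",
    "ExpectedSummary",
    "build_profile",
    "profile_names",
    "expected_summary",
    "expected_click_fractions",
    "calibrate_apnea_rates",
    "apply_treatment",
]

#: minimum physiological cycle duration; the regular-duration normal is
#: truncated below this value (s)
MIN_CYCLE_S = 0.1

#: number of consecutive cycles converted to vocal cycles per vocal bout
VOCAL_BOUT_CYCLES = 4


@dataclass(frozen=True)
class SimProfile:
    """Generative parameters for one simulated cohort condition.

    Durations are seconds, amplitudes microliters, probabilities per cycle
    (or per event where noted).  ``noise_sd`` is expressed as a fraction of
    ``vt_mean``; ``drift_ppm`` is the audio-vs-pressure clock drift in parts
    per million.
    """

    name: str
    mu_reg: float = 0.4        # mean regular cycle duration (s)
    sigma_reg: float = 0.04    # SD of regular cycle duration (s)
    ti_fraction: float = 0.35  # Ti / (Ti + Te)
    vt_mean: float = 8.0       # tidal amplitude (uL)
    p_bh: float = 0.0          # per-cycle breath-holding apnea probability
    p_cl: float = 0.0          # per-cycle central-like apnea probability
    dur_bh: tuple[float, float] = (1.0, 4.0)   # breath-hold duration range (s)
    dur_cl: tuple[float, float] = (1.0, 4.0)   # central-like duration range (s)
    plateau_frac: float = 0.8  # retained volume during breath hold, in V_T
    p_click_bh: float = 0.0    # P(click) at a breath-hold termination
    vocal_rate: float = 0.0    # vocal bouts per minute
    p_click_vocal: float = 0.0  # P(click) per vocal compression event
    p_click_eup: float = 0.0   # P(click) per regular cycle (inspiratory onset)
    p_click_cl: float = 0.0    # P(click) per central-like apnea
    noise_sd: float = 0.03     # additive pressure noise SD (fraction of vt_mean)
    drift_ppm: float = 50.0    # audio clock drift relative to pressure clock
    weight_g: float = 1.4      # pup mass (g)

    def __post_init__(self) -> None:
        probs = (self.p_bh, self.p_cl, self.p_click_bh, self.p_click_vocal,
                 self.p_click_eup, self.p_click_cl, self.ti_fraction)
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"probabilities must lie in [0, 1]: {probs}")
        if not 0.0 <= self.p_bh + self.p_cl < 1.0:
            raise ValueError("p_bh + p_cl must lie in [0, 1)")
        if not 0.0 <= self.plateau_frac <= 1.0:
            raise ValueError("plateau_frac must lie in [0, 1]")
        if self.mu_reg <= 0 or self.sigma_reg < 0:
            raise ValueError("mu_reg must be > 0 and sigma_reg >= 0")
        floor = self.mu_reg + 3.0 * self.sigma_reg
        for label, (lo, hi) in (("dur_bh", self.dur_bh), ("dur_cl", self.dur_cl)):
            if not lo < hi:
                raise ValueError(f"{label} must be an increasing (min, max) pair")
            if (self.p_bh > 0 or self.p_cl > 0) and lo <= floor:
                raise ValueError(
                    f"{label} must start strictly above mu_reg + 3*sigma_reg "
                    f"({floor:.3f} s); apneic cycles are genuinely long")
        if abs(self.drift_ppm) > 200:
            raise ValueError("|drift_ppm| must be <= 200")

    # ---- moments of the stated duration distributions -------------------
    def mean_regular_duration(self) -> float:
        """Exact mean of the truncated-normal regular cycle duration."""
        if self.sigma_reg == 0:
            return self.mu_reg
        a = (MIN_CYCLE_S - self.mu_reg) / self.sigma_reg
        return float(stats.truncnorm.mean(a, float("inf"),
                                          loc=self.mu_reg, scale=self.sigma_reg))

    def mean_bh_duration(self) -> float:
        return 0.5 * (self.dur_bh[0] + self.dur_bh[1])

    def mean_cl_duration(self) -> float:
        return 0.5 * (self.dur_cl[0] + self.dur_cl[1])

    def mean_cycle_duration(self) -> float:
        """Expected cycle duration under the stationary kind mixture."""
        q = 1.0 - self.p_bh - self.p_cl
        return (q * self.mean_regular_duration()
                + self.p_bh * self.mean_bh_duration()
                + self.p_cl * self.mean_cl_duration())

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dur_bh"] = list(self.dur_bh)
        d["dur_cl"] = list(self.dur_cl)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimProfile":
        d = dict(d)
        d["dur_bh"] = tuple(d["dur_bh"])
        d["dur_cl"] = tuple(d["dur_cl"])
        return cls(**d)


@dataclass(frozen=True)
class ExpectedSummary:
    """Closed-form expectations implied by a profile (fractions, not %)."""

    atf_bh: float
    atf_cl: float
    atf_total: float
    mean_cycle_s: float


def expected_summary(profile: SimProfile) -> ExpectedSummary:
    """Expected apneic time fraction, total and per type.

    Under the stationary per-cycle mixture the time fraction spent in apneas
    of one type is ``p_type * E[D_type] / E[D]`` with ``E[D]`` the mean cycle
    duration of the mixture.
    """
    mean_cycle = profile.mean_cycle_duration()
    atf_bh = profile.p_bh * profile.mean_bh_duration() / mean_cycle
    atf_cl = profile.p_cl * profile.mean_cl_duration() / mean_cycle
    return ExpectedSummary(atf_bh=atf_bh, atf_cl=atf_cl,
                           atf_total=atf_bh + atf_cl, mean_cycle_s=mean_cycle)


def calibrate_apnea_rates(atf_bh: float, atf_cl: float, *,
                          mean_reg: float, mean_bh: float,
                          mean_cl: float) -> tuple[float, float]:
    """Invert :func:`expected_summary` for the per-cycle apnea probabilities.

    Solves for ``(p_bh, p_cl)`` such that the stationary mixture spends
    exactly ``atf_bh`` and ``atf_cl`` of its time in each apnea type, given
    the mean durations of regular, breath-hold and central-like cycles.
    """
    if atf_bh < 0 or atf_cl < 0 or atf_bh + atf_cl >= 1:
        raise ValueError("target ATFs must be >= 0 and sum below 1")
    r = 1.0 - atf_bh - atf_cl  # fraction of time in regular breathing
    q = 1.0 / (1.0 + (mean_reg / r) * (atf_bh / mean_bh + atf_cl / mean_cl))
    p_bh = atf_bh * q * mean_reg / (r * mean_bh)
    p_cl = atf_cl * q * mean_reg / (r * mean_cl)
    return p_bh, p_cl


def expected_click_fractions(profile: SimProfile) -> dict[str, float]:
    """Expected fraction of emitted clicks per respiratory context.

    Click rates per unit time: breath-hold terminations, vocal compressions
    (``VOCAL_BOUT_CYCLES`` compression events per bout), eupneic inspiratory
    onsets and central-like pauses each emit clicks independently with their
    profile probability.
    """
    mean_cycle = profile.mean_cycle_duration()
    cycles_per_s = 1.0 / mean_cycle
    vocal_cycles_per_s = profile.vocal_rate / 60.0 * VOCAL_BOUT_CYCLES
    q_reg = 1.0 - profile.p_bh - profile.p_cl
    rates = {
        "breath_hold": profile.p_bh * cycles_per_s * profile.p_click_bh,
        "vocal": vocal_cycles_per_s * profile.p_click_vocal,
        # vocal cycles are carved out of the regular population
        "eupnea": max(q_reg * cycles_per_s - vocal_cycles_per_s, 0.0)
        * profile.p_click_eup,
        "central": profile.p_cl * cycles_per_s * profile.p_click_cl,
    }
    total = sum(rates.values())
    if total == 0:
        return {k: 0.0 for k in rates}
    return {k: v / total for k, v in rates.items()}


# ---------------------------------------------------------------------------
# registry

#: target (breath-hold ATF, central-like ATF) per named condition, as
#: fractions of recording time.  Totals: mutant 29.3%, control 12.3%.  The
#: null line's central-like component is assumed equal to the control one.
_ATF_TARGETS: dict[str, tuple[float, float]] = {
    "control_P0_12h": (0.083, 0.040),
    "mutant_n4A_P0_12h": (0.226, 0.067),
    "null_LacZ": (0.017, 0.040),
    "wt_joint_audio": (0.097, 0.040),
    "dreadd_baseline": (0.035, 0.015),
}

#: measured distribution of clicks across breathing contexts in joint
#: audio-plethysmography recordings of wild-type pups (vocal, breath-hold,
#: eupneic, central-like), used to calibrate the wt_joint_audio profile
_CLICK_CONTEXT_TARGETS = {"vocal": 0.815, "breath_hold": 0.150,
                          "eupnea": 0.022, "central": 0.011}

#: fraction of breath holds terminated by a click in wild-type recordings
P_CLICK_BH_WT = 0.695


def _calibrated_profile(name: str, *, atf_bh: float, atf_cl: float,
                        **overrides) -> SimProfile:
    base = SimProfile(name=name, **overrides)
    p_bh, p_cl = calibrate_apnea_rates(
        atf_bh, atf_cl, mean_reg=base.mean_regular_duration(),
        mean_bh=base.mean_bh_duration(), mean_cl=base.mean_cl_duration())
    return replace(base, p_bh=p_bh, p_cl=p_cl)


def _with_click_emission(profile: SimProfile, *, vocal_rate: float = 2.5,
                         p_click_bh: float = P_CLICK_BH_WT,
                         context_targets: dict[str, float] | None = None,
                         ) -> SimProfile:
    """Set click probabilities so context fractions match the targets.

    ``p_click_bh`` anchors the absolute click rate; the vocal, eupneic and
    central-like emission probabilities are solved from the target context
    ratios.
    """
    t = dict(context_targets or _CLICK_CONTEXT_TARGETS)
    norm = sum(t.values())
    t = {k: v / norm for k, v in t.items()}
    mean_cycle = profile.mean_cycle_duration()
    cycles_per_s = 1.0 / mean_cycle
    bh_clicks_per_s = profile.p_bh * cycles_per_s * p_click_bh
    vocal_cycles_per_s = vocal_rate / 60.0 * VOCAL_BOUT_CYCLES
    q_reg = 1.0 - profile.p_bh - profile.p_cl
    eup_cycles_per_s = q_reg * cycles_per_s - vocal_cycles_per_s
    cl_cycles_per_s = profile.p_cl * cycles_per_s
    ratio = bh_clicks_per_s / t["breath_hold"]
    p_vocal = t["vocal"] * ratio / vocal_cycles_per_s
    p_eup = t["eupnea"] * ratio / eup_cycles_per_s
    p_cl_click = t["central"] * ratio / cl_cycles_per_s
    for label, p in (("vocal", p_vocal), ("eupnea", p_eup), ("central", p_cl_click)):
        if not 0 <= p <= 1:
            raise ValueError(f"click calibration infeasible for {label}: {p:.3f}")
    return replace(profile, vocal_rate=vocal_rate, p_click_bh=p_click_bh,
                   p_click_vocal=p_vocal, p_click_eup=p_eup,
                   p_click_cl=p_cl_click)


def _build_registry() -> dict[str, SimProfile]:
    reg: dict[str, SimProfile] = {}
    for name, (a, b) in _ATF_TARGETS.items():
        reg[name] = _calibrated_profile(name, atf_bh=a, atf_cl=b)
    reg["wt_joint_audio"] = _with_click_emission(reg["wt_joint_audio"])
    return reg


_REGISTRY = _build_registry()


def profile_names() -> list[str]:
    return sorted(_REGISTRY)


def build_profile(name: str) -> SimProfile:
    """Return the registered profile ``name``.

    Raises
    ------
    KeyError
        If the name is unknown; the message lists valid names.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; registered profiles: "
            f"{', '.join(profile_names())}") from None


# ---------------------------------------------------------------------------
# treatments

#: PTZ shortens the regular cycle (breathing-rate increase) and suppresses
#: breath holds so that the expected total ATF of the mutant profile drops
#: by about half (> 40%); central-like apneas are untouched.
_PTZ_BH_ATF_SCALE = 0.35
_PTZ_MU_SCALE = 0.85

#: CNO scales both apnea types so the expected total ATF rises five-fold.
_CNO_ATF_SCALE = 5.0


def apply_treatment(profile: SimProfile, treatment: str) -> SimProfile:
    """Return the profile transformed by a pharmacological treatment.

    ``PTZ`` (GABA_A antagonist) raises the breathing rate and selectively
    suppresses breath-holding apneas; ``CNO`` (DREADD agonist) scales both
    apnea types five-fold; ``saline`` is the identity.  Rate parameters are
    re-derived from the closed-form ATF inversion so the expected summaries
    of the transformed profiles hit the stated effect sizes exactly.
    """
    if treatment == "saline":
        return profile
    exp = expected_summary(profile)
    if treatment == "PTZ":
        base = replace(profile, name=f"{profile.name}+PTZ",
                       mu_reg=profile.mu_reg * _PTZ_MU_SCALE,
                       p_bh=0.0, p_cl=0.0)
        p_bh, p_cl = calibrate_apnea_rates(
            exp.atf_bh * _PTZ_BH_ATF_SCALE, exp.atf_cl,
            mean_reg=base.mean_regular_duration(),
            mean_bh=base.mean_bh_duration(), mean_cl=base.mean_cl_duration())
        return replace(base, p_bh=p_bh, p_cl=p_cl)
    if treatment == "CNO":
        base = replace(profile, name=f"{profile.name}+CNO", p_bh=0.0, p_cl=0.0)
        p_bh, p_cl = calibrate_apnea_rates(
            exp.atf_bh * _CNO_ATF_SCALE, exp.atf_cl * _CNO_ATF_SCALE,
            mean_reg=base.mean_regular_duration(),
            mean_bh=base.mean_bh_duration(), mean_cl=base.mean_cl_duration())
        return replace(base, p_bh=p_bh, p_cl=p_cl)
    raise ValueError(f"unknown treatment {treatment!r}; "
                     "expected one of 'PTZ', 'CNO', 'saline'")
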