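"""Simulation of animal-level dose-response cohorts.

Generates cohorts with the statistical structure the downstream
estimators assume: binary responders drawn from a logistic law in dose
(or in LQ biologically effective dose when schedules are mixed),
log-normal response latencies truncated at the follow-up horizon and an
independent exponential censoring process standing in for intercurrent
disease.

The built-in study design reproduces the published dose-level table:
four cord positions (dose-averaged LET 26/66/98/141 keV/um), single and
split schedules, 5 animals per dose level, 10 unirradiated controls,
280 animals in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "CohortDesign",
    "TrueResponseParams",
    "AnimalRecord",
    "simulate_cohort",
    "design_from_table1",
    "control_design",
    "simulate_table1",
    "total_animals",
]


@dataclass(frozen=True)
class CohortDesign:
    """One radiation quality x schedule arm of the study.

    ``dose_levels`` are total doses in Gy (strictly increasing),
    ``animals_per_level`` animals are irradiated at each level and
    ``n_controls`` unirradiated animals may be attached to the arm.
    """

    radiation_label: str
    let_value: float  # keV/um, 0 for photons/controls
    depth_mm: float
    n_fractions: int
    dose_levels: tuple[float, ...]
    animals_per_level: int = 5
    n_controls: int = 0
    followup_horizon: float = 300.0  # days

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.animals_per_level < 1:
            raise ValueError("animals_per_level must be >= 1")
        if self.followup_horizon <= 0:
            raise ValueError("followup_horizon must be positive")
        levels = tuple(float(d) for d in self.dose_levels)
        if any(d < 0 for d in levels):
            raise ValueError("doses must be non-negative")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("dose_levels must be strictly increasing")
        object.__setattr__(self, "dose_levels", levels)

    @property
    def n_animals(self) -> int:
        return len(self.dose_levels) * self.animals_per_level + self.n_controls


@dataclass(frozen=True)
class TrueResponseParams:
    """Generating law for a simulated cohort.

    ``ed50_total_dose`` is the single-fraction total dose at which the
    response probability is exactly 0.5 and ``logistic_slope`` the slope
    of the logistic law on the single-fraction dose axis at that point.
    When ``alpha_beta`` is finite the probability depends on dose only
    through BED(D, n) = D*(1 + (D/n)/alpha_beta), which makes alpha/beta
    recovery from multi-schedule cohorts well posed; ``alpha_beta =
    inf`` degenerates to a plain logistic in total dose for every
    schedule.
    """

    ed50_total_dose: float
    logistic_slope: float  # per Gy, on the 1-Fx dose axis at ED50
    alpha_beta: float = math.inf  # Gy
    censor_hazard: float = 0.0  # per day
    latency_location: float = math.log(140.0)  # log-days
    latency_scale: float = 0.35

    def __post_init__(self) -> None:
        vals = (self.ed50_total_dose, self.logistic_slope, self.alpha_beta,
                self.censor_hazard, self.latency_location, self.latency_scale)
        if any(not math.isfinite(v) for v in vals if v != self.alpha_beta):
            raise ValueError("non-finite parameter")
        if not math.isfinite(self.ed50_total_dose):
            raise ValueError("non-finite ed50_total_dose")
        if self.logistic_slope <= 0:
            raise ValueError("logistic_slope must be > 0")
        if self.ed50_total_dose <= 0:
            raise ValueError("ed50_total_dose must be > 0")
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be > 0")
        if self.censor_hazard < 0:
            raise ValueError("censor_hazard must be >= 0")
        if self.latency_scale <= 0:
            raise ValueError("latency_scale must be > 0")

    def _bed(self, total_dose: float, n_fractions: int) -> float:
        if not math.isfinite(self.alpha_beta):
            return total_dose
        d = total_dose / n_fractions
        return total_dose * (1.0 + d / self.alpha_beta)

    def response_probability(self, total_dose: float, n_fractions: int = 1) -> float:
        """Responder probability under the generating law."""
        if total_dose < 0:
            raise ValueError("dose must be >= 0")
        bed50 = self._bed(self.ed50_total_dose, 1)
        if math.isfinite(self.alpha_beta):
            # chain rule: slope on the BED axis that reproduces the
            # requested dose-axis slope at the 1-Fx ED50
            g1 = self.logistic_slope / (1.0 + 2.0 * self.ed50_total_dose / self.alpha_beta)
        else:
            g1 = self.logistic_slope
        eta = g1 * (self._bed(total_dose, n_fractions) - bed50)
        return 1.0 / (1.0 + math.exp(-eta))


@dataclass(frozen=True)
class AnimalRecord:
    """One irradiated (or control) animal."""

    animal_id: str
    radiation_label: str
    let_value: float
    n_fractions: int
    total_dose: float
    responder: bool
    event_day: float | None  # latency to endpoint, responders only
    followup_day: float  # day of censoring, event, or horizon
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.total_dose < 0:
            raise ValueError("total_dose must be >= 0")
        if self.responder and self.event_day is None:
            raise ValueError("responder requires event_day")
        if self.excluded and self.responder:
            raise ValueError("excluded animals cannot be responders")


def _truncated_lognormal(u: float, mu: float, sigma: float, upper: float) -> float:
    """Inverse-CDF draw from LogNormal(mu, sigma) truncated above at ``upper``."""
    cap = norm.cdf((math.log(upper) - mu) / sigma)
    return float(math.exp(mu + sigma * norm.ppf(u * cap)))


def simulate_cohort(
    design: CohortDesign,
    truth: TrueResponseParams,
    seed: int | np.random.Generator,
) -> list[AnimalRecord]:
    """Simulate one cohort arm.

    One generator is seeded per cohort; per animal the draws happen in
    fixed order (response, latency, censoring) so output is reproducible
    for a fixed seed regardless of outcome pattern.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[AnimalRecord] = []
    for level_idx, dose in enumerate(design.dose_levels):
        records.extend(
            _simulate_group(design, truth, rng, dose, level_idx, design.animals_per_level)
        )
    if design.n_controls:
        records.extend(
            _simulate_group(design, truth, rng, 0.0, len(design.dose_levels),
                            design.n_controls, label_suffix="ctrl")
        )
    return records


def _simulate_group(
    design: CohortDesign,
    truth: TrueResponseParams,
    rng: np.random.Generator,
    dose: float,
    level_idx: int,
    n_animals: int,
    label_suffix: str = "",
) -> list[AnimalRecord]:
    horizon = design.followup_horizon
    p = truth.response_probability(dose, design.n_fractions) if dose > 0 else 0.0
    out = []
    for k in range(n_animals):
        u_resp = rng.uniform()
        u_lat = rng.uniform()
        u_cens = rng.uniform()
        responds = u_resp < p
        event_day = (
            _truncated_lognormal(u_lat, truth.latency_location, truth.latency_scale, horizon)
            if responds
            else None
        )
        if truth.censor_hazard > 0:
            censor_day = -math.log1p(-u_cens) / truth.censor_hazard
        else:
            censor_day = math.inf
        cutoff = event_day if responds else horizon
        tag = f"{design.radiation_label}-{design.n_fractions}fx-L{level_idx}{label_suffix}-{k:02d}"
        if censor_day < cutoff and censor_day < horizon:
            out.append(AnimalRecord(
                animal_id=tag,
                radiation_label=design.radiation_label,
                let_value=design.let_value,
                n_fractions=design.n_fractions,
                total_dose=dose,
                responder=False,
                event_day=None,
                followup_day=censor_day,
                excluded=True,
                exclusion_reason="intercurrent disease",
            ))
        else:
            out.append(AnimalRecord(
                animal_id=tag,
                radiation_label=design.radiation_label,
                let_value=design.let_value,
                n_fractions=design.n_fractions,
                total_dose=dose,
                responder=responds,
                event_day=event_day,
                followup_day=event_day if responds else horizon,
            ))
    return out


# --- built-in study design -------------------------------------------------

def _steps(lo: float, n: int, step: float = 1.0) -> tuple[float, ...]:
    return tuple(round(lo + step * i, 3) for i in range(n))


#: (label, LET keV/um, depth mm, n_fractions, dose levels Gy)
_TABLE1_ROWS = (
    ("O-26", 26.0, 35.0, 1, _steps(15.5, 6)),
    ("O-66", 66.0, 100.0, 1, _steps(12.5, 6)),
    ("O-98", 98.0, 120.0, 1, _steps(10.5, 6)),
    ("O-141", 141.0, 127.0, 1, _steps(12.5, 8)),
    ("O-26", 26.0, 35.0, 2, _steps(18.0, 8)),
    ("O-66", 66.0, 100.0, 2, _steps(15.0, 6)),
    ("O-98", 98.0, 120.0, 2, _steps(12.5, 6)),
    ("O-141", 141.0, 127.0, 2, _steps(12.0, 8)),
)

TABLE1_N_CONTROLS = 10


def design_from_table1() -> list[CohortDesign]:
    """The eight irradiated arms of the built-in study design.

    Four LET positions x two schedules, 5 animals per dose level.
    Controls are separate (see :func:`control_design`): 270 irradiated
    animals + 10 controls = 280.
    """
    return [
        CohortDesign(
            radiation_label=label,
            let_value=let,
            depth_mm=depth,
            n_fractions=nfx,
            dose_levels=levels,
        )
        for label, let, depth, nfx, levels in _TABLE1_ROWS
    ]


def control_design(n_controls: int = TABLE1_N_CONTROLS) -> CohortDesign:
    """Unirradiated control arm (single dose level 0 Gy, never responders)."""
    return CohortDesign(
        radiation_label="control",
        let_value=0.0,
        depth_mm=0.0,
        n_fractions=1,
        dose_levels=(0.0,),
        animals_per_level=n_controls,
    )


def simulate_table1(
    truth_by_let: dict[float, TrueResponseParams] | TrueResponseParams,
    seed: int,
) -> list[AnimalRecord]:
    """Simulate the full built-in design (all arms + controls, 280 records).

    ``truth_by_let`` maps LET to generating parameters; a single
    :class:`TrueResponseParams` is broadcast to every arm.  Each arm gets
    an independent child seed spawned from ``seed``.
    """
    designs = design_from_table1() + [control_design()]
    seeds = np.random.SeedSequence(seed).spawn(len(designs))
    records: list[AnimalRecord] = []
    for design, ss in zip(designs, seeds):
        if isinstance(truth_by_let, TrueResponseParams):
            truth = truth_by_let
        else:
            # controls fall back to any arm's truth; dose 0 never responds
            truth = truth_by_let.get(design.let_value,
                                     next(iter(truth_by_let.values())))
        records.extend(simulate_cohort(design, truth, np.random.default_rng(ss)))
    return records


def total_animals(designs: list[CohortDesign], n_controls: int = 0) -> int:
    """Count animals across arms plus external controls."""
    return sum(d.n_animals for d in designs) + n_controls
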