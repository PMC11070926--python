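"""Actuarial response rates and effective sample sizes.

Censored animal records are reduced to a per-dose-group response
probability by the product-limit estimator: responders contribute an
event at their latency day, excluded animals are censored at their last
follow-up day and non-responders remain at risk through the horizon.
The variance comes from Greenwood's formula and is converted into an
effective sample size n_eff = p(1-p)/var(p), the binomial sample size
carrying the same information; the logistic regressions downstream
consume (n_eff, r_eff = n_eff * p) as fractional counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .synthetic_cohort import AnimalRecord

__all__ = ["DoseGroupSummary", "actuarial_rate", "summarize_cohort"]


@dataclass(frozen=True)
class DoseGroupSummary:
    """Actuarial summary for one dose level of one arm."""

    radiation_label: str
    let_value: float
    n_fractions: int
    total_dose: float
    n_crude: int
    p_actuarial: float
    var_p: float
    n_eff: float
    r_eff: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_actuarial <= 1.0:
            raise ValueError("p_actuarial outside [0, 1]")
        if self.n_eff < 0 or self.r_eff < 0:
            raise ValueError("effective counts must be >= 0")


def actuarial_rate(records: list[AnimalRecord], horizon: float = 300.0) -> DoseGroupSummary:
    """Product-limit response probability for one dose group.

    All records must share dose, schedule and radiation quality.  Ties
    between an event day and a censoring day are resolved events-first
    (the standard product-limit convention).  Animals censored on day 0
    contribute no risk time and are dropped.  When p is 0 or 1 the
    Greenwood variance vanishes and n_eff falls back to the crude count
    so downstream weights stay defined.
    """
    if not records:
        raise ValueError("empty dose group")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    key = {(r.radiation_label, r.n_fractions, r.total_dose) for r in records}
    if len(key) != 1:
        raise ValueError("records mix dose groups: %r" % (sorted(key),))
    for r in records:
        if r.followup_day > horizon + 1e-9:
            raise ValueError(f"followup_day beyond horizon for {r.animal_id}")

    kept = [r for r in records if not (r.excluded and r.followup_day <= 0.0)]
    n_crude = len(kept)
    if n_crude == 0:
        raise ValueError("all animals excluded at day 0")

    # (time, is_event); events sorted before censorings at equal times
    times = sorted(
        ((r.event_day if r.responder else min(r.followup_day, horizon)),
         bool(r.responder))
        for r in kept
    )
    times.sort(key=lambda t: (t[0], not t[1]))

    surv = 1.0
    greenwood = 0.0
    at_risk = n_crude
    i = 0
    while i < len(times):
        t, _ = times[i]
        if t > horizon:
            break
        d = sum(1 for tt, ev in times[i:] if tt == t and ev)
        c = sum(1 for tt, ev in times[i:] if tt == t and not ev)
        if d > 0:
            surv *= 1.0 - d / at_risk
            if at_risk > d:
                greenwood += d / (at_risk * (at_risk - d))
        at_risk -= d + c
        i += d + c

    p = 1.0 - surv
    p = min(max(p, 0.0), 1.0)
    var_p = surv * surv * greenwood  # Greenwood: var(S) = var(1 - S)

    if 0.0 < p < 1.0 and var_p > 0.0:
        n_eff = p * (1.0 - p) / var_p
    else:
        n_eff = float(n_crude)
        var_p = p * (1.0 - p) / n_crude if 0.0 < p < 1.0 else 0.0
    r_eff = n_eff * p

    first = kept[0]
    return DoseGroupSummary(
        radiation_label=first.radiation_label,
        let_value=first.let_value,
        n_fractions=first.n_fractions,
        total_dose=first.total_dose,
        n_crude=n_crude,
        p_actuarial=p,
        var_p=var_p,
        n_eff=n_eff,
        r_eff=r_eff,
    )


def summarize_cohort(records: list[AnimalRecord], horizon: float = 300.0) -> list[DoseGroupSummary]:
    """Group records by (label, schedule, dose) and summarize each group.

    Groups are returned sorted by label, schedule and dose.
    """
    groups: dict[tuple, list[AnimalRecord]] = {}
    for r in records:
        groups.setdefault((r.radiation_label, r.n_fractions, r.total_dose), []).append(r)
    out = []
    for key in sorted(groups):
        out.append(actuarial_rate(groups[key], horizon))
    return out
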