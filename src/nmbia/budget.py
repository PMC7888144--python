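"""Budget-impact engine: drug costs, expected events, offsets, net savings.

For every reporting row of the decision tree the engine prices both
scenarios, applies the per-procedure clinical cost offset to the procedures
that actually receive sugammadex, and aggregates to national totals and
per-procedure averages.  The defining identity, per row and in total, is

    net saving = clinical cost offsets - (alternative drug cost - prior drug cost)

where the offset is either computed from the event-risk differences and unit
costs (``from_components``) or fixed to a calibrated per-procedure value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cohort import (
    PriorAgent,
    PriorStrategy,
    Stratum,
    StratumCount,
    nmba_procedure_count,
    stratify,
    sugammadex_by_row,
    sugammadex_population,
    total_annual_procedures,
)
from .parameters import (
    ELIGIBLE_ROW_KEYS,
    DrugCostParams,
    EventParams,
    ModelParameters,
    ParameterError,
    round_currency,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EVENT_TYPES",
    "scenario_drug_cost",
    "per_procedure_offset",
    "calibrate_atelectasis_cost",
    "effective_events",
    "expected_events",
    "stratum_budget_impact",
    "aggregate",
    "BudgetImpactRow",
    "BudgetImpactReport",
    "evaluate",
]

EVENT_TYPES = ("atelectasis", "pneumonia")


def scenario_drug_cost(stratum: Stratum, scenario: str,
                       drugs: DrugCostParams) -> float:
    """Per-procedure drug acquisition cost for one stratum and scenario.

    Prior scenario: the blocking agent (switched-cisatracurium cells are
    priced at the cisatracurium cost, which defaults to the rocuronium cost)
    plus neostigmine/atropine when the prior strategy used it.  Alternative
    scenario: rocuronium plus the sugammadex dose for the stratum's block
    depth.
    """
    if scenario == "prior":
        if stratum.prior_agent is PriorAgent.cisatracurium_switched:
            cost = drugs.cisatracurium_cost
        else:
            cost = drugs.rocuronium
        if stratum.prior_strategy is PriorStrategy.neostigmine:
            cost += drugs.neostigmine_atropine
        return cost
    if scenario == "alternative":
        return drugs.rocuronium + drugs.sugammadex(stratum.block_depth.value)
    raise ParameterError(f"unknown scenario '{scenario}'")


def per_procedure_offset(events: EventParams) -> float:
    """Per-procedure clinical cost offset of using sugammadex.

    ``from_components``: sum over event types of risk difference times unit
    cost.  ``calibrated``: the fixed calibrated offset.  A negative risk
    difference (sugammadex riskier) is allowed but logged as a harm scenario.
    """
    if events.offset_mode == "calibrated":
        return float(events.calibrated_offset)
    total = 0.0
    for name, ev in events.types.items():
        if ev.risk_difference < 0:
            logger.warning("negative risk difference for %s (harm scenario): %.6f",
                           name, ev.risk_difference)
        total += ev.risk_difference * ev.unit_cost
    return total


def calibrate_atelectasis_cost(target_offset: float, events: EventParams) -> float:
    """Atelectasis unit cost that reconciles the components with a target offset.

    Keeps the pneumonia component fixed and solves
    ``target = d_atel * cost_atel + d_pneu * cost_pneu`` for ``cost_atel``.
    """
    d_atel = events.atelectasis.risk_difference
    if d_atel == 0:
        raise ParameterError("atelectasis risk difference is zero; cannot calibrate")
    pneumonia_component = events.pneumonia.risk_difference * events.pneumonia.unit_cost
    return (target_offset - pneumonia_component) / d_atel


def effective_events(events: EventParams) -> EventParams:
    """Event parameters with the offset re-expressed through components.

    In calibrated mode the atelectasis unit cost is replaced by the value
    implied by the calibrated offset, so that component-level computations
    (sensitivity analysis, microsimulation) reproduce the calibrated offset
    at base values and respond to perturbations.  In ``from_components`` mode
    the parameters are returned unchanged.
    """
    if events.offset_mode == "from_components":
        return events
    implied = calibrate_atelectasis_cost(events.calibrated_offset, events)
    logger.warning(
        "calibrated offset %.2f implies an atelectasis unit cost of %.2f "
        "(configured unit cost %.2f is not used in component form)",
        events.calibrated_offset, implied, events.atelectasis.unit_cost)
    return events.model_copy(update={
        "atelectasis": events.atelectasis.model_copy(update={"unit_cost": implied}),
        "offset_mode": "from_components",
        "calibrated_offset": None,
    })


def expected_events(n: float, risk: float) -> float:
    """Expected number of events among ``n`` procedures at the given risk."""
    if n < 0:
        raise ParameterError(f"procedure count must be >= 0, got {n}")
    return n * risk


@dataclass
class BudgetImpactRow:
    """National budget impact of one reporting row (Tables 4/5 shape).

    ``prior_drug_cost``, ``alternative_drug_cost``, ``offsets`` and
    ``net_saving`` are annual national euros over the row's sugammadex-using
    procedures; the ``unit_*`` fields are the corresponding per-procedure
    values.  ``events`` maps event type to (prior, alternative) expected
    counts among sugammadex users.
    """

    row_key: str
    n_sugammadex: int
    prior_drug_cost: float
    alternative_drug_cost: float
    offsets: float
    unit_prior: float = 0.0
    unit_alternative: float = 0.0
    unit_offset: float = 0.0
    events: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def net_saving(self) -> float:
        return self.offsets - (self.alternative_drug_cost - self.prior_drug_cost)

    @property
    def unit_net(self) -> float:
        return self.unit_offset - (self.unit_alternative - self.unit_prior)


def stratum_budget_impact(counts: list[StratumCount], row_key: str,
                          drugs: DrugCostParams,
                          events: EventParams) -> BudgetImpactRow:
    """Budget impact of one reporting row from its agent-level cells.

    Per-procedure quantities are the sugammadex-count-weighted averages over
    the row's cells (they differ between cells only if a distinct
    cisatracurium cost is configured); national quantities are per-procedure
    values times the row's sugammadex count.  Offsets and expected events are
    attributed to sugammadex-using procedures only.
    """
    cells = [sc for sc in counts
             if sc.stratum.is_eligible and sc.stratum.row_key == row_key]
    if not cells:
        raise ParameterError(f"no eligible cells for row '{row_key}'")
    n = sum(sc.sugammadex_count for sc in cells)
    prior = sum(scenario_drug_cost(sc.stratum, "prior", drugs) * sc.sugammadex_count
                for sc in cells)
    alt = sum(scenario_drug_cost(sc.stratum, "alternative", drugs) * sc.sugammadex_count
              for sc in cells)
    offset = per_procedure_offset(events)
    ev = {name: (expected_events(n, t.risk_no_sugammadex),
                 expected_events(n, t.risk_sugammadex))
          for name, t in events.types.items()}
    return BudgetImpactRow(
        row_key=row_key,
        n_sugammadex=n,
        prior_drug_cost=prior,
        alternative_drug_cost=alt,
        offsets=offset * n,
        unit_prior=prior / n if n else scenario_drug_cost(cells[0].stratum, "prior", drugs),
        unit_alternative=alt / n if n else scenario_drug_cost(cells[0].stratum,
                                                              "alternative", drugs),
        unit_offset=offset,
        events=ev,
    )


@dataclass
class BudgetImpactReport:
    """Aggregated national budget impact with per-procedure averages."""

    rows: list[BudgetImpactRow]
    total_prior_drug_cost: float
    total_alternative_drug_cost: float
    total_offsets: float
    total_net_saving: float
    n_sugammadex: int
    n_all_procedures: int
    avg_per_sugammadex: dict[str, float]
    avg_per_all_procedures: dict[str, float]
    events_prior: dict[str, float]
    events_alternative: dict[str, float]
    events_avoided: dict[str, float]

    @property
    def total_events_avoided(self) -> float:
        return sum(self.events_avoided.values())


def aggregate(rows: list[BudgetImpactRow],
              denominators: dict[str, int]) -> BudgetImpactReport:
    """Sum rows to national totals and divide by the stated denominators.

    ``denominators`` must provide ``sugammadex_total`` and
    ``all_procedures_total``.  Averages are rounded to cents; totals are kept
    at full precision.
    """
    if not rows:
        raise ParameterError("cannot aggregate an empty row list")
    n_sug = denominators["sugammadex_total"]
    n_all = denominators["all_procedures_total"]
    if n_sug <= 0 or n_all <= 0:
        raise ParameterError("aggregation denominators must be positive")

    prior = sum(r.prior_drug_cost for r in rows)
    alt = sum(r.alternative_drug_cost for r in rows)
    offsets = sum(r.offsets for r in rows)
    net = offsets - (alt - prior)

    def averages(denom: int) -> dict[str, float]:
        return {
            "prior_drug_cost": round_currency(prior / denom),
            "alternative_drug_cost": round_currency(alt / denom),
            "offsets": round_currency(offsets / denom),
            "net_saving": round_currency(net / denom),
        }

    ev_prior = {t: sum(r.events.get(t, (0.0, 0.0))[0] for r in rows) for t in EVENT_TYPES}
    ev_alt = {t: sum(r.events.get(t, (0.0, 0.0))[1] for r in rows) for t in EVENT_TYPES}
    return BudgetImpactReport(
        rows=rows,
        total_prior_drug_cost=prior,
        total_alternative_drug_cost=alt,
        total_offsets=offsets,
        total_net_saving=net,
        n_sugammadex=n_sug,
        n_all_procedures=n_all,
        avg_per_sugammadex=averages(n_sug),
        avg_per_all_procedures=averages(n_all),
        events_prior=ev_prior,
        events_alternative=ev_alt,
        events_avoided={t: ev_prior[t] - ev_alt[t] for t in EVENT_TYPES},
    )


def evaluate(params: ModelParameters,
             all_procedures_denominator: int | None = None) -> BudgetImpactReport:
    """Run the full pipeline: volumes -> strata -> budget-impact report."""
    total = total_annual_procedures(params.volumes)
    nmba = nmba_procedure_count(total, params.population.p_nmba)
    strata = stratify(nmba, params.population, params.mix)
    strata = sugammadex_population(strata, params.adoption)
    n_sug = sum(sugammadex_by_row(strata).values())
    rows = [stratum_budget_impact(strata, key, params.drugs, params.events)
            for key in ELIGIBLE_ROW_KEYS]
    denom_all = all_procedures_denominator or max(total, 1)
    return aggregate(rows, {"sugammadex_total": n_sug or 1,
                            "all_procedures_total": denom_all})
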