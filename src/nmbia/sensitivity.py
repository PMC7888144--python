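"""One-way deterministic sensitivity analysis with tornado ranking.

Each model parameter named in the published analysis is varied one at a time
to 50% and 150% of its base value (probabilities clamped to [0, 1]), the full
pipeline is re-run, and parameters are ranked by the width of the resulting
net-saving range.  Under the calibrated offset the event risks and unit
costs are first re-expressed through the implied atelectasis cost
(:func:`nmbia.budget.effective_events`) so that perturbing them actually
moves the offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .budget import effective_events, evaluate
from .cohort import eligible_by_row, nmba_procedure_count, stratify, total_annual_procedures
from .parameters import ELIGIBLE_ROW_KEYS, ModelParameters, ParameterError, round_count

logger = logging.getLogger(__name__)

__all__ = [
    "DSA_PARAMETER_IDS",
    "DsaParameterSpec",
    "DsaResult",
    "default_dsa_specs",
    "perturb",
    "run_one_way_dsa",
    "tornado_table",
]

DSA_PARAMETER_IDS = (
    "p_nmba",
    "event_risks",
    "event_unit_costs",
    "sugammadex_uptake_moderate",
    "p_switch_cisatracurium",
    "rocuronium_share_per_arm",
)


@dataclass(frozen=True)
class DsaParameterSpec:
    """One parameter (or joint parameter family) to vary one-way."""

    parameter_id: str
    low_multiplier: float = 0.5
    high_multiplier: float = 1.5

    def __post_init__(self) -> None:
        if self.parameter_id not in DSA_PARAMETER_IDS:
            raise ParameterError(f"unknown DSA parameter '{self.parameter_id}'")
        if self.low_multiplier <= 0 or self.high_multiplier <= 0:
            raise ParameterError("DSA multipliers must be positive")


@dataclass(frozen=True)
class DsaResult:
    """Net savings at the low and high perturbation of one parameter."""

    parameter_id: str
    net_at_low: float
    net_at_high: float
    rank: int = 0

    @property
    def range(self) -> float:
        return abs(self.net_at_high - self.net_at_low)


def default_dsa_specs() -> list[DsaParameterSpec]:
    """The published +/-50% one-way analysis over all six parameters."""
    return [DsaParameterSpec(pid) for pid in DSA_PARAMETER_IDS]


def _clamp_prob(value: float, context: str) -> float:
    if value > 1.0:
        logger.warning("%s: %.4f exceeds 1 after perturbation; clamped to 1",
                       context, value)
        return 1.0
    return max(value, 0.0)


def _perturb_arm(arm, m: float):
    """Scale an arm's rocuronium share; 'other agents' absorbs the residual.

    If the scaled rocuronium plus cisatracurium shares exceed 1 even with the
    'other' share floored at 0, both are renormalized proportionally (with a
    warning) so the arm stays a valid share vector.
    """
    roc = arm.rocuronium * m
    cis = arm.cisatracurium
    other = 1.0 - roc - cis
    if other < 0:
        logger.warning(
            "rocuronium share perturbation x%.2f makes shares infeasible "
            "(rocuronium %.4f + cisatracurium %.4f > 1); renormalizing", m, roc, cis)
        scale = 1.0 / (roc + cis)
        roc, cis, other = roc * scale, cis * scale, 0.0
    return arm.model_copy(update={"rocuronium": roc, "cisatracurium": cis,
                                  "other": other})


def perturb(params: ModelParameters, spec: DsaParameterSpec,
            which: str) -> ModelParameters:
    """Return a copy of ``params`` with one DSA parameter scaled.

    Only the targeted value (and, for agent shares, the absorbing 'other'
    share) differs from the base; probabilities are clamped to [0, 1] with a
    warning rather than failing.
    """
    if which not in ("low", "high"):
        raise ParameterError(f"perturbation side must be 'low' or 'high', got '{which}'")
    m = spec.low_multiplier if which == "low" else spec.high_multiplier
    pid = spec.parameter_id

    if pid in ("event_risks", "event_unit_costs"):
        params = params.model_copy(update={"events": effective_events(params.events)})

    if pid == "p_nmba":
        pop = params.population.model_copy(update={
            "p_nmba": _clamp_prob(params.population.p_nmba * m, "p_nmba")})
        return params.model_copy(update={"population": pop})

    if pid == "event_risks":
        updates = {}
        for name, ev in params.events.types.items():
            updates[name] = ev.model_copy(update={
                "risk_no_sugammadex": _clamp_prob(ev.risk_no_sugammadex * m,
                                                  f"{name}.risk_no_sugammadex"),
                "risk_sugammadex": _clamp_prob(ev.risk_sugammadex * m,
                                               f"{name}.risk_sugammadex"),
            })
        return params.model_copy(update={"events": params.events.model_copy(update=updates)})

    if pid == "event_unit_costs":
        updates = {name: ev.model_copy(update={"unit_cost": ev.unit_cost * m})
                   for name, ev in params.events.types.items()}
        return params.model_copy(update={"events": params.events.model_copy(update=updates)})

    if pid == "sugammadex_uptake_moderate":
        adoption = params.adoption
        moderate_rows = [k for k in ELIGIBLE_ROW_KEYS if k.startswith("moderate/")]
        if adoption.mode == "fractional":
            uptake = dict(adoption.uptake)
            for key in moderate_rows:
                uptake[key] = _clamp_prob(uptake[key] * m, f"uptake[{key}]")
            return params.model_copy(update={
                "adoption": adoption.model_copy(update={"uptake": uptake})})
        # direct_counts: scale the moderate-row counts, capping at the
        # eligible count only where the base count did not already exceed it
        # (the published neostigmine-row calibration does).
        eligible = eligible_by_row(stratify(
            nmba_procedure_count(total_annual_procedures(params.volumes),
                                 params.population.p_nmba),
            params.population, params.mix))
        counts = dict(adoption.counts)
        for key in moderate_rows:
            scaled = round_count(counts[key] * m)
            if counts[key] <= eligible[key] and scaled > eligible[key]:
                logger.warning("uptake perturbation capped at eligible count for "
                               "row '%s' (%d -> %d)", key, scaled, eligible[key])
                scaled = eligible[key]
            counts[key] = scaled
        return params.model_copy(update={
            "adoption": adoption.model_copy(update={"counts": counts})})

    if pid == "p_switch_cisatracurium":
        mix = params.mix.model_copy(update={
            "p_switch_cisatracurium": _clamp_prob(
                params.mix.p_switch_cisatracurium * m, "p_switch_cisatracurium")})
        return params.model_copy(update={"mix": mix})

    if pid == "rocuronium_share_per_arm":
        mix = params.mix.model_copy(update={
            "agents_no_reversal": _perturb_arm(params.mix.agents_no_reversal, m),
            "agents_neostigmine": _perturb_arm(params.mix.agents_neostigmine, m),
        })
        return params.model_copy(update={"mix": mix})

    raise ParameterError(f"unknown DSA parameter '{pid}'")


def _rescale_direct_counts(base: ModelParameters,
                           perturbed: ModelParameters) -> ModelParameters:
    """Hold the implied uptake fixed when a perturbation moves eligible counts.

    In ``direct_counts`` adoption the sugammadex counts are calibration
    constants; a perturbation that changes the eligible population (p_nmba,
    switch probability, agent shares) is taken to scale usage proportionally,
    so each row's count is multiplied by the ratio of perturbed to base
    eligible counts.
    """
    if base.adoption.mode != "direct_counts":
        return perturbed

    def eligible(p: ModelParameters) -> dict[str, int]:
        nmba = nmba_procedure_count(total_annual_procedures(p.volumes),
                                    p.population.p_nmba)
        return eligible_by_row(stratify(nmba, p.population, p.mix))

    base_rows, pert_rows = eligible(base), eligible(perturbed)
    if base_rows == pert_rows:
        return perturbed
    counts = dict(perturbed.adoption.counts)
    for key in ELIGIBLE_ROW_KEYS:
        ratio = pert_rows[key] / base_rows[key] if base_rows[key] else 0.0
        counts[key] = round_count(counts[key] * ratio)
    return perturbed.model_copy(update={
        "adoption": perturbed.adoption.model_copy(update={"counts": counts})})


def run_one_way_dsa(params: ModelParameters,
                    specs: list[DsaParameterSpec] | None = None,
                    all_procedures_denominator: int | None = None) -> list[DsaResult]:
    """Re-run the full pipeline at the low and high value of every parameter.

    Returns one :class:`DsaResult` per spec with ranks assigned by
    descending net-saving range (ties broken by parameter id).  The output
    is deterministic: the model itself has no randomness.
    """
    if specs is None:
        specs = default_dsa_specs()
    results = []
    for spec in specs:
        nets = {}
        for which in ("low", "high"):
            try:
                perturbed = _rescale_direct_counts(
                    params, perturb(params, spec, which))
                nets[which] = evaluate(
                    perturbed, all_procedures_denominator).total_net_saving
            except Exception as exc:
                raise ParameterError(
                    f"DSA evaluation failed for parameter "
                    f"'{spec.parameter_id}' ({which})") from exc
        results.append(DsaResult(spec.parameter_id, nets["low"], nets["high"]))
    order = sorted(range(len(results)),
                   key=lambda i: (-results[i].range, results[i].parameter_id))
    ranked = [None] * len(results)
    for rank, i in enumerate(order, start=1):
        r = results[i]
        ranked[i] = DsaResult(r.parameter_id, r.net_at_low, r.net_at_high, rank)
    return ranked


def tornado_table(results: list[DsaResult],
                  base_net: float | None = None) -> pd.DataFrame:
    """Tornado-ordered table of DSA results (widest range first)."""
    if not results:
        raise ParameterError("tornado_table requires at least one result")
    df = pd.DataFrame(
        [{"parameter_id": r.parameter_id, "net_low": r.net_at_low,
          "net_high": r.net_at_high, "range": r.range, "rank": r.rank}
         for r in results]
    ).sort_values("rank").reset_index(drop=True)
    if base_net is not None:
        df["base_net"] = base_net
    return df
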