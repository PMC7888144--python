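"""Decision-tree cohort model: from annual procedure volumes to stratum counts.

The tree splits the procedures that use a neuromuscular blocking agent by
block depth at the end of surgery (moderate / deep), by prior reversal
strategy (no pharmacological reversal / neostigmine) and by prior blocking
agent (rocuronium, or cisatracurium switched to rocuronium so that sugammadex
becomes usable).  Deep block cannot be reversed with neostigmine, so the
(deep, neostigmine) cells are retained only for bookkeeping with zero
eligible count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

from .parameters import (
    ELIGIBLE_ROW_KEYS,
    AdoptionParams,
    ParameterError,
    PopulationParams,
    ProcedureVolumeTable,
    ReversalMixParams,
    implied_uptake,
    round_count,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BlockDepth",
    "PriorStrategy",
    "PriorAgent",
    "Stratum",
    "StratumCount",
    "CalibrationError",
    "total_annual_procedures",
    "nmba_procedure_count",
    "stratify",
    "sugammadex_population",
    "eligible_by_row",
    "sugammadex_by_row",
]


class BlockDepth(str, Enum):
    moderate = "moderate"
    deep = "deep"


class PriorStrategy(str, Enum):
    no_reversal = "no_reversal"
    neostigmine = "neostigmine"


class PriorAgent(str, Enum):
    rocuronium_native = "rocuronium_native"
    cisatracurium_switched = "cisatracurium_switched"


class CalibrationError(ParameterError):
    """Direct sugammadex counts are inconsistent with eligible counts."""


@dataclass(frozen=True)
class Stratum:
    """One (block depth, prior strategy, prior agent) cell of the tree."""

    block_depth: BlockDepth
    prior_strategy: PriorStrategy
    prior_agent: PriorAgent

    @property
    def is_eligible(self) -> bool:
        """Whether sugammadex substitution is modelled for this cell."""
        return not (self.block_depth is BlockDepth.deep
                    and self.prior_strategy is PriorStrategy.neostigmine)

    @property
    def row_key(self) -> str:
        """Reporting-row key, e.g. ``moderate/no_reversal``."""
        return f"{self.block_depth.value}/{self.prior_strategy.value}"


@dataclass
class StratumCount:
    """A stratum with its annual eligible and sugammadex-using counts."""

    stratum: Stratum
    eligible_count: int
    sugammadex_count: int = 0


#: Fixed cell order: eligible rows first, bookkeeping (deep, neostigmine) last.
ALL_STRATA: tuple[Stratum, ...] = tuple(
    Stratum(BlockDepth(d), PriorStrategy(s), agent)
    for d, s in [k.split("/") for k in ELIGIBLE_ROW_KEYS] + [["deep", "neostigmine"]]
    for agent in PriorAgent
)


def total_annual_procedures(volumes: ProcedureVolumeTable) -> int:
    """Exact sum of the annual procedure counts."""
    return volumes.total


def nmba_procedure_count(total: int, p_nmba: float) -> int:
    """Annual procedures using a neuromuscular blocking agent."""
    if total < 0:
        raise ParameterError(f"total procedures must be >= 0, got {total}")
    return round_count(total * p_nmba)


def _branch_share(stratum: Stratum, population: PopulationParams,
                  mix: ReversalMixParams) -> float:
    depth = (population.p_moderate if stratum.block_depth is BlockDepth.moderate
             else population.p_deep)
    strategy = (mix.p_no_reversal if stratum.prior_strategy is PriorStrategy.no_reversal
                else mix.p_neostigmine)
    arm = mix.arm(stratum.prior_strategy.value)
    if stratum.prior_agent is PriorAgent.rocuronium_native:
        agent = arm.rocuronium
    else:
        agent = arm.cisatracurium * mix.p_switch_cisatracurium
    return depth * strategy * agent


def stratify(nmba_count: int, population: PopulationParams,
             mix: ReversalMixParams) -> list[StratumCount]:
    """Eligible procedure counts per cell of the decision tree.

    Each cell's count is the NMBA procedure count times the product of its
    branch probabilities, rounded to the nearest integer at the cell level;
    switched-cisatracurium cells additionally carry the switch probability.
    (deep, neostigmine) cells get zero eligible count.
    """
    out = []
    for stratum in ALL_STRATA:
        if not stratum.is_eligible:
            out.append(StratumCount(stratum, 0))
            continue
        share = _branch_share(stratum, population, mix)
        out.append(StratumCount(stratum, round_count(nmba_count * share)))
    return out


def eligible_by_row(strata: list[StratumCount]) -> dict[str, int]:
    """Eligible counts aggregated to reporting rows."""
    rows = {key: 0 for key in ELIGIBLE_ROW_KEYS}
    for sc in strata:
        if sc.stratum.is_eligible:
            rows[sc.stratum.row_key] += sc.eligible_count
    return rows


def sugammadex_by_row(strata: list[StratumCount]) -> dict[str, int]:
    """Sugammadex-using counts aggregated to reporting rows."""
    rows = {key: 0 for key in ELIGIBLE_ROW_KEYS}
    for sc in strata:
        if sc.stratum.is_eligible:
            rows[sc.stratum.row_key] += sc.sugammadex_count
    return rows


def _distribute(total: int, weights: list[int]) -> list[int]:
    """Split ``total`` across cells proportionally to ``weights``.

    Rounds each part to the nearest integer, then corrects any residual on
    the heaviest cell so that the parts always sum exactly to ``total``.
    """
    wsum = sum(weights)
    if wsum == 0:
        parts = [0] * len(weights)
        if total:
            parts[0] = total
        return parts
    parts = [round_count(total * w / wsum) for w in weights]
    residual = total - sum(parts)
    if residual:
        parts[max(range(len(parts)), key=lambda i: weights[i])] += residual
    return parts


def sugammadex_population(strata: list[StratumCount],
                          adoption: AdoptionParams) -> list[StratumCount]:
    """Fill sugammadex-using counts according to the adoption parameters.

    In ``fractional`` mode each eligible cell receives ``round(eligible x
    uptake)`` of its row's uptake.  In ``direct_counts`` mode the given row
    totals are distributed across the row's agent cells proportionally to
    their eligible counts; a row count exceeding the eligible count raises
    :class:`CalibrationError` unless the adoption allows the overrun, in
    which case it is logged as a warning.
    """
    out = [replace(sc) for sc in strata]
    rows = eligible_by_row(strata)

    if adoption.mode == "fractional":
        for sc in out:
            if sc.stratum.is_eligible:
                uptake = adoption.uptake[sc.stratum.row_key]
                sc.sugammadex_count = round_count(sc.eligible_count * uptake)
        return out

    for key in ELIGIBLE_ROW_KEYS:
        target = adoption.counts[key]
        if target > rows[key]:
            msg = (f"direct sugammadex count for row '{key}' ({target}) exceeds "
                   f"the eligible count ({rows[key]})")
            if not adoption.allow_count_overrun:
                raise CalibrationError(msg)
            logger.warning("%s; keeping the calibrated count", msg)
        cells = [sc for sc in out
                 if sc.stratum.is_eligible and sc.stratum.row_key == key]
        parts = _distribute(target, [sc.eligible_count for sc in cells])
        for sc, part in zip(cells, parts):
            sc.sugammadex_count = part

    uptakes = implied_uptake({k: float(v) for k, v in rows.items()}, adoption)
    logger.info("implied sugammadex uptake by row: %s",
                {k: round(v, 4) for k, v in uptakes.items()})
    return out
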