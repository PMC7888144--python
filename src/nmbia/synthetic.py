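"""Randomized parameter sets and a patient-level Monte Carlo oracle.

The deterministic engine computes expected values analytically; the
microsimulation here re-derives the same quantities by sampling individual
procedures, drawing post-operative event indicators in both scenarios and
accumulating drug and event costs.  Agreement of the sampled mean net saving
with the deterministic per-procedure value (within Monte Carlo error)
validates the cohort arithmetic end to end without any external data.

:func:`generate_parameter_set` draws fully valid :class:`ModelParameters`
with the model's statistical structure — strata shares summing to one,
per-scenario Bernoulli event risks, positive unit costs — for property
tests over many seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .budget import effective_events, scenario_drug_cost
from .cohort import StratumCount
from .parameters import (
    ELIGIBLE_ROW_KEYS,
    AdoptionParams,
    AgentShares,
    DrugCostParams,
    EventParams,
    EventRisk,
    ModelParameters,
    ParameterError,
    PopulationParams,
    ProcedureVolumeTable,
    ReversalMixParams,
    VolumeEntry,
)

__all__ = ["GeneratorConfig", "generate_parameter_set", "MicrosimResult", "microsimulate"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ranges for the randomized parameter generator (uniform draws)."""

    seed: int
    n_categories: int = 15
    volume_range: tuple[int, int] = (20_000, 120_000)
    p_nmba_range: tuple[float, float] = (0.5, 0.9)
    p_moderate_range: tuple[float, float] = (0.6, 0.9)
    p_no_reversal_range: tuple[float, float] = (0.4, 0.8)
    uptake_range: tuple[float, float] = (0.2, 0.9)
    rocuronium_cost_range: tuple[float, float] = (1.0, 5.0)
    neostigmine_cost_range: tuple[float, float] = (0.2, 1.0)
    sugammadex_moderate_cost_range: tuple[float, float] = (30.0, 120.0)
    risk_no_sugammadex_range: tuple[float, float] = (0.02, 0.15)
    event_cost_range: tuple[float, float] = (1_000.0, 9_000.0)
    #: draw risk_sugammadex below risk_no_sugammadex (benefit direction)
    enforce_risk_ordering: bool = True

    def __post_init__(self) -> None:
        for name in ("volume_range", "p_nmba_range", "p_moderate_range",
                     "p_no_reversal_range", "uptake_range",
                     "rocuronium_cost_range", "neostigmine_cost_range",
                     "sugammadex_moderate_cost_range",
                     "risk_no_sugammadex_range", "event_cost_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ParameterError(f"infeasible range for {name}: ({lo}, {hi})")
        for name in ("p_nmba_range", "p_moderate_range", "p_no_reversal_range",
                     "uptake_range", "risk_no_sugammadex_range"):
            if getattr(self, name)[1] > 1:
                raise ParameterError(f"{name} must stay within [0, 1]")


def _uniform(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    return float(rng.uniform(*lo_hi))


def _shares(rng: np.random.Generator) -> AgentShares:
    raw = rng.uniform(0.05, 1.0, size=3)
    roc, cis, other = (raw / raw.sum()).tolist()
    # absorb float residue so the shares sum to 1 within validator tolerance
    other = 1.0 - roc - cis
    return AgentShares(rocuronium=roc, cisatracurium=cis, other=other)


def generate_parameter_set(config: GeneratorConfig) -> ModelParameters:
    """Draw a random, fully validated parameter set (deterministic by seed)."""
    rng = np.random.default_rng(config.seed)
    volumes = ProcedureVolumeTable(entries=[
        VolumeEntry(category=f"procedure_{i:02d}",
                    annual_count=int(rng.integers(*config.volume_range)))
        for i in range(config.n_categories)
    ])
    p_moderate = _uniform(rng, config.p_moderate_range)
    population = PopulationParams(p_nmba=_uniform(rng, config.p_nmba_range),
                                  p_moderate=p_moderate, p_deep=1.0 - p_moderate)
    p_no_rev = _uniform(rng, config.p_no_reversal_range)
    mix = ReversalMixParams(
        p_no_reversal=p_no_rev,
        p_neostigmine=1.0 - p_no_rev,
        agents_no_reversal=_shares(rng),
        agents_neostigmine=_shares(rng),
        p_switch_cisatracurium=float(rng.uniform(0.0, 1.0)),
    )
    adoption = AdoptionParams(mode="fractional", uptake={
        key: _uniform(rng, config.uptake_range) for key in ELIGIBLE_ROW_KEYS})
    sug_moderate = _uniform(rng, config.sugammadex_moderate_cost_range)
    drugs = DrugCostParams(
        rocuronium=_uniform(rng, config.rocuronium_cost_range),
        neostigmine_atropine=_uniform(rng, config.neostigmine_cost_range),
        sugammadex_moderate=sug_moderate,
        sugammadex_deep=2.0 * sug_moderate,
    )

    def event() -> EventRisk:
        r_ns = _uniform(rng, config.risk_no_sugammadex_range)
        r_s = float(rng.uniform(0.0, r_ns if config.enforce_risk_ordering
                                else config.risk_no_sugammadex_range[1]))
        return EventRisk(risk_no_sugammadex=r_ns, risk_sugammadex=r_s,
                         unit_cost=_uniform(rng, config.event_cost_range))

    events = EventParams(atelectasis=event(), pneumonia=event(),
                         offset_mode="from_components")
    return ModelParameters(volumes=volumes, population=population, mix=mix,
                           adoption=adoption, drugs=drugs, events=events)


@dataclass
class MicrosimResult:
    """Summary of a seeded patient-level simulation."""

    n_draws: int
    seed: int
    mean_net_saving: float
    se_net_saving: float
    #: event counts per type, keys like "atelectasis/prior"
    event_counts: dict[str, int] = field(default_factory=dict)
    mean_incremental_drug_cost: float = 0.0
    mean_event_saving: float = 0.0


def microsimulate(strata: list[StratumCount], params: ModelParameters,
                  n_draws: int, seed: int,
                  common_random_numbers: bool = False) -> MicrosimResult:
    """Sample individual sugammadex-treated procedures in both scenarios.

    Procedures are drawn from the eligible strata proportionally to their
    sugammadex counts.  For each draw, event indicators per type are sampled
    under the prior-scenario risks and under the sugammadex risks
    (independent draws by default; with ``common_random_numbers`` the same
    uniforms drive both scenarios, reducing variance), and the net saving is
    the event-cost saving minus the incremental drug cost.  The mean over
    draws estimates the deterministic per-procedure net saving.
    """
    if n_draws < 1:
        raise ParameterError(f"n_draws must be >= 1, got {n_draws}")
    cells = [sc for sc in strata if sc.stratum.is_eligible and sc.sugammadex_count > 0]
    if not cells:
        raise ParameterError("no sugammadex-using strata to simulate")

    rng = np.random.default_rng(seed)
    weights = np.array([sc.sugammadex_count for sc in cells], dtype=float)
    probs = weights / weights.sum()
    prior_cost = np.array([scenario_drug_cost(sc.stratum, "prior", params.drugs)
                           for sc in cells])
    alt_cost = np.array([scenario_drug_cost(sc.stratum, "alternative", params.drugs)
                         for sc in cells])
    idx = rng.choice(len(cells), size=n_draws, p=probs)
    drug_saving = prior_cost[idx] - alt_cost[idx]

    events = effective_events(params.events)
    event_saving = np.zeros(n_draws)
    counts: dict[str, int] = {}
    for name, ev in events.types.items():
        u_prior = rng.random(n_draws)
        u_alt = u_prior if common_random_numbers else rng.random(n_draws)
        prior_hit = u_prior < ev.risk_no_sugammadex
        alt_hit = u_alt < ev.risk_sugammadex
        event_saving += (prior_hit.astype(float) - alt_hit.astype(float)) * ev.unit_cost
        counts[f"{name}/prior"] = int(prior_hit.sum())
        counts[f"{name}/alternative"] = int(alt_hit.sum())

    net = event_saving + drug_saving
    se = float(net.std(ddof=1) / np.sqrt(n_draws)) if n_draws > 1 else float("inf")
    return MicrosimResult(
        n_draws=n_draws,
        seed=seed,
        mean_net_saving=float(net.mean()),
        se_net_saving=se,
        event_counts=counts,
        mean_incremental_drug_cost=float(-drug_saving.mean()),
        mean_event_saving=float(event_saving.mean()),
    )
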