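"""Bit-stable table exports, run summaries and manifests.

Exports mirror the three published result tables: per-procedure budget
impact, annual national budget impact, and post-operative events avoided.
Numbers are formatted with two decimals for euros and plain integers for
counts ('.' decimal separator, no thousands separators) so that repeated
runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .budget import EVENT_TYPES, BudgetImpactReport
from .cohort import StratumCount
from .parameters import round_count, round_currency

__all__ = ["RunManifest", "warning_collector", "write_strata_table",
           "write_report_tables", "write_summary", "write_manifest"]

_ROW_LABELS = {
    "moderate/no_reversal": ("Moderate", "Rocuronium + No reversal"),
    "moderate/neostigmine": ("Moderate", "Rocuronium + Neostigmine"),
    "deep/no_reversal": ("Deep", "Rocuronium + No reversal"),
}


@dataclass
class RunManifest:
    """Provenance record for one CLI run."""

    command: str
    config_path: str
    config_sha256: str
    code_version: str
    offset_mode: str
    seeds: list[int] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


class _ListHandler(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record: logging.LogRecord) -> None:
        self.sink.append(record.getMessage())


class warning_collector:
    """Context manager capturing package WARNING logs into a list."""

    def __init__(self) -> None:
        self.messages: list[str] = []
        self._handler = _ListHandler(self.messages)
        self._logger = logging.getLogger("nmbia")

    def __enter__(self) -> "warning_collector":
        self._logger.addHandler(self._handler)
        return self

    def __exit__(self, *exc) -> None:
        self._logger.removeHandler(self._handler)


def _eur(x: float) -> str:
    return f"{round_currency(x):.2f}"


def write_strata_table(strata: list[StratumCount], path: Path) -> None:
    """Tab-delimited stratum-level counts."""
    lines = ["block_depth\tprior_strategy\tprior_agent\teligible_count\tsugammadex_count"]
    for sc in strata:
        s = sc.stratum
        lines.append(f"{s.block_depth.value}\t{s.prior_strategy.value}\t"
                     f"{s.prior_agent.value}\t{sc.eligible_count}\t{sc.sugammadex_count}")
    path.write_text("\n".join(lines) + "\n")


def write_report_tables(report: BudgetImpactReport, out_dir: Path) -> list[Path]:
    """Write the three result tables; returns the paths written."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    # per-procedure level
    p = out_dir / "procedure_level.tsv"
    lines = ["block_depth\tprior_reversal\tprior_drug_cost\talternative_drug_cost"
             "\toffsets\tnet_saving"]
    for row in report.rows:
        depth, label = _ROW_LABELS[row.row_key]
        lines.append(f"{depth}\t{label}\t{_eur(row.unit_prior)}\t"
                     f"{_eur(row.unit_alternative)}\t{_eur(row.unit_offset)}\t"
                     f"{_eur(row.unit_net)}")
    avg_s = report.avg_per_sugammadex
    avg_a = report.avg_per_all_procedures
    lines.append("\t".join(["", "Average per procedure using sugammadex",
                            _eur(avg_s["prior_drug_cost"]),
                            _eur(avg_s["alternative_drug_cost"]),
                            _eur(avg_s["offsets"]), _eur(avg_s["net_saving"])]))
    lines.append("\t".join(["", "Average across all surgical procedures",
                            _eur(avg_a["prior_drug_cost"]),
                            _eur(avg_a["alternative_drug_cost"]),
                            _eur(avg_a["offsets"]), _eur(avg_a["net_saving"])]))
    p.write_text("\n".join(lines) + "\n")
    paths.append(p)

    # national level
    p = out_dir / "national_level.tsv"
    lines = ["block_depth\tprior_reversal\tprior_drug_cost\talternative_drug_cost"
             "\toffsets\tnet_saving"]
    for row in report.rows:
        depth, label = _ROW_LABELS[row.row_key]
        lines.append(f"{depth}\t{label}\t{_eur(row.prior_drug_cost)}\t"
                     f"{_eur(row.alternative_drug_cost)}\t{_eur(row.offsets)}\t"
                     f"{_eur(row.net_saving)}")
    lines.append("\t".join(["", "Total budget impact",
                            _eur(report.total_prior_drug_cost),
                            _eur(report.total_alternative_drug_cost),
                            _eur(report.total_offsets),
                            _eur(report.total_net_saving)]))
    p.write_text("\n".join(lines) + "\n")
    paths.append(p)

    # events
    p = out_dir / "events.tsv"
    lines = ["block_depth\tprior_reversal\tevents_prior\tevents_alternative"]
    for row in report.rows:
        depth, label = _ROW_LABELS[row.row_key]
        prior = sum(row.events[t][0] for t in EVENT_TYPES)
        alt = sum(row.events[t][1] for t in EVENT_TYPES)
        lines.append(f"{depth}\t{label}\t{round_count(prior)}\t{round_count(alt)}")
    for t in EVENT_TYPES:
        lines.append(f"\t{t} cases avoided\t{round_count(report.events_avoided[t])}\t")
    p.write_text("\n".join(lines) + "\n")
    paths.append(p)
    return paths


def summary_dict(report: BudgetImpactReport) -> dict:
    """Machine-readable run summary (full-precision totals, cent averages)."""
    return {
        "n_sugammadex_procedures": report.n_sugammadex,
        "n_all_procedures": report.n_all_procedures,
        "total_prior_drug_cost": round_currency(report.total_prior_drug_cost),
        "total_alternative_drug_cost": round_currency(report.total_alternative_drug_cost),
        "total_offsets": round_currency(report.total_offsets),
        "total_net_saving": round_currency(report.total_net_saving),
        "avg_per_sugammadex_procedure": report.avg_per_sugammadex,
        "avg_per_all_procedures": report.avg_per_all_procedures,
        "events_avoided": {t: round_count(v) for t, v in report.events_avoided.items()},
    }


def write_summary(report: BudgetImpactReport, path: Path, **extra) -> None:
    payload = summary_dict(report)
    payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_manifest(manifest: RunManifest, path: Path) -> None:
    path.write_text(json.dumps(manifest.__dict__, indent=2, sort_keys=True) + "\n")


def config_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_manifest(command: str, config: Path, offset_mode: str,
                  outputs: list[Path], warnings: list[str],
                  seeds: list[int] | None = None) -> RunManifest:
    return RunManifest(
        command=command,
        config_path=str(config),
        config_sha256=config_hash(config),
        code_version=__version__,
        offset_mode=offset_mode,
        seeds=seeds or [],
        outputs=[p.name for p in outputs],
        warnings=warnings,
    )
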