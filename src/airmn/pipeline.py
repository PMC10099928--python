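"""End-to-end pipeline: scoring table -> index report + genotoxicity verdicts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import pandas as pd

from .data_model import (
    DEFAULT_CELLS_PER_INSERT,
    DEFAULT_TARGET_BNC_PER_INSERT,
    Experiment,
)
from .errors import ConfigError
from .indices import experiment_indices, round_half_up
from .io import read_scoring_table
from .stats import FisherSidedness, GenotoxCall, TrendSpec, genotoxic_call

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analyze_experiments"]

log = logging.getLogger("airmn")

#: Report rounding: decimals per column family (half-up).
DEFAULT_ROUNDING = {"pct_mn": 2, "pct_bnc": 1, "relative": 1}


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings; defaults reproduce the published evaluation."""

    alpha: float = 0.05
    fisher_sidedness: FisherSidedness = "two_sided"
    trend_scores: Literal["dose", "rank", "log"] = "dose"
    trend_sidedness: Literal["increasing", "two_sided"] = "increasing"
    rounding: dict = field(default_factory=lambda: dict(DEFAULT_ROUNDING))
    cells_per_insert_target: int = DEFAULT_CELLS_PER_INSERT
    bnc_per_insert_target: int = DEFAULT_TARGET_BNC_PER_INSERT

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class PipelineResult:
    index_report: pd.DataFrame
    verdict_report: pd.DataFrame
    calls: dict[str, GenotoxCall]


def _index_rows(exp: Experiment, call: GenotoxCall, cfg: PipelineConfig):
    r = cfg.rounding
    starred = set(call.significant_doses)
    for res in experiment_indices(exp):
        yield {
            "chemical": res.chemical,
            "concentration_ug_per_ml": res.concentration,
            "n_bnc_observed": res.n_bnc_scored,
            "n_bnc_with_mn": res.n_bnc_mn,
            "pct_mn": (
                round_half_up(res.pct_mn, r["pct_mn"])
                if res.pct_mn is not None
                else None
            ),
            "pct_bnc": round_half_up(res.pct_bnc, r["pct_bnc"]),
            "pct_bnc_relative": round_half_up(res.pct_bnc_relative, r["relative"]),
            "cbpi_relative": round_half_up(res.cbpi_relative, r["relative"]),
            "ri_pct": round_half_up(res.ri, r["relative"]),
            "significant": res.concentration in starred,
        }


def analyze_experiments(
    experiments: Sequence[Experiment], config: Optional[PipelineConfig] = None
) -> PipelineResult:
    """Indices and verdicts for a batch of per-chemical experiments.

    The index report mirrors the conventional results-table layout
    (concentration, BNCs observed, BNCs with MN, %MN, %BNCs, relative
    %BNCs, relative CBPI, RI) with a star column marking doses whose
    Fisher test is significant.  The verdict report has one row per
    chemical.  All assumption flags are logged so calls are auditable.
    """
    cfg = config or PipelineConfig()
    index_rows, verdict_rows, calls = [], [], {}
    for exp in experiments:
        spec = TrendSpec.from_concentrations(
            [g.concentration for g in exp.groups],
            mode=cfg.trend_scores,
            sidedness=cfg.trend_sidedness,
        )
        call = genotoxic_call(
            exp,
            alpha=cfg.alpha,
            spec=spec,
            fisher_sidedness=cfg.fisher_sidedness,
        )
        calls[call.chemical] = call
        log.info(
            "%s: verdict=%s trend_p=%.3g significant=%s "
            "(fisher=%s, trend scores=%s/%s, any-dose rule)",
            call.chemical,
            "genotoxic" if call.verdict else "not genotoxic",
            call.trend_p,
            list(call.significant_doses),
            cfg.fisher_sidedness,
            cfg.trend_scores,
            cfg.trend_sidedness,
        )
        if call.heterogeneity_warning:
            log.warning(
                "%s: between-insert MN heterogeneity detected (chi-square "
                "p < 0.05); pooled tests may be anti-conservative",
                call.chemical,
            )
        index_rows.extend(_index_rows(exp, call, cfg))
        verdict_rows.append(
            {
                "chemical": call.chemical,
                "verdict": "genotoxic" if call.verdict else "not genotoxic",
                "trend_z": round_half_up(call.trend_z, 4),
                "trend_p": call.trend_p,
                "n_significant_doses": len(call.significant_doses),
                "significant_doses": ";".join(
                    f"{c:g}" for c in call.significant_doses
                ),
                "alpha": call.alpha,
                "heterogeneity_warning": call.heterogeneity_warning,
            }
        )
    return PipelineResult(
        index_report=pd.DataFrame(index_rows),
        verdict_report=pd.DataFrame(verdict_rows),
        calls=calls,
    )


def run_pipeline(
    scoring_table_path: Union[str, Path],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Read a scoring table and analyze every chemical in it."""
    return analyze_experiments(read_scoring_table(scoring_table_path), config)
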