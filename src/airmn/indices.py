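"""Cytotoxicity / proliferation indices for the CBMN assay.

Three indices summarize how strongly a treatment suppressed cell division
relative to the solvent control:

* ``%BNC``  — percentage of binucleated cells among all classified cells;
  also reported relative to control as a ratio of the two fractions.
* ``CBPI``  — cytokinesis-block proliferation index,
  ``(mono + 2*bi + 3*multi) / total``, ranging 1 (no division) to 3;
  reported relative to control as a simple ratio of the two CBPI values.
* ``RI``    — replication index, control-relative ratio of
  ``(bi + 2*multi) / total``.

The micronucleus frequency ``%MN`` is the percentage of micronucleated
BNCs among BNCs scored, pooled over replicate inserts.

Computation is kept unrounded; report formatting rounds half-up to match
the conventional table layout (2 decimals for %MN, 1 for the others).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .data_model import CellClassCounts, DoseGroup, Experiment, MnCounts, pool_mn
from .errors import UndefinedRelativeError

__all__ = [
    "IndexResult",
    "pct_bnc",
    "pct_bnc_relative",
    "cbpi",
    "cbpi_relative",
    "replication_index",
    "pct_mn",
    "round_half_up",
    "group_indices",
]


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero at the given decimal place.

    Banker's rounding (Python's built-in) would turn 16.545 into 16.54;
    published assay tables round such ties up, so report formatting uses
    this explicitly.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct_bnc(counts: CellClassCounts) -> float:
    """Absolute percentage of binucleated cells, ``100 * n_bi / n_total``."""
    if counts.n_total == 0:
        raise ZeroDivisionError("pct_bnc undefined for n_total == 0")
    return 100.0 * counts.n_bi / counts.n_total


def pct_bnc_relative(
    treated: CellClassCounts, control: CellClassCounts
) -> float:
    """Binucleation fraction of the treated culture as % of control's."""
    if control.n_bi == 0:
        raise UndefinedRelativeError(
            "relative %BNC undefined: control has no binucleated cells"
        )
    return 100.0 * (
        (treated.n_bi / treated.n_total) / (control.n_bi / control.n_total)
    )


def cbpi(counts: CellClassCounts) -> float:
    """Cytokinesis-block proliferation index.

    Average number of nuclei per cell capped at three classes; equals
    ``1 + %BNC/100 + 2 * multi-fraction`` and lies in [1, 3].
    """
    if counts.n_total == 0:
        raise ZeroDivisionError("cbpi undefined for n_total == 0")
    return (
        counts.n_mono + 2 * counts.n_bi + 3 * counts.n_multi
    ) / counts.n_total


def cbpi_relative(treated: CellClassCounts, control: CellClassCounts) -> float:
    """Treated CBPI as a percentage of control CBPI (simple ratio)."""
    return 100.0 * cbpi(treated) / cbpi(control)


def replication_index(
    treated: CellClassCounts, control: CellClassCounts
) -> float:
    """Replication index: control-relative ``(bi + 2*multi)/total`` in %.

    When no multinucleated cells are present in either group this reduces
    exactly to the relative %BNC.
    """
    control_num = control.n_bi + 2 * control.n_multi
    if control_num == 0:
        raise UndefinedRelativeError(
            "replication index undefined: control has no divided cells"
        )
    t = (treated.n_bi + 2 * treated.n_multi) / treated.n_total
    c = control_num / control.n_total
    return 100.0 * t / c


def pct_mn(mn: MnCounts) -> float:
    """Micronucleated-BNC frequency, ``100 * n_bnc_mn / n_bnc_scored``."""
    if mn.n_bnc_scored == 0:
        raise ZeroDivisionError("pct_mn undefined for zero BNCs scored")
    return 100.0 * mn.n_bnc_mn / mn.n_bnc_scored


@dataclass(frozen=True)
class IndexResult:
    """All indices for one dose group, unrounded.

    ``pct_mn`` is None when the group carries no MN counts.
    """

    chemical: str
    concentration: float
    n_bnc_scored: Optional[int]
    n_bnc_mn: Optional[int]
    pct_mn: Optional[float]
    pct_bnc: float
    pct_bnc_relative: float
    cbpi: float
    cbpi_relative: float
    ri: float


def group_indices(
    group: DoseGroup, control: DoseGroup, with_mn: bool = True
) -> IndexResult:
    """Compute every index for one dose group against its control.

    Class counts are pooled over the group's inserts before computing the
    indices (equivalent to weighting inserts by cells scored).
    """
    gc = group.pooled_class_counts()
    cc = control.pooled_class_counts()
    mn = None
    if with_mn and all(i.mn_counts is not None for i in group.inserts):
        mn = pool_mn(group)
    return IndexResult(
        chemical=group.chemical,
        concentration=group.concentration,
        n_bnc_scored=mn.n_bnc_scored if mn else None,
        n_bnc_mn=mn.n_bnc_mn if mn else None,
        pct_mn=pct_mn(mn) if mn and mn.n_bnc_scored > 0 else None,
        pct_bnc=pct_bnc(gc),
        pct_bnc_relative=pct_bnc_relative(gc, cc),
        cbpi=cbpi(gc),
        cbpi_relative=cbpi_relative(gc, cc),
        ri=replication_index(gc, cc),
    )


def experiment_indices(experiment: Experiment) -> list[IndexResult]:
    """Index rows for every group of an experiment, control first."""
    return [
        group_indices(g, experiment.control) for g in experiment.groups
    ]
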