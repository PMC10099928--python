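"""Domain types for cytokinesis-block micronucleus (CBMN) scoring data.

The CBMN assay scores cells harvested from tissue-culture inserts after
cytochalasin-B block: each cell is classified by nucleus number
(mono-/bi-/multinucleated), and binucleated cells (BNCs) are examined for
micronuclei (MN).  The types here mirror the physical structure of an
experiment — cells on an insert, triplicate inserts per dose group, a
solvent-control group plus ascending dose groups per chemical — and enforce
the scoring rules that decide which cells enter the cytotoxicity indices
and the MN frequency:

* cells are classed mono (1 nucleus), bi (2), or multi (>= 3) for the
  proliferation indices;
* only binucleated, non-mitotic, non-apoptotic cells are eligible for MN
  scoring (mitotic cells, apoptotic cells, and cells with four or more
  nuclei are excluded from the MN analysis);
* a candidate MN body is accepted only if its maximum diameter is at most
  half that of the main nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Optional, Sequence

from .errors import EmptyInputError, IncompleteGroupError, InvalidRecordError

__all__ = [
    "CellAnnotation",
    "CellClassCounts",
    "MnCounts",
    "InsertRecord",
    "DoseGroup",
    "Experiment",
    "CellClassification",
    "classify_cell",
    "tally_cells",
    "pool_mn",
    "MN_DIAMETER_RATIO_MAX",
    "DEFAULT_CELLS_PER_INSERT",
    "DEFAULT_TARGET_BNC_PER_INSERT",
]

#: A micronucleus may be at most half the diameter of the main nucleus.
MN_DIAMETER_RATIO_MAX = 0.5

#: Advisory scoring targets (not hard validation: real slides fall short
#: at cytotoxic doses where too few BNCs are available).
DEFAULT_CELLS_PER_INSERT = 500
DEFAULT_TARGET_BNC_PER_INSERT = 667


@dataclass(frozen=True)
class CellAnnotation:
    """A single manually scored cell.

    Parameters
    ----------
    nucleus_count
        Number of main nuclei (>= 1).
    is_mitotic, is_apoptotic
        Morphology flags; either excludes the cell from MN scoring.
    mn_diameter_ratios
        One entry per candidate micronucleus body: its maximum diameter
        divided by the maximum diameter of the main nucleus.
    """

    nucleus_count: int
    is_mitotic: bool = False
    is_apoptotic: bool = False
    mn_diameter_ratios: tuple[float, ...] = ()

    def __post_init__(self):
        if self.nucleus_count < 1:
            raise InvalidRecordError(
                f"nucleus_count must be >= 1, got {self.nucleus_count}"
            )
        object.__setattr__(
            self, "mn_diameter_ratios", tuple(self.mn_diameter_ratios)
        )
        if any(r < 0 for r in self.mn_diameter_ratios):
            raise InvalidRecordError("mn_diameter_ratios must be non-negative")


@dataclass(frozen=True)
class CellClassCounts:
    """Per-insert tally of nucleation classes (the index denominators)."""

    n_mono: int
    n_bi: int
    n_multi: int
    n_total: int

    def __post_init__(self):
        for name in ("n_mono", "n_bi", "n_multi", "n_total"):
            if getattr(self, name) < 0:
                raise InvalidRecordError(f"{name} must be non-negative")
        if self.n_total != self.n_mono + self.n_bi + self.n_multi:
            raise InvalidRecordError(
                "n_total must equal n_mono + n_bi + n_multi "
                f"({self.n_total} != {self.n_mono}+{self.n_bi}+{self.n_multi})"
            )

    def __add__(self, other: "CellClassCounts") -> "CellClassCounts":
        return CellClassCounts(
            self.n_mono + other.n_mono,
            self.n_bi + other.n_bi,
            self.n_multi + other.n_multi,
            self.n_total + other.n_total,
        )


@dataclass(frozen=True)
class MnCounts:
    """BNCs examined for micronuclei and BNCs bearing at least one."""

    n_bnc_scored: int
    n_bnc_mn: int

    def __post_init__(self):
        if self.n_bnc_scored < 0 or self.n_bnc_mn < 0:
            raise InvalidRecordError("MN counts must be non-negative")
        if self.n_bnc_mn > self.n_bnc_scored:
            raise InvalidRecordError(
                f"n_bnc_mn ({self.n_bnc_mn}) exceeds n_bnc_scored "
                f"({self.n_bnc_scored})"
            )

    def __add__(self, other: "MnCounts") -> "MnCounts":
        return MnCounts(
            self.n_bnc_scored + other.n_bnc_scored,
            self.n_bnc_mn + other.n_bnc_mn,
        )


@dataclass(frozen=True)
class InsertRecord:
    """One physical tissue insert (one slide's worth of scoring).

    ``pooled`` marks pseudo-inserts holding counts already summed over
    replicates, as in published tables that print only group totals.
    """

    insert_id: str
    class_counts: Optional[CellClassCounts] = None
    mn_counts: Optional[MnCounts] = None
    teer_ohm: Optional[float] = None
    ak_rlu: Optional[float] = None
    pooled: bool = False

    def __post_init__(self):
        if self.class_counts is None and self.mn_counts is None:
            raise InvalidRecordError(
                f"insert {self.insert_id!r}: needs class_counts or mn_counts"
            )


@dataclass(frozen=True)
class DoseGroup:
    """All inserts treated with one concentration of one chemical."""

    chemical: str
    concentration: float
    inserts: tuple[InsertRecord, ...]
    is_control: bool = False

    def __post_init__(self):
        object.__setattr__(self, "inserts", tuple(self.inserts))
        if self.concentration < 0:
            raise InvalidRecordError("concentration must be non-negative")
        if self.is_control != (self.concentration == 0):
            raise InvalidRecordError(
                "is_control must hold exactly when concentration == 0"
            )
        if not self.inserts:
            raise InvalidRecordError("a dose group needs at least one insert")

    def pooled_class_counts(self) -> CellClassCounts:
        counts = [i.class_counts for i in self.inserts]
        if any(c is None for c in counts):
            raise IncompleteGroupError(
                f"{self.chemical} @ {self.concentration}: "
                "insert(s) missing class_counts"
            )
        total = counts[0]
        for c in counts[1:]:
            total = total + c
        return total


@dataclass(frozen=True)
class Experiment:
    """A solvent-control group plus concentration-ordered dose groups."""

    control: DoseGroup
    treated: tuple[DoseGroup, ...]

    def __post_init__(self):
        object.__setattr__(self, "treated", tuple(self.treated))
        if not self.control.is_control:
            raise InvalidRecordError("control group must have concentration 0")
        concs = [g.concentration for g in self.treated]
        if any(c <= 0 for c in concs):
            raise InvalidRecordError("treated concentrations must be > 0")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise InvalidRecordError(
                "treated concentrations must be strictly increasing"
            )

    @property
    def chemical(self) -> str:
        return self.treated[0].chemical if self.treated else self.control.chemical

    @property
    def groups(self) -> tuple[DoseGroup, ...]:
        """Control first, then doses in ascending concentration."""
        return (self.control,) + self.treated


class CellClassification(NamedTuple):
    index_class: Literal["mono", "bi", "multi"]
    mn_eligible: bool
    mn_count: int


def classify_cell(cell: CellAnnotation) -> CellClassification:
    """Classify one cell for the proliferation indices and MN scoring.

    The index class follows nucleus count alone (1 -> mono, 2 -> bi,
    >= 3 -> multi), so mitotic or apoptotic binucleated cells still count
    in the BNC column of the indices.  MN eligibility is stricter: only
    binucleated cells that are neither mitotic nor apoptotic enter the MN
    denominator.  Candidate MN bodies larger than half the main-nucleus
    diameter are rejected (ratio 0.5 itself is accepted).
    """
    if cell.nucleus_count == 1:
        index_class: Literal["mono", "bi", "multi"] = "mono"
    elif cell.nucleus_count == 2:
        index_class = "bi"
    else:
        index_class = "multi"

    mn_eligible = (
        cell.nucleus_count == 2 and not cell.is_mitotic and not cell.is_apoptotic
    )
    mn_count = 0
    if mn_eligible:
        mn_count = sum(
            1 for r in cell.mn_diameter_ratios if r <= MN_DIAMETER_RATIO_MAX
        )
    return CellClassification(index_class, mn_eligible, mn_count)


def tally_cells(
    cells: Sequence[CellAnnotation],
) -> tuple[CellClassCounts, MnCounts]:
    """Aggregate per-cell classifications into insert-level counts.

    ``MnCounts.n_bnc_scored`` is the number of MN-eligible cells and
    ``n_bnc_mn`` the number of those with at least one accepted
    micronucleus (a cell with several micronuclei still counts once).
    """
    if not cells:
        raise EmptyInputError("tally_cells requires a non-empty cell list")
    n_mono = n_bi = n_multi = 0
    n_scored = n_mn = 0
    for cell in cells:
        cls = classify_cell(cell)
        if cls.index_class == "mono":
            n_mono += 1
        elif cls.index_class == "bi":
            n_bi += 1
        else:
            n_multi += 1
        if cls.mn_eligible:
            n_scored += 1
            if cls.mn_count >= 1:
                n_mn += 1
    return (
        CellClassCounts(n_mono, n_bi, n_multi, len(cells)),
        MnCounts(n_scored, n_mn),
    )


def pool_mn(group: DoseGroup) -> MnCounts:
    """Pool MN counts over a group's replicate inserts (element-wise sum).

    The MN frequency is reported on counts combined across triplicate
    inserts, not as a mean of per-insert frequencies.
    """
    pooled = MnCounts(0, 0)
    for insert in group.inserts:
        if insert.mn_counts is None:
            raise IncompleteGroupError(
                f"{group.chemical} @ {group.concentration}: insert "
                f"{insert.insert_id!r} has no mn_counts"
            )
        pooled = pooled + insert.mn_counts
    return pooled
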