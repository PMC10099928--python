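"""Bundled reference dataset: clastogen/aneugen CBMN dose-response counts.

Published pooled-triplicate micronucleus counts for two clastogens,
mitomycin C (MMC) and methyl methanesulfonate (MMS), and one aneugen,
colchicine (COL), applied apically to an organotypic human airway
epithelium model.  For each dose group the dataset carries:

* ``n_bnc_scored`` / ``n_bnc_mn`` — exact published counts of BNCs
  examined and BNCs with micronuclei, summed over triplicate inserts;
* ``pct_bnc`` — the published binucleated-cell percentage.

Per-insert splits and raw nucleation-class counts were not published, so
each group is represented as one pooled pseudo-insert (``pooled=True``)
and its class counts are a synthetic reconstruction: 1500 classified
cells (3 x 500), ``n_bi`` = round(%BNC x 15), no multinucleated cells.
MN counts and therefore %MN and all significance tests are exact;
index columns recomputed from the reconstructed class counts are
approximate (published relative indices were derived from unrounded
replicate data).
"""

from __future__ import annotations

import pandas as pd

from .data_model import (
    CellClassCounts,
    DoseGroup,
    Experiment,
    InsertRecord,
    MnCounts,
)

__all__ = ["REFERENCE_COUNTS", "reference_experiments", "reference_scoring_table"]

# chemical -> list of (concentration ug/mL, BNCs scored, BNCs with MN, %BNC)
REFERENCE_COUNTS: dict[str, list[tuple[float, int, int, float]]] = {
    "MMC": [
        (0.00, 1811, 5, 8.5),
        (1.25, 2098, 44, 7.5),
        (2.50, 2125, 88, 6.2),
        (5.00, 1827, 176, 6.8),
        (10.00, 1033, 171, 3.7),
        (20.00, 217, 23, 1.2),
    ],
    "MMS": [
        (0.00, 2001, 2, 6.9),
        (1280.00, 2001, 7, 7.0),
        (1600.00, 2001, 4, 6.2),
        (2000.00, 2001, 12, 6.0),
        (2500.00, 1870, 20, 4.4),
    ],
    "COL": [
        (0.00, 2001, 2, 6.9),
        (0.51, 1975, 7, 5.9),
        (0.64, 2001, 9, 5.7),
        (0.80, 2001, 13, 4.0),
        (1.00, 1555, 32, 3.8),
        (1.25, 593, 18, 2.8),
    ],
}

_CELLS_CLASSIFIED = 1500  # 3 inserts x 500 cells


def _group(chemical: str, conc: float, scored: int, mn: int, bnc_pct: float) -> DoseGroup:
    n_bi = round(bnc_pct / 100 * _CELLS_CLASSIFIED)
    counts = CellClassCounts(
        n_mono=_CELLS_CLASSIFIED - n_bi,
        n_bi=n_bi,
        n_multi=0,
        n_total=_CELLS_CLASSIFIED,
    )
    record = InsertRecord(
        insert_id=f"{chemical}-{conc:g}-pooled",
        class_counts=counts,
        mn_counts=MnCounts(scored, mn),
        pooled=True,
    )
    return DoseGroup(
        chemical=chemical,
        concentration=conc,
        inserts=(record,),
        is_control=conc == 0,
    )


def reference_experiments() -> dict[str, Experiment]:
    """One Experiment per chemical (MMC, MMS, COL), pooled pseudo-inserts."""
    out = {}
    for chem, rows in REFERENCE_COUNTS.items():
        groups = [_group(chem, *row) for row in rows]
        out[chem] = Experiment(control=groups[0], treated=tuple(groups[1:]))
    return out


def reference_scoring_table() -> pd.DataFrame:
    """The reference dataset in the standard scoring-table schema."""
    rows = []
    for chem, data in REFERENCE_COUNTS.items():
        for conc, scored, mn, bnc_pct in data:
            n_bi = round(bnc_pct / 100 * _CELLS_CLASSIFIED)
            rows.append(
                {
                    "chemical": chem,
                    "concentration_ug_per_ml": conc,
                    "insert_id": f"{chem}-{conc:g}-pooled",
                    "n_mono": _CELLS_CLASSIFIED - n_bi,
                    "n_bi": n_bi,
                    "n_multi": 0,
                    "n_bnc_scored": scored,
                    "n_bnc_mn": mn,
                    "teer_ohm": None,
                    "ak_rlu": None,
                    "pooled": True,
                }
            )
    return pd.DataFrame(rows)
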