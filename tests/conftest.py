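import pytest

from airmn.data_model import (
    CellClassCounts,
    DoseGroup,
    Experiment,
    InsertRecord,
    MnCounts,
)


def make_group(
    chemical="X",
    conc=0.0,
    mn=((500, 0),),
    classes=None,
):
    """Build a DoseGroup from (scored, with_mn) pairs, one per insert."""
    inserts = []
    for i, (scored, n_mn) in enumerate(mn):
        cc = None
        if classes is not None:
            cc = CellClassCounts(*classes[i])
        inserts.append(
            InsertRecord(
                insert_id=f"{chemical}-{conc:g}-{i}",
                class_counts=cc,
                mn_counts=MnCounts(scored, n_mn),
            )
        )
    return DoseGroup(
        chemical=chemical,
        concentration=conc,
        inserts=tuple(inserts),
        is_control=conc == 0,
    )


def make_experiment(control_mn, dose_mn: dict):
    """Experiment from {dose: [(scored, mn), ...]} plus control inserts."""
    control = make_group(conc=0.0, mn=control_mn)
    treated = tuple(
        make_group(conc=c, mn=tuple(pairs)) for c, pairs in sorted(dose_mn.items())
    )
    return Experiment(control=control, treated=treated)


@pytest.fixture(scope="session")
def reference():
    from airmn.reference_data import reference_experiments

    return reference_experiments()
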