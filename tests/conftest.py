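import pytest

from multistress.database import (
    ExperimentRecord,
    ResponseDatabase,
    TreatmentSummary,
)


def make_record(
    c=10.0,
    sa=12.0,
    sb=15.0,
    xo=16.0,
    sd=1.0,
    n=4,
    metric="growth_size",
    study_id="S1",
    response_id="R1",
    stressor_b_type="nutrients",
    organisation_level="population",
    organism_group="invertebrate",
    c_sd=None,
    sa_sd=None,
    sb_sd=None,
    xo_sd=None,
):
    """Handy factory for a single factorial record with common defaults."""
    return ExperimentRecord(
        study_id=study_id,
        response_id=response_id,
        stressor_b_type=stressor_b_type,
        organisation_level=organisation_level,
        organism_group=organism_group,
        response_metric=metric,
        control=TreatmentSummary(c, c_sd if c_sd is not None else sd, n),
        temp_alone=TreatmentSummary(sa, sa_sd if sa_sd is not None else sd, n),
        stressorB_alone=TreatmentSummary(sb, sb_sd if sb_sd is not None else sd, n),
        combined=TreatmentSummary(xo, xo_sd if xo_sd is not None else sd, n),
    )


@pytest.fixture
def small_db():
    """Three well-formed records across two studies."""
    return ResponseDatabase(
        [
            make_record(study_id="S1", response_id="R1"),
            make_record(study_id="S1", response_id="R2", metric="abundance",
                        c=20.0, sa=15.0, sb=12.0, xo=10.0),
            make_record(study_id="S2", response_id="R1",
                        organisation_level="community", c=5.0, sa=8.0,
                        sb=4.0, xo=7.5),
        ],
        provenance="fixture",
    )
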