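import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture()
def toy_records():
    """Three hand-checkable proteins: one repeat-rich, one PPG-only, one bare."""
    from polypro.io import ProteinRecord

    return [
        ProteinRecord(protein_id="p1", gene_id="g1",
                      sequence="MAPPPPPLKPPPGAA"),   # runs 5P,3P; one PPG
        ProteinRecord(protein_id="p2", gene_id="g2",
                      sequence="MPPGAPPGW"),          # two PPG, no PPP
        ProteinRecord(protein_id="p3", gene_id="g3",
                      sequence="MKLVNQ"),             # nothing
    ]
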