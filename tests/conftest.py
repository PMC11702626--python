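import io

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


CATALOG_HEADER = "GENE\tACC_ID\tORGANISM\tMOD_RSD\tSITE_+/-7_AA\tCST_CAT#\n"


def make_catalog(rows, preamble="Banner\nMarch release\n\n"):
    """Assemble catalog text in the PhosphoSitePlus dialect."""
    return preamble + CATALOG_HEADER + "".join("\t".join(r) + "\n" for r in rows)


@pytest.fixture
def catalog_stream():
    def _make(rows, **kwargs):
        return io.StringIO(make_catalog(rows, **kwargs))

    return _make
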