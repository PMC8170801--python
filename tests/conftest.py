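import sys
from pathlib import Path

import pytest

# make the in-repo oracles importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))

from metaburden.growth import GompertzParams


#: fitted NSCLC reference patients: growth-rate decay a [1/day], primary size
#: at diagnosis [ml], tumor age at diagnosis [d], doubling time [d]
CLINICAL_PATIENTS = {
    "KE-01": {"a": 7.284e-3, "m": 1.635e-7, "size_ml": 240.74, "age_d": 407.1, "tvdt_d": 91.6},
    "KE-02": {"a": 6.877e-3, "m": 1.984e-7, "size_ml": 14.27, "age_d": 272.2, "tvdt_d": 25.9},
    "KE-03": {"a": 6.984e-3, "m": 2.738e-7, "size_ml": 71.75, "age_d": 336.5, "tvdt_d": 43.7},
}


@pytest.fixture(params=sorted(CLINICAL_PATIENTS))
def clinical_patient(request):
    rec = dict(CLINICAL_PATIENTS[request.param])
    rec["id"] = request.param
    rec["params"] = GompertzParams(rec["a"])
    rec["size_cells"] = rec["size_ml"] * 1e9
    return rec


@pytest.fixture
def ke01_growth():
    return GompertzParams(CLINICAL_PATIENTS["KE-01"]["a"])
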