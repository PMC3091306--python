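"""Shared fixtures: canonical queries, resolution models, simulated datasets."""

import numpy as np
import pytest

from lipidquery import pipeline, synth
from lipidquery.averaging import ResolutionModel

PC_QUERY = """
QUERYNAME = Phosphatidylcholine;
DEFINE headPC = 'C5 H15 O4 N1 P1' WITH CHG = +1;
DEFINE prPC = 'C[30..48]H[30..200]N[1]O[8]P[1]' WITH CHG = +1, DBR = (1.5, 7.5);
IDENTIFY
    prPC IN MS1+ AND
    headPC IN MS2+
SUCHTHAT
    isEven(prPC.chemsc[C])
REPORT
    MASS = prPC.mass;
    NAME = "PC [%d:%d]" % "((prPC.chemsc - headPC.chemsc)[C] - 3, prPC.chemsc[db] - 1.5)";
    CHEMSC = prPC.chemsc;
    ERROR = "%dppm" % "(prPC.errppm)";
    INTENS = prPC.intensity;
    FRAGINTENS = headPC.intensity;;
"""


@pytest.fixture(scope="session")
def orbitrap_model():
    return ResolutionModel(100000.0, 400.0)


@pytest.fixture(scope="session")
def unit_model():
    return ResolutionModel(800.0, 400.0)


@pytest.fixture(scope="session")
def pc_query_text():
    return PC_QUERY


@pytest.fixture(scope="session")
def pc_masterscan(orbitrap_model):
    """MasterScan of the PC 36:1 + decoys mixture (3 acquisitions)."""
    truth = synth.pc_truth()
    acqs = synth.simulate_acquisitions(
        truth, n_acquisitions=3, scans_per_spectrum=16,
        resolution_ms1=orbitrap_model, seed=7,
    )
    return pipeline.import_dataset(acqs, orbitrap_model)


@pytest.fixture(scope="session")
def template_masses():
    return synth.make_template()
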