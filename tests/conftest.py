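import numpy as np
import pytest

from tsmr.gwas_io import SummaryStatRecord, load_fixture
from tsmr.harmonize import HarmonizedPair

# Printed per-SNP F values used as oracles, keyed by snp_id -> (pvalue, F).
PRINTED_F = {
    # exposure: benign prostatic hyperplasia (23 instruments)
    "rs12027141": (1.90e-06, 22.691),
    "rs12131120": (2.00e-08, 31.483),
    "rs4953671": (1.30e-06, 23.477),
    "rs2556378": (2.10e-09, 35.868),
    "rs11926963": (2.60e-06, 22.062),
    "rs13077048": (1.90e-06, 22.709),
    "rs35425714": (4.10e-07, 25.665),
    "rs1379553": (3.10e-08, 30.630),
    "rs630231": (2.00e-07, 26.996),
    "rs380286": (4.90e-19, 79.461),
    "rs9504961": (8.70e-07, 24.196),
    "rs113360274": (1.70e-06, 22.914),
    "rs9348716": (1.80e-11, 45.128),
    "rs2740817": (3.10e-06, 21.741),
    "rs10788160": (6.10e-19, 79.023),
    "rs12255539": (1.80e-11, 45.140),
    "rs4266963": (6.90e-10, 38.054),
    "rs600231": (3.30e-07, 26.037),
    "rs3116616": (4.20e-10, 39.014),
    "rs7162895": (3.30e-06, 21.639),
    "rs9958656": (7.40e-08, 28.956),
    "rs11084596": (5.60e-13, 51.983),
    "rs3213180": (2.80e-07, 26.377),
    # exposure: prostatitis (10 instruments)
    "rs10915225": (1.06e-06, 23.853),
    "rs4953907": (2.64e-06, 22.081),
    "rs9789699": (2.10e-06, 22.440),
    "rs114884055": (3.23e-06, 21.674),
    "rs76569337": (4.21e-08, 30.004),
    "rs117901033": (5.83e-07, 24.970),
    "rs79554384": (4.40e-06, 21.058),
    "rs79165844": (4.11e-06, 21.204),
    "rs35521406": (6.18e-07, 24.861),
    "rs66617371": (3.90e-06, 21.364),
}


@pytest.fixture(scope="session")
def bph_records():
    return list(load_fixture("bph_instruments"))


@pytest.fixture(scope="session")
def prostatitis_records():
    return list(load_fixture("prostatitis_instruments"))


@pytest.fixture(scope="session")
def study_meta():
    return list(load_fixture("study_meta"))


def make_record(snp_id="rs1", ea="A", nea="G", eaf=0.3, beta=0.1, se=0.02,
                pvalue=1e-7, **kw):
    return SummaryStatRecord(
        snp_id=snp_id, effect_allele=ea, other_allele=nea, eaf=eaf,
        beta=beta, se=se, pvalue=pvalue, **kw,
    )


def make_pairs(bx, by, sy=None, sx=None, eaf_x=0.3, eaf_y=0.3):
    """Build HarmonizedPair list from parallel effect arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.full_like(bx, 0.05) if sy is None else np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    return [
        HarmonizedPair(
            snp_id=f"rs{i + 1}", effect_allele="A", other_allele="G",
            beta_x=float(bx[i]), se_x=float(sx[i]),
            beta_y=float(by[i]), se_y=float(sy[i]),
            eaf_x=eaf_x, eaf_y=eaf_y, action="unchanged",
        )
        for i in range(len(bx))
    ]
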