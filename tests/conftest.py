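import numpy as np
import pandas as pd
import pytest

from lineagescreen.bulk_screen import GuideLibrary, ScreenCountMatrix


def make_library(guide_ids, targets):
    return GuideLibrary(
        pd.DataFrame(
            {
                "guide_id": guide_ids,
                "target_gene": targets,
                "is_ntc": [t == "NTC" for t in targets],
            }
        )
    )


def make_scm(mat, guide_ids=None, targets=None, sample_meta=None):
    """Wrap a plain integer matrix into a ScreenCountMatrix.

    Defaults: all guides are NTCs, one sample per column with distinct
    population labels in the Cas9 arm.
    """
    mat = np.asarray(mat)
    n, m = mat.shape
    if guide_ids is None:
        guide_ids = [f"NTC_{i:03d}" for i in range(n)]
    if targets is None:
        targets = ["NTC"] * n
    lib = make_library(guide_ids, targets)
    cols = [f"s{j}" for j in range(m)]
    counts = pd.DataFrame(mat, index=pd.Index(guide_ids, name="guide_id"),
                          columns=cols)
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {
                "sample_id": cols,
                "population": [f"pop{j}" for j in range(m)],
                "cas9": True,
                "system": "sysA",
                "replicate": "r1",
            }
        )
    return ScreenCountMatrix(counts=counts, library=lib, samples=sample_meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_library():
    return make_library(
        ["Gata1_g1", "Gata1_g2", "Spi1_g1", "Spi1_g2", "NTC_01", "NTC_02"],
        ["Gata1", "Gata1", "Spi1", "Spi1", "NTC", "NTC"],
    )
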