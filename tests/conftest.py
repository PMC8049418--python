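import numpy as np
import pytest

import hotqtl as h


@pytest.fixture(scope="session")
def study_map():
    return h.GeneticMap.equally_spaced()


@pytest.fixture(scope="session")
def study_bins(study_map):
    return h.build_bins(study_map, 2.0)


@pytest.fixture(scope="session")
def study_sim():
    """The default three-hotspot study data set (seed 1) with its LOD matrix."""
    cross, truth = h.simulate_reference_design(1)
    lod = h.hk_scan(cross, step=2.0)
    return cross, truth, lod


@pytest.fixture(scope="session")
def singleton_qtlset():
    """50 monogenic QTL in pairwise-distinct, well-separated bins (no trunks)."""
    rng = np.random.default_rng(3)
    qtls = []
    for t in range(50):
        chrom = str(t % 5 + 1)
        peak = 5.0 + (t // 5) * 9.0 + rng.uniform(0, 1)
        sd = rng.uniform(1, 2)
        qtls.append(h.QTLInterval(trait=f"t{t + 1}", chromosome=chrom, peak=peak,
                                  start=max(peak - 1.96 * sd, 0.0),
                                  end=min(peak + 1.96 * sd, 100.0),
                                  sd=sd, lod=4.0))
    return h.QTLSet(qtls=qtls)
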