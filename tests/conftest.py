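import numpy as np
import pytest

from admixgwas import io_core, simulate


@pytest.fixture(scope="session")
def toy():
    """Hand-built 6-line panel (2 D, 2 A, 2 F) with known ancestry mosaics."""
    mmap = io_core.MarkerMap(
        ["m1", "m2", "m3", "m4"],
        ["1", "1", "2", "2"],
        [100, 200, 100, 300],
    )
    lines = ["D1", "D2", "A1", "A2", "F1", "F2"]
    calls = np.array([
        [0, 1, 1, 0],   # D1
        [1, 1, 0, 0],   # D2
        [0, 1, 1, 0],   # A1
        [1, 0, 0, 1],   # A2
        [1, 0, 0, 1],   # F1
        [1, 1, 1, 0],   # F2
    ], dtype=np.int8)
    G = io_core.GenotypeMatrix(lines, mmap, calls)
    ped = io_core.Pedigree([
        io_core.LineInfo("D1", "D"), io_core.LineInfo("D2", "D"),
        io_core.LineInfo("F1", "F"), io_core.LineInfo("F2", "F"),
        io_core.LineInfo("A1", "A", "D1", "F1"),
        io_core.LineInfo("A2", "A", "D2", "F2"),
    ])
    # A1: chr1 fully D, chr2 fully F; A2: chr1 D then F (switch at 150), chr2 D
    t1 = io_core.AncestryTrack("A1", {
        "1": [(1, 250, "D", "D1")],
        "2": [(1, 350, "F", "F1")],
    })
    t2 = io_core.AncestryTrack("A2", {
        "1": [(1, 150, "D", "D2"), (151, 250, "F", "F2")],
        "2": [(1, 350, "D", "D2")],
    })
    t1.validate(); t2.validate()
    return G, ped, {"A1": t1, "A2": t2}


@pytest.fixture(scope="session")
def sim_panel():
    """One simulated mid-size panel shared by pipeline-level tests."""
    cfg = simulate.SimConfig(seed=11, n_dent=100, n_flint=100, n_admixed=100,
                             n_markers=800, n_chromosomes=5)
    return simulate.simulate_panel(cfg)
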