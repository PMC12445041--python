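import numpy as np
import pandas as pd
import pytest

from slscreen.essentiality import call_essentiality
from slscreen.library import LibraryAnnotation
from slscreen.preprocess import preprocess
from slscreen.qc import apply_exclusions, qc_screen
from slscreen.scaling import scale_lfc
from slscreen.simulate import SimConfig, simulate_screen


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_gene_pairs=30, n_cell_lines=1, seed=11)


@pytest.fixture(scope="session")
def sim_screen(sim_config):
    """One small simulated screen: (library, truth, counts)."""
    return simulate_screen(sim_config)


@pytest.fixture(scope="session")
def analysed_screen(sim_screen):
    """The simulated screen taken through preprocess, QC and scaling."""
    library, truth, counts = sim_screen
    pre = preprocess(counts)
    report = qc_screen(pre.lfc, counts.counts, library, counts.samples)
    retained, _ = apply_exclusions(report)
    scaled, anchors = scale_lfc(pre.lfc[retained], library)
    return {
        "library": library,
        "truth": truth,
        "counts": counts,
        "pre": pre,
        "qc": report,
        "retained": retained,
        "scaled": scaled,
        "anchors": anchors,
    }


@pytest.fixture(scope="session")
def essentiality_calls(analysed_screen):
    return call_essentiality(
        analysed_screen["scaled"],
        analysed_screen["library"],
        analysed_screen["counts"].samples,
    )


def make_library(rows):
    """Library from (construct_id, guide_a, gene_a, guide_b, gene_b, class) rows."""
    frame = pd.DataFrame(
        rows,
        columns=["construct_id", "guide_a_id", "gene_a", "guide_b_id", "gene_b", "control_class"],
    )
    return LibraryAnnotation(frame)


@pytest.fixture
def toy_library():
    return make_library(
        [
            ("d1", "gX_1", "GX", "gY_1", "GY", "library"),
            ("d2", "gY_2", "GY", "gX_2", "GX", "library"),
            ("s_x1", "gX_1", "GX", "sf_1", "SAFE", "library"),
            ("s_x2", "sf_2", "SAFE", "gX_2", "GX", "library"),
            ("s_y1", "gY_1", "GY", "sf_1", "SAFE", "library"),
            ("s_y2", "sf_2", "SAFE", "gY_2", "GY", "library"),
            ("s_e1", "gE_1", "ESS1", "sf_1", "SAFE", "essential"),
            ("s_n1", "gN_1", "NON1", "sf_1", "SAFE", "non_essential"),
            ("ss1", "sf_2", "SAFE", "sf_1", "SAFE", "safe"),
            ("ss2", "sf_3", "SAFE", "sf_4", "SAFE", "safe"),
        ]
    )
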