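"""Shared fixtures: one small synthetic universe reused across test modules."""

import numpy as np
import pytest

from stormkit import synthdata as sd
from stormkit.readstruct import ReadStructure

FAMILY_WEIGHTS = {"LINE/L1": 0.3, "LINE/L2": 0.2, "SINE/Alu": 0.3,
                  "LTR/ERV1": 0.2}


@pytest.fixture(scope="session")
def small_model():
    return sd.build_transcriptome(40, (200, 1500), intergenic_fraction=0.7,
                                  seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_model):
    return sd.build_annotations(small_model, FAMILY_WEIGHTS, n_enhancers=20,
                                n_rloops=10, seed=3)


@pytest.fixture(scope="session")
def small_truth(small_model):
    return sd.simulate_cells(small_model, n_cells=6, mean_molecules=25,
                             dispersion=2.0, umi_length=8, seed=11)


@pytest.fixture(scope="session")
def small_library(small_truth, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_library")
    return sd.emit_library(
        small_truth, ReadStructure(umi_length=8),
        sd.ArtifactRates(gdna_fraction=0.1, strand_invasion_fraction=0.02),
        outdir, mean_reads_per_molecule=2.0, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
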