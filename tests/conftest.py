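"""Shared fixtures: miniature paradigms and recordings, all generated in-process."""

import numpy as np
import pytest

from pairlg.montage import standard_montage
from pairlg.paradigm import ParadigmConfig, generate_session
from pairlg.preprocess import filter_chain
from pairlg.simulate import NoiseSpec, build_default_components, simulate_recording


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture()
def mini_config():
    """Smallest feasible paradigm with both global contexts represented."""
    return ParadigmConfig(n_total_pairs=44, n_regularity_pairs=4,
                          n_ss=16, n_sf=15, n_st=9,
                          n_st_context_ss=4, n_st_context_sf=5, seed=3)


@pytest.fixture(scope="session")
def mini_filtered(montage):
    """One small filtered passive recording shared by read-only tests."""
    cfg = ParadigmConfig(n_total_pairs=44, n_regularity_pairs=4,
                         n_ss=16, n_sf=15, n_st=9,
                         n_st_context_ss=4, n_st_context_sf=5, seed=3)
    schedule = generate_session(cfg, "passive")
    raw = simulate_recording(schedule, build_default_components("passive"),
                             NoiseSpec(), montage, seed=11)
    return filter_chain(raw)
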