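import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mirnaome.preprocess import merge_libraries, process_reads
from mirnaome.synthetic import (SimulationConfig, build_references,
                                simulate_reads)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: enough planted structure to exercise every
    stage (incl. one rRNA-embedded and one arm-paired hairpin) while
    keeping the suite fast."""
    return SimulationConfig(
        seed=7, reads_per_library=4000, n_conserved_spikes=8,
        n_novel_hairpins=4, n_rrna_hairpins=1, n_armpaired=1,
        n_degradation_fragments=25, error_rate=0.0)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return build_references(small_config)


@pytest.fixture(scope="session")
def small_libraries(small_config, small_bundle):
    return simulate_reads(small_bundle, small_config)


@pytest.fixture(scope="session")
def small_tags(small_config, small_libraries):
    per_lib = {}
    for lib, reads in small_libraries.items():
        seqs = [s for _, s in reads]
        tags, _ = process_reads(seqs, lib, small_config.adapter)
        per_lib[lib] = tags
    return merge_libraries(per_lib)
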