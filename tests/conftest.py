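import matplotlib
import pytest

matplotlib.use("Agg")

import helpers  # noqa: E402
from ppibench import synthetic  # noqa: E402


@pytest.fixture(scope="session")
def net500():
    """Scale-free network at moderate size: edges and degree series."""
    cfg = synthetic.SyntheticConfig(n_proteins=500, n_edges_per_new_node=2, seed=11)
    edges, degrees = synthetic.generate_network(cfg)
    return cfg, edges, degrees


@pytest.fixture(scope="session")
def default_universe():
    """Full universe under the reference generator conditions."""
    return synthetic.generate_universe(synthetic.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def strong_signal_data():
    """Gold standard, splits and FG features for the strong-signal universe."""
    return helpers.build_benchmark_data(helpers.strong_signal_config(42), split_seed=5)


@pytest.fixture(scope="session")
def null_signal_data():
    """Same pipeline with no planted signal anywhere."""
    return helpers.build_benchmark_data(helpers.null_signal_config(43), split_seed=6)
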