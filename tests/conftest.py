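import numpy as np
import pytest

from mopane_es.config import RunConfig
from mopane_es.inventory import Plot, StemRecord
from mopane_es.synth import SynthConfig, default_type_params, gen_dataset, gen_linkage_table, gen_plot


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def type_params(run_config):
    return default_type_params(run_config)


@pytest.fixture(scope="session")
def links(run_config):
    return gen_linkage_table(1, config=run_config)


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study (7 villages, 154 plots), generated once."""
    return gen_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def balanced_plots(type_params, run_config):
    """30 uncut plots per woodland type, for typology recovery checks."""
    rng = np.random.default_rng(0)
    plots, truth = [], {}
    for name, tp in type_params.items():
        for i in range(30):
            pid = f"{name}-{i:02d}"
            plots.append(gen_plot(tp, 0.0, rng, config=run_config, plot_id=pid))
            truth[pid] = name
    return plots, truth


def make_plot(stems=(), plot_id="P", village="V", radius=20.0, **kw):
    """Hand-built plot from (species, dbh) pairs or StemRecord kwargs dicts."""
    plot = Plot(plot_id=plot_id, village=village, radius=radius, **kw)
    for s in stems:
        if isinstance(s, dict):
            plot.stems.append(StemRecord(plot_id=plot_id, **s))
        else:
            species, dbh = s
            plot.stems.append(StemRecord(plot_id=plot_id, species=species, diameter=dbh))
    return plot


@pytest.fixture
def plot_factory():
    return make_plot
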