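import numpy as np
import pytest

import cycleprof.quantify as q
import cycleprof.synthetic as syn


@pytest.fixture(scope="session")
def params():
    return syn.PopulationParams()


@pytest.fixture(scope="session")
def default_noise():
    return syn.NoiseParams(seed=7)


def make_spec(length=10.0, stage=syn.Stage.G2_MONO, p=0.3, conc=100.0,
              enrichment=1.0, params=None):
    """Hand-built CellSpec with consistent nucleus layout."""
    params = params or syn.PopulationParams()
    centers, radius = syn._nucleus_layout(length, stage, params)
    septum = length / 2.0 if stage is syn.Stage.SEPTATED else None
    return syn.CellSpec(length=length, stage=stage, cycle_position=p,
                        nucleus_centers=centers, nucleus_radius=radius,
                        true_wholecell_conc=conc,
                        true_nuclear_conc=conc * enrichment,
                        septum_position=septum)


@pytest.fixture(scope="session")
def constant_records(params):
    """Measured constant-strain population (n=800, default noise)."""
    specs = syn.sample_population(params, syn.preset("constant"), 800, seed=11)
    return q.measure_population(specs, params, syn.NoiseParams(seed=12))


@pytest.fixture(scope="session")
def control_records(params):
    """Measured untagged-control population (n=800, default noise)."""
    specs = syn.sample_population(params, syn.preset("untagged"), 800, seed=13)
    return q.measure_population(specs, params, syn.NoiseParams(seed=14))
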