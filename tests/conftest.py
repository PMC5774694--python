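import numpy as np
import pandas as pd
import pytest

from fermphen.must import MustComposition
from fermphen.simulate import CurveParams, EffectModel, SimulationDesign, simulate_experiment


@pytest.fixture(scope="session")
def reference_design():
    """The reference 4 strains x 2 musts x 2 oxygenation x 10 replicates design."""
    return SimulationDesign(seed=7)


@pytest.fixture(scope="session")
def reference_experiment(reference_design):
    """One simulated reference experiment (weighing logs + traits + truth)."""
    return simulate_experiment(reference_design, EffectModel.reference(reference_design))


@pytest.fixture()
def delayed_logistic():
    """A realistic delayed-logistic trajectory and the tCO2max it ferments against."""
    return CurveParams(onset=6.0, inflection=45.0, rate=0.08, co2max=95.0), 98.0


@pytest.fixture()
def balanced_table():
    """Random balanced 3 x 2 x 2 x 4 factorial trait table."""
    rng = np.random.default_rng(42)
    rows = []
    for s in ["A", "B", "C"]:
        for m in ["M1", "M2"]:
            for o in [False, True]:
                for _ in range(4):
                    rows.append({"strain": s, "must": m, "shaking": o,
                                 "value": rng.normal()})
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_must():
    return MustComposition("TOY", 200, 120, 2.0, 3.4, 40, 20)
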