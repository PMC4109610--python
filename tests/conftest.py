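import numpy as np
import pytest

import hypnoconn as hc
from hypnoconn.preprocess import EpochSet


@pytest.fixture(scope="session")
def montage():
    return hc.default_montage()


@pytest.fixture(scope="session")
def axis_1024():
    return hc.frequency_axis(1024, 500.0)


@pytest.fixture(scope="session")
def white_epochs():
    """200 epochs of independent white noise on 4 channels."""
    rng = np.random.default_rng(42)
    eps = rng.standard_normal((200, 4, 1024))
    return EpochSet(eps, np.ones(200, bool), 500.0, ("A", "B", "C", "D"))


@pytest.fixture(scope="session")
def mixed_coherency(montage, axis_1024):
    """Coherency tensor of a 200-epoch no-coupling recording: instantaneous
    mixing only, so any nonzero iCOH is estimator noise."""
    spec = hc.SimulationSpec(duration_s=420.0, seed=314)
    rec = hc.simulate_recording(spec, "s1", "high", "pre")
    es = hc.preprocess_recording(rec)
    se = hc.epoch_cross_spectra(es, axis_1024)
    return hc.coherency(se), se, es


@pytest.fixture(scope="session")
def planted_study_result():
    """One reduced planted-effect study analysed for theta iCOH."""
    spec = hc.SimulationSpec(duration_s=60.0, seed=21,
                             couplings=hc.default_effect_couplings())
    study = hc.make_study(spec, n_high=8, n_low=8)
    cfg = hc.Config(n_permutations=200, n_bootstraps=200, seed=7)
    res = hc.run_study(study, cfg, bands=["theta"], measures=("iCOH",),
                       amplitude=False)
    return study, res


@pytest.fixture()
def random_feature_matrix():
    """A null 2x2 design feature matrix: 6+5 subjects, 20 features."""
    rng = np.random.default_rng(7)
    features = {}
    import pandas as pd
    entries = []
    for g, n in (("high", 6), ("low", 5)):
        for i in range(n):
            s = f"{g}{i}"
            entries.append({"subject": s, "group": g,
                            "path_pre": s, "path_hypnosis": s})
            for cond in ("pre", "hypnosis"):
                features[(s, cond)] = rng.normal(size=20)
    manifest = hc.StudyManifest(pd.DataFrame(entries))
    return hc.build_feature_matrix(features, manifest), manifest
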