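import numpy as np
import pytest

import erpspeller as es


@pytest.fixture(scope="session")
def matrix_layout():
    return es.build_layout("matrix")


@pytest.fixture(scope="session")
def hex_layout():
    return es.build_layout("hex")


@pytest.fixture(scope="session")
def geometry():
    return es.DisplayGeometry()


@pytest.fixture(scope="session")
def components():
    return es.default_components()


@pytest.fixture(scope="session")
def erp_dataset():
    """Small simulated 2x2 ERP dataset (speller x attention), 250 Hz path.

    24 trials per condition at a reduced noise level (2.0 uV rms) so the
    qualitative modulation contrasts are resolvable at desk-scale trial
    counts; contamination filters applied. Returns
    {(speller, attention): EpochSet}.
    """
    from erpspeller import preprocessing as prep
    from erpspeller.experiment import _concat_epochs

    noise = es.NoiseModel(rms_uV=2.0)
    rng = np.random.default_rng(20260924)
    out = {}
    for speller in ("matrix", "hex"):
        layout = es.build_layout(speller)
        letters = [s for s in layout.symbols if s.isalpha()]
        for attention in ("overt", "covert"):
            profile = es.ModulationProfile.preset(attention, speller)
            sets = []
            for _ in range(24):
                target = str(rng.choice(letters))
                seed = int(rng.integers(0, 2**31 - 1))
                sch = es.generate_trial_schedule(layout, target, seed=seed)
                rec = es.synthesize_recording(
                    sch, modulation=profile, noise=noise, seed=seed + 1
                )
                sets.append(prep.apply_erp_filters(
                    prep.extract_epochs(prep.resample(rec, 250.0))
                ))
            out[(speller, attention)] = _concat_epochs(sets)
    return out


def make_stream_schedule(layout, flags, timing=None, level=1):
    """Hand-crafted schedule whose level stream has the given target flags.

    Element ids cycle over the level's groups; is_target is forced to the
    provided flags, which is all the stream-based filters look at.
    """
    timing = timing or es.TimingParams()
    n_groups = layout.n_groups(level)
    events = tuple(
        es.IntensificationEvent(
            index=i, onset_ms=i * timing.soa_ms, element_id=i % n_groups,
            phase="core", level=level, is_target=bool(f),
        )
        for i, f in enumerate(flags)
    )
    return es.TrialSchedule(
        layout=layout, target_symbol=layout.symbols[0], timing=timing,
        events={level: events}, rng_seed=0,
    )
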