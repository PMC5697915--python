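import numpy as np
import pytest

import replaykit as rk
from replaykit import ratemaps as rm


@pytest.fixture(scope="session")
def track():
    return rk.make_track()


@pytest.fixture(scope="session")
def small_session():
    """Default-condition session, modest size: 40 place cells, 10 traversals."""
    spec = rk.SessionSpec(seed=5, n_laps=10)
    return rk.simulate_session(spec)


@pytest.fixture(scope="session")
def clean_session():
    """Low-noise session for ground-truth recovery: dense ensemble, near-silent
    baseline during stops so injected bursts are uncontaminated."""
    spec = rk.SessionSpec(seed=11, n_laps=12, n_place_cells=60,
                          baseline_stop_rate_hz=0.05)
    return rk.simulate_session(spec)


@pytest.fixture(scope="session")
def clean_maps(clean_session):
    s = clean_session
    maps = rm.build_all_ratemaps(s.positions, s.spikes, s.track)
    ids = sorted(maps["outbound"])
    mats = {d: rm.ratemap_matrix(maps, d, ids)[1:] for d in ("outbound", "inbound")}
    id_to_idx = {c: i for i, c in enumerate(ids)}
    return {"maps": maps, "ids": ids, "mats": mats, "id_to_idx": id_to_idx}


@pytest.fixture(scope="session")
def clean_place_spikes(clean_session, clean_maps):
    psp = clean_session.spikes[clean_session.spikes.cell_type == "place"]
    st = psp.t.to_numpy()
    sc = np.array([clean_maps["id_to_idx"][c] for c in psp.cell_id])
    return st, sc
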