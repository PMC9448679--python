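import numpy as np
import pytest

from oligofret.core import InstrumentParams
from oligofret.synthetic import load_preset


@pytest.fixture(scope="session")
def default_params():
    """Instrument constants matching the packaged paper_mimic preset."""
    return InstrumentParams(
        autofluor_donor=2.0,
        autofluor_acceptor=2.0,
        crosstalk=0.05,
        gamma=1.0,
        monomer_brightness=50.0,
    )


@pytest.fixture(scope="session")
def clean_params():
    """No backgrounds, no cross-talk: corrections are the identity."""
    return InstrumentParams(monomer_brightness=50.0)


@pytest.fixture(scope="session")
def paper_mimic():
    return load_preset("paper_mimic")


@pytest.fixture(scope="session")
def mimic_events(paper_mimic, default_params):
    """One analyzed 5,000-event paper_mimic stream, shared across tests."""
    from oligofret.bursts import analyze_events, detect_events
    from oligofret.synthetic import simulate_burst_stream

    trace, truth = simulate_burst_stream(paper_mimic, seed=1, n_events=5000)
    events = analyze_events(detect_events(trace), default_params)
    return events, truth


def brute_force_events(donor, acceptor, threshold):
    """Independent per-bin oracle for burst detection: walk the trace and
    collect maximal supra-threshold donor runs with per-run coincidence."""
    events = []
    i, n = 0, len(donor)
    while i < n:
        if donor[i] >= threshold:
            j = i
            while j < n and donor[j] >= threshold:
                j += 1
            events.append(
                {
                    "start": i,
                    "stop": j,
                    "donor_sum": int(sum(donor[i:j])),
                    "acceptor_sum": int(sum(acceptor[i:j])),
                    "coincident": any(acceptor[k] >= threshold for k in range(i, j)),
                }
            )
            i = j
        else:
            i += 1
    return events


@pytest.fixture(scope="session")
def oracle():
    return brute_force_events


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
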