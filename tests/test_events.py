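import numpy as np
import pandas as pd
import pytest

from cypevol.events import (Event, EventError, EventSet,
                            PresenceAbsenceMatrix, brute_force_min_events,
                            count_events, dollo_reconstruct, event_rate,
                            load_b_type_events, pseudogenization_events,
                            rates_from_events)
from cypevol.treeio import chronogram_from_string, total_branch_length
from cypevol.validation import random_chronogram


def pam(species, rows):
    df = pd.DataFrame(rows, columns=species)
    df.index = [str(i) for i in range(len(rows))]
    return PresenceAbsenceMatrix(counts=df)


def test_event_rate_arithmetic():
    assert event_rate(19, 2685) == pytest.approx(100 * 19 / 2685)
    with pytest.raises(EventError):
        event_rate(1, 0)


def test_count_events_filters():
    ev = EventSet(events=[
        Event(branch=frozenset({"A"}), type="gain", group="g1"),
        Event(branch=frozenset({"A", "B"}), type="loss", group="g1"),
        Event(branch=frozenset({"C"}), type="gain", group="g2"),
    ])
    assert count_events(ev) == 3
    assert count_events(ev, type="gain") == 2
    assert count_events(ev, type="gain", clade={"A", "B"}) == 1
    with pytest.raises(EventError):
        count_events(ev, type="duplication")


def test_dollo_single_gain_and_loss():
    c = chronogram_from_string("((H:90,M:90):310,Z:400);")
    matrix = pam(["H", "M", "Z"], [[1, 0, 1]])
    anc, events = dollo_reconstruct(matrix, c)
    types = sorted(e.type for e in events)
    assert types == ["gain", "loss"]
    gain = next(e for e in events if e.type == "gain")
    assert gain.branch == frozenset({"H", "M", "Z"})
    loss = next(e for e in events if e.type == "loss")
    assert loss.branch == frozenset({"M"})


def test_dollo_copy_number_shared_elevation():
    # both leaves carry 2 copies: one extra gain on the shared stem branch
    c = chronogram_from_string("((A:10,B:10):10,C:20);")
    matrix = pam(["A", "B", "C"], [[2, 2, 0]])
    anc, events = dollo_reconstruct(matrix, c)
    assert count_events(events, type="gain") == 2
    assert count_events(events, type="loss") == 0
    assert len(events) == brute_force_min_events({"A": 2, "B": 2, "C": 0}, c)


def test_dollo_matches_brute_force_randomized():
    rng = np.random.default_rng(2024)
    for _ in range(25):
        n = int(rng.integers(3, 7))
        c = random_chronogram(rng, n)
        counts = {sp: int(x) for sp, x in
                  zip(c.species, rng.integers(0, 4, size=n))}
        if not any(counts.values()):
            counts[c.species[0]] = 1
        matrix = pam(c.species, [[counts[sp] for sp in c.species]])
        _, events = dollo_reconstruct(matrix, c)
        assert len(events) == brute_force_min_events(counts, c), counts


def test_rates_from_events_fixture():
    events = load_b_type_events()
    rates = rates_from_events(events, 2685.0)
    assert rates.gains == 19 and rates.losses == 16
    assert rates.pseudogenizations == 5
    assert round(rates.gain_rate, 1) == 0.7
    assert round(rates.loss_rate, 1) == 0.6
    assert round(rates.pseudo_rate, 2) == 0.19


def test_pseudogenization_events_placement():
    c = chronogram_from_string("((H:90,M:90):310,Z:400);")
    ev = pseudogenization_events({"gx": ["H", "M"], "gy": ["Z"]}, c)
    branches = {e.group: e.branch for e in ev}
    assert branches["gx"] == frozenset({"H", "M"})
    assert branches["gy"] == frozenset({"Z"})


def test_presence_absence_tsv_roundtrip(tmp_path):
    m = pam(["A", "B"], [[1, 0], [2, 3]])
    p = tmp_path / "m.tsv"
    m.to_tsv(p)
    back = PresenceAbsenceMatrix.from_tsv(p)
    assert (back.counts.values == m.counts.values).all()


def test_event_set_frame_roundtrip():
    ev = EventSet(events=[
        Event(branch=frozenset({"A", "B"}), type="gain", group="g1")])
    back = EventSet.from_frame(ev.to_frame())
    assert back.events == ev.events
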