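import numpy as np
import pytest

from facetempo.simulate import SimConfig, generate_all
from facetempo.types import AUEvent, Bout, GazeSegment


def make_bout(
    events,
    gaze=None,
    duration=10.0,
    fps=25.0,
    bout_id="b1",
    outcome="affiliation",
    signaller="A",
    receiver="B",
    group="G1",
):
    """Bout builder with full-clip qualifying gaze by default."""
    if gaze is None:
        gaze = [GazeSegment(0.0, duration, True)]
    return Bout(
        bout_id=bout_id,
        signaller=signaller,
        receiver=receiver,
        group=group,
        outcome=outcome,
        fps=fps,
        duration=duration,
        events=events,
        gaze=gaze,
    )


def random_bout(rng, max_events=6, grid=0.01, duration=6.0):
    """Random event stream on a 10 ms grid (keeps oracles exact)."""
    n = rng.integers(1, max_events + 1)
    codes = ["AU10", "AU12", "AU26", "AU27", "EAU3", "AD181", "AD182"]
    events = []
    for _ in range(n):
        code = codes[rng.integers(len(codes))]
        a, b = np.sort(rng.integers(0, int(duration / grid), size=2))
        if a == b:
            b = a + 1
        intensity = (
            ("low", "high")[rng.integers(2)]
            if code in ("AU10", "AU12", "AU26", "EAU3")
            else "uncoded"
        )
        events.append(AUEvent(code, a * grid, b * grid, intensity))
    if not any(e.au_code in ("AU10", "AU12", "AU26", "AU27", "EAU3") for e in events):
        events.append(AUEvent("AU26", 0.0, duration / 2, "low"))
    return make_bout(events, duration=duration)


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic dataset shared across tests."""
    return generate_all(SimConfig(), seed=20240917 % (2**31))


@pytest.fixture(scope="session")
def sim_small():
    return generate_all(SimConfig(n_bouts=60, n_males=3, n_females=5), seed=11)


def build_analysis(data, eps=None):
    """Score bouts, compute social covariates and assemble the model table."""
    from facetempo import models as fmod
    from facetempo import social as fsoc
    from facetempo.metrics import score_bouts

    metrics = score_bouts(data["bouts"])
    effort = data["effort"]
    elo = fsoc.recalibrate_female_elo(fsoc.compute_elo(data["dominance"], effort))
    hours = dict(zip(effort["id"], effort["hours"]))
    csis = [
        fsoc.compute_csi(
            [r for r in data["affiliation"] if r.dyad[0] in set(sub["id"])],
            [s for s in data["scans"] if s.dyad[0] in set(sub["id"])],
            hours,
            list(sub["id"]),
            group=g,
        )
        for g, sub in effort.groupby("group")
    ]
    dyads = fsoc.dyad_covariates(elo, csis)
    sexes = dict(zip(effort["id"], effort["sex"]))
    table = fmod.assemble_analysis_table(metrics, dyads, sexes, eps=eps)
    return metrics, dyads, sexes, table


@pytest.fixture(scope="session")
def sim_analysis(sim_default):
    return build_analysis(sim_default)
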