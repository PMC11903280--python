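import numpy as np
import pytest

from vestgait import WalkerSpec, generate_walk


@pytest.fixture(scope="session")
def default_walk():
    """Noiseless reference walk: 0.60 m steps at 100 spm, 62% stance."""
    spec = WalkerSpec(step_length_m=0.60, cadence_spm=100.0,
                      stance_fraction=0.62)
    traj, truth = generate_walk(spec)
    return spec, traj, truth


@pytest.fixture
def noisy_walk_factory():
    def make(seed, noise_sd_m=0.003, **kwargs):
        spec = WalkerSpec(step_length_m=0.60, cadence_spm=100.0,
                          stance_fraction=0.62, noise_sd_m=noise_sd_m,
                          seed=seed, **kwargs)
        return generate_walk(spec)
    return make


def event_errors(events, truth):
    """Absolute frame error of each detected event vs nearest true event."""
    gt = {}
    for r in truth.events.itertuples():
        gt.setdefault((r.side, r.kind), []).append(r.frame)
    errs = []
    for e in events:
        cands = gt.get((e.side, e.kind))
        if cands:
            errs.append(min(abs(e.frame - f) for f in cands))
    return np.asarray(errs)
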