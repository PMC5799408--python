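import numpy as np
import pandas as pd
import pytest

from lickstruct import LickTrain, handling_effect_preset, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_train(rng, n_max=60, subject="r", day=0, conc=4.0, duration=900.0):
    """A random lick train on the 0.01 s grid with gaps straddling 0.25 s."""
    n = int(rng.integers(0, n_max))
    if n == 0:
        return LickTrain(subject, day, conc, (), duration)
    # mix of sub- and supra-threshold gaps, including exact 0.25 ties
    gaps = rng.choice(
        [0.05, 0.10, 0.13, 0.24, 0.25, 0.26, 0.50, 2.00],
        size=n - 1,
        p=[0.2, 0.2, 0.2, 0.1, 0.1, 0.05, 0.1, 0.05],
    )
    ts = np.round(np.concatenate(([0.10], 0.10 + np.cumsum(gaps))), 2)
    ts = ts[ts <= duration]
    return LickTrain(subject, day, conc, tuple(ts.tolist()), duration)


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced synthetic experiment for plumbing tests (full-size runs live
    in the acceptance suite)."""
    import dataclasses
    cfg = dataclasses.replace(handling_effect_preset(), n_per_group=4,
                              sessions_per_phase=2)
    return simulate_experiment(cfg, 11)


@pytest.fixture(scope="session")
def preset_experiment():
    """One full-size preset experiment, shared across tests that read it."""
    return simulate_experiment(handling_effect_preset(), 5)


def balanced_mixed_dataset(rng, n_per_group=8, within_levels=(2,), effects=True):
    """Random balanced 2 x (within...) long-format dataset."""
    rows = []
    unit = 0
    for g, gname in enumerate(("g1", "g2")):
        for _ in range(n_per_group):
            unit += 1
            subj_eff = rng.normal(0, 1)
            cells = [()]
            for nl in within_levels:
                cells = [c + (l,) for c in cells for l in range(nl)]
            for cell in cells:
                y = subj_eff + rng.normal(0, 1)
                if effects:
                    y += 0.5 * g + 0.3 * sum(cell) + 0.2 * g * sum(cell)
                row = {"unit": f"u{unit}", "group": gname, "y": y}
                for k, l in enumerate(cell):
                    row[f"w{k + 1}"] = f"l{l}"
                rows.append(row)
    return pd.DataFrame(rows)
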