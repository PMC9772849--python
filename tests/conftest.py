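import numpy as np
import pytest

from pavpupil import synthetic as syn


@pytest.fixture(scope="session")
def config():
    """Default generator configuration (root seed 0)."""
    return syn.GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def gain_free_config():
    """Generator with event gains disabled: pooled IRTs follow the plain
    two-exponential mixture with the true (q, w, b)."""
    return syn.GeneratorConfig(seed=0, cs_anticipation_gain=1.0, us_consummatory_gain=1.0)


@pytest.fixture(scope="session")
def fast_video_config():
    """Low frame-rate generator for quick landmark/extraction tests."""
    return syn.GeneratorConfig(seed=0, frame_rate=10.0)


@pytest.fixture(scope="session")
def contingent_schedule(config):
    return syn.gen_schedule("contingent", 30, config, seed=1)


def pooled_irts(config, n_irts, group="contingent", n_rewards=120, seed0=100):
    """Pool IRTs across seeded sessions until at least ``n_irts`` collected."""
    from pavpupil.bouts import compute_irts

    chunks, total, k = [], 0, 0
    while total < n_irts:
        sch = syn.gen_schedule(group, n_rewards, config, seed=seed0 + k)
        licks = syn.gen_licks(sch, config, seed=seed0 + k)
        tau = compute_irts(licks)
        chunks.append(tau)
        total += len(tau)
        k += 1
    return np.concatenate(chunks)[:n_irts]


def circle_points(radius, center=(0.0, 0.0), n=8, phase=0.0):
    ang = np.deg2rad(np.arange(0, 360, 360 / n)) + phase
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def ellipse_points(a, b, center=(0.0, 0.0), theta=0.0, n=8, phase=0.0):
    ang = np.deg2rad(np.arange(0, 360, 360 / n)) + phase
    x = a * np.cos(ang)
    y = b * np.sin(ang)
    c, s = np.cos(theta), np.sin(theta)
    return np.column_stack(
        [center[0] + c * x - s * y, center[1] + s * x + c * y]
    )
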