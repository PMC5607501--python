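import numpy as np
import pytest

from cmrmulti.synthetic import (
    CineSpec,
    Lesion,
    PhantomSpec,
    circle_contour,
    simulate_cine,
    simulate_heart_phantom,
)

ECHO_TIMES = np.arange(16.0, 97.0, 16.0)


@pytest.fixture(scope="session")
def clean_phantom():
    """Lesion-free, noise-free phantom: constant T2 on an annulus."""
    return simulate_heart_phantom(
        PhantomSpec(grid_size=64, r_endo=10.0, r_epi=20.0, base_t2=60.0, sigma=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def lesion_phantom():
    """One 60-degree basal lesion, +20 ms, no jitter, noise-free."""
    lesion = Lesion(
        center_angle_deg=30.0,
        extent_deg=60.0,
        transmural_fraction=1.0,
        delta_t2=20.0,
        t2_spread=0.0,
        level="basal",
    )
    return simulate_heart_phantom(
        PhantomSpec(
            grid_size=64,
            r_endo=10.0,
            r_epi=20.0,
            base_t2=60.0,
            lesions=(lesion,),
            rv_insertion_angle=0.0,
            sigma=0.0,
            seed=0,
        )
    )


def sine_squared_strain(n_frames: int, peak: float) -> tuple[float, ...]:
    t = np.arange(n_frames) / n_frames
    eps = peak * np.sin(np.pi * t) ** 2
    eps[0] = 0.0
    return tuple(eps)


@pytest.fixture(scope="session")
def contracting_cine():
    """25%-contraction ring phantom with mild image noise."""
    spec = CineSpec(
        n_frames=20,
        contour=circle_contour((64.0, 64.0), 26.0, 48),
        strain_curve=sine_squared_strain(20, -25.0),
        noise_sd=2.0,
        seed=11,
    )
    return simulate_cine(spec)
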