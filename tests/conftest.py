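import pytest

from gcsdn.simulate import (
    CONSERVATIVE,
    STRATEGIST,
    NetworkSpec,
    ScanParams,
    simulate_subject,
    simulate_var_bekk,
)


def scalar_network(a: float = 0.5, b: float = 0.4, c: float = 1.0) -> NetworkSpec:
    """Single-region AR-BEKK network used across the model tests."""
    return NetworkSpec(
        regions=("x",),
        self_coeffs={"x": a},
        var_coeffs={("x", "x"): b},
        base_noise={"x": c},
    )


def pair_network(
    a: float = 0.5,
    b_own: float = 0.3,
    d: float = 0.0,
    b_cross: float = 0.0,
) -> NetworkSpec:
    """Two-region network with driver y -> target x couplings."""
    return NetworkSpec(
        regions=("x", "y"),
        self_coeffs={"x": a, "y": a},
        var_coeffs={("x", "x"): b_own, ("y", "y"): b_own, ("y", "x"): b_cross},
        mean_coeffs={("y", "x"): d} if d else {},
        base_noise={"x": 1.0, "y": 1.0},
    )


@pytest.fixture(scope="session")
def bekk_series_2000():
    """A T=2000 scalar AR-BEKK path at the canonical (0.5, 0.4, 1.0)."""
    return simulate_var_bekk(scalar_network(), 2000, seed=42)[:, 0]


_REGIONS = ("rPFC", "DLPFC", "RSC", "dACC", "MPC")


def five_region_network() -> NetworkSpec:
    """Five independent regions with own-signal SDN and no cross edges."""
    return NetworkSpec(
        regions=_REGIONS,
        self_coeffs={r: 0.5 for r in _REGIONS},
        var_coeffs={(r, r): 0.35 for r in _REGIONS},
        base_noise={r: 1.0 for r in _REGIONS},
    )


@pytest.fixture(scope="session")
def strategist_subject():
    return simulate_subject(STRATEGIST, five_region_network(), ScanParams(),
                            seed=7, subject_id="S001")


@pytest.fixture(scope="session")
def conservative_subject():
    return simulate_subject(CONSERVATIVE, five_region_network(), ScanParams(),
                            seed=11, subject_id="S002")
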