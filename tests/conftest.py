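"""Shared fixtures: expensive equilibrations computed once per session."""
from __future__ import annotations

import pytest

import hpaxis as hx
from hpaxis import challenge as ch


@pytest.fixture(scope="session")
def ref():
    """The reference parameter set."""
    return hx.REFERENCE


@pytest.fixture(scope="session")
def ref_fixed_points(ref):
    """Classified nullcline intersections of the reference set."""
    return hx.find_fixed_points(ref)


@pytest.fixture(scope="session")
def dst_results(ref, ref_fixed_points):
    """The four DST runs: {(basin, mode): SuppressionResult}."""
    out = {}
    for basin in ("normal", "diseased"):
        for mode in ("period_averaged", "instantaneous"):
            proto = ch.dex_protocol(measurement_mode=mode)
            out[(basin, mode)] = hx.run_dex_test(
                ref, basin, protocol=proto, fixed_points=ref_fixed_points
            )
    return out


@pytest.fixture(scope="session")
def acth_sweeps(ref):
    """Phase sweeps of the stimulation test for normal and hyporeactive glands."""
    return {
        lam: hx.phase_sweep_acth(ref, lam, n_phases=8)
        for lam in (1.0, 0.9)
    }


@pytest.fixture(scope="session")
def two_stage_results(ref, ref_fixed_points):
    """Two-stage (DEX + stressor) runs from both basins."""
    return {
        basin: hx.run_two_stage_test(ref, basin, fixed_points=ref_fixed_points)
        for basin in ("normal", "diseased")
    }
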