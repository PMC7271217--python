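"""Shared fixtures: the heavyweight solver runs are executed once per
session and reused by the validation, coupling and acceptance tests."""

import pytest

from coaflow.coupling import RunConfig, run_coupled


def coa_patient():
    return dict(SV=60, HR=75, ejection_time=0.3, A_ao=5.0, EOA_av=2.0,
                EOA_coa=0.9, A_dist=3.8, P_sys=140, P_dia=85)


def straight_config(**overrides):
    """Coarse straight-tube (healthy-template) coupled run configuration.

    The lattice runs a reduced-Reynolds version of the flow (viscosity
    scaled up, coarse grid) so a full multi-cycle coupled simulation fits in
    test time; conservation, determinism and monotonicity properties are
    unaffected by the scaling.
    """
    cfg = dict(
        patient=coa_patient(),
        geometry=dict(kind="straight", R0=0.011, L=0.06),
        dx=1.375e-3, dt=1.3e-4, nu_phys=1.67e-4, les=True,
        warmup_cycles=1, measured_cycles=2, phases_per_cycle=16,
    )
    cfg.update(overrides)
    return RunConfig(**cfg)


def coarctation_config(**overrides):
    """Matched coarctation run: same inflow, ~56% throat area."""
    return straight_config(
        geometry=dict(kind="coarctation", L=0.06, R0=0.011,
                      R_throat=0.00825, z0=0.03, w=0.012),
        dt=6.5e-5, **overrides)


@pytest.fixture(scope="session")
def straight_run():
    report, artifacts = run_coupled(straight_config())
    return report, artifacts


@pytest.fixture(scope="session")
def coarctation_run():
    report, artifacts = run_coupled(coarctation_config())
    return report, artifacts


@pytest.fixture(scope="session")
def poiseuille_result():
    from coaflow.validation import poiseuille_tube_benchmark

    return poiseuille_tube_benchmark()


@pytest.fixture(scope="session")
def inclined_result():
    from coaflow.validation import inclined_channel_benchmark

    return inclined_channel_benchmark()


@pytest.fixture(scope="session")
def les_result():
    from coaflow.validation import les_laminar_benchmark

    return les_laminar_benchmark()
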