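"""Shared fixtures: a small stickleback-style experiment and synthetic files.

Everything is generated at test time by the package's own simulator; no data
files ship with the repository.
"""

from __future__ import annotations

import pytest

from ifresp import BackgroundSpec, SimSpec, build_info, generate_background_test, generate_experiment


@pytest.fixture(scope="session")
def info4():
    """Four swim-tunnel chambers, stickleback-sized fish, mg/L."""
    return build_info(
        ids=["Stickleback_1", "Stickleback_2", "Stickleback_3", "Stickleback_4"],
        masses=[1.86, 1.92, 2.23, 1.80],
        volumes=[250.0, 250.0, 250.0, 250.0],
        do_unit="mg/L",
    )


@pytest.fixture(scope="session")
def exp_spec(info4):
    """8-cycle run with exponentially growing background, noise-free."""
    return SimSpec(
        chambers=info4.chambers,
        true_mo2=(200.0, 210.0, 190.0, 205.0),
        flush_s=120,
        wait_s=60,
        measure_s=600,
        n_cycles=8,
        background=BackgroundSpec("exponential", -0.10, -0.30),
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def exp_files(exp_spec, tmp_path_factory):
    """Generated measurement + pre/post blank files and the ground-truth table."""
    d = tmp_path_factory.mktemp("exp")
    truth = generate_experiment(exp_spec, d / "meas.txt", d / "truth.csv")
    generate_background_test(exp_spec, "pre", d / "pre.txt")
    generate_background_test(exp_spec, "post", d / "post.txt")
    return {"dir": d, "meas": d / "meas.txt", "pre": d / "pre.txt",
            "post": d / "post.txt", "truth": truth}
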