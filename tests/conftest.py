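"""Shared fixtures: synthetic sessions generated once per test run."""

from __future__ import annotations

import numpy as np
import pytest

from dspike.synthetic import SimParams, generate_session, simulate_session


@pytest.fixture(scope="session")
def default_params() -> SimParams:
    """The standard study conditions: 600 s, 0.3 Hz DS2 / 0.05 Hz DS1 /
    0.3 Hz SPW-R during immobility, 2 mV DS over 0.1 mV noise, 50 place
    cells."""
    return SimParams(duration=600.0, rng_seed=1)


@pytest.fixture(scope="session")
def session600(default_params):
    """In-memory default session + ground truth (generated once)."""
    return simulate_session(default_params)


@pytest.fixture(scope="session")
def session600_dir(default_params, tmp_path_factory):
    """The same standard conditions written to disk (fresh seed so the
    on-disk session is independent of the in-memory fixture)."""
    params = SimParams(duration=600.0, rng_seed=2)
    out = tmp_path_factory.mktemp("session600")
    path, truth = generate_session(params, out / "sess")
    return path, truth, params


def match_events(detected_times: np.ndarray, true_times: np.ndarray,
                 tol_s: float = 0.010) -> tuple[float, float]:
    """(recall, false-positive fraction) for detected vs injected times."""
    if len(true_times) == 0:
        return np.nan, 1.0 if len(detected_times) else 0.0
    hits = sum(
        1 for t in true_times
        if detected_times.size and np.min(np.abs(detected_times - t)) <= tol_s
    )
    fps = sum(
        1 for t in detected_times
        if np.min(np.abs(true_times - t)) > tol_s
    )
    recall = hits / len(true_times)
    fp_frac = fps / max(1, len(detected_times))
    return recall, fp_frac
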