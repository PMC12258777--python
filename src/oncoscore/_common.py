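"""Shared error types, seeding scheme, and endpoint vocabulary.

All stochastic code in this package draws from :func:`substream`, which
derives an independent ``numpy.random.Generator`` from a single user seed
and a small fixed stream id. Modules therefore reproduce independently:
re-running one stage with the same seed gives the same draws regardless of
what ran before it.
"""

from __future__ import annotations

import numpy as np

#: Time-to-event endpoints tracked throughout the pipeline.
ENDPOINTS = ("DRFI", "RFI", "DFS", "OS", "BCSS")

# Fixed stream ids; the pair (seed, stream) keys an independent generator.
STREAM_SCORES = 0
STREAM_ARMS = 1
STREAM_SURVIVAL = 2
STREAM_SLIDES = 3
STREAM_CLINICAL = 4
STREAM_CALIBRATION = 5
STREAM_AUGMENT = 6
STREAM_BOOTSTRAP = 7
STREAM_TRIALS = 8


class OncoscoreError(Exception):
    """Base class for package errors."""


class ConfigError(OncoscoreError):
    """Invalid configuration (bad rates, proportions, thresholds ...)."""


class DataError(OncoscoreError):
    """Structurally invalid or degenerate data at run time."""


def substream(seed: int, stream: int) -> np.random.Generator:
    """Independent generator keyed by ``(seed, stream)``.

    Uses ``SeedSequence`` entropy mixing, so distinct stream ids give
    statistically independent streams from one master seed.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def check_proportion(name: str, value: float, *, open_left: bool = False,
                     open_right: bool = False) -> None:
    lo_ok = value > 0 if open_left else value >= 0
    hi_ok = value < 1 if open_right else value <= 1
    if not (np.isfinite(value) and lo_ok and hi_ok):
        raise ConfigError(f"{name} must be a proportion in "
                          f"{'(' if open_left else '['}0, 1{')' if open_right else ']'}; "
                          f"got {value!r}")
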