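"""Shared fixtures: cached pacing runs reused across test modules.

The heavy scenario simulations (500 paced beats each, the protocol used
for all reported quantities) are computed once per session and shared.
"""

from __future__ import annotations

from functools import lru_cache

import pytest

from ordcamk.protocols import run_protocol, scenario


@lru_cache(maxsize=None)
def _run(cycle_length: float, ikr_block: float, iso_uM: float,
         overexpressed: str | None, n_beats: int, n_trace_beats: int):
    prot, reg = scenario(cycle_length, ikr_block=ikr_block, iso_uM=iso_uM,
                         overexpressed=overexpressed, n_beats=n_beats,
                         n_trace_beats=n_trace_beats)
    return run_protocol(prot, reg)


class SimCache:
    """Session-wide access point for paced scenario runs."""

    @staticmethod
    def run(cycle_length=2000.0, ikr_block=0.0, iso_uM=0.0,
            overexpressed=None, n_beats=500, n_trace_beats=8):
        return _run(cycle_length, ikr_block, iso_uM, overexpressed,
                    n_beats, n_trace_beats)


@pytest.fixture(scope="session")
def sim() -> SimCache:
    return SimCache()
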