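"""Shared fixtures: synthetic tables generated once per session."""

import numpy as np
import pytest

from premotif.mutability import ERMTable, HexamerRateTable
from premotif.synthetic_data import SynthSpec, gen_erm_table, gen_score_table


@pytest.fixture(scope="session")
def synth_spec() -> SynthSpec:
    return SynthSpec()


@pytest.fixture(scope="session")
def synth_erm(synth_spec) -> ERMTable:
    """Default synthetic heptamer rate table (hotspots + heavy tail)."""
    return gen_erm_table(synth_spec, np.random.default_rng(101))


@pytest.fixture(scope="session")
def hex_rates(synth_erm) -> HexamerRateTable:
    return HexamerRateTable.from_erm(synth_erm)


@pytest.fixture(scope="session")
def synth_ei(synth_spec, hex_rates):
    """Activity scores coupled to mutability at the default rho."""
    return gen_score_table(synth_spec, hex_rates, np.random.default_rng(102))


@pytest.fixture(scope="session")
def uniform_erm() -> ERMTable:
    return ERMTable.uniform(1.0)


@pytest.fixture(scope="session")
def hot_cold_erm() -> ERMTable:
    """Rates depending only on the middle base: A hot, T cold, C/G neutral.

    Makes AAAAAA the most and TTTTTT the least mutable hexamer, with no
    context effects — handy for directional motif-depletion checks.
    """
    by_mid = {0: 10.0, 1: 1.0, 2: 1.0, 3: 0.1}
    mid = ERMTable.middle_bases()
    rates = np.array([by_mid[int(m)] for m in mid])[:, None] * np.ones(4)
    rates[np.arange(len(mid)), mid] = np.nan
    return ERMTable(rates)
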