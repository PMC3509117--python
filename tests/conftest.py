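from collections import Counter

import pytest

from ystrpop import Dataset, LocusPanel, PopulationSample, STRHaplotype


@pytest.fixture
def panel2():
    return LocusPanel(("DYS19", "DYS390"))


@pytest.fixture
def make_pop():
    """Factory: build a PopulationSample from repeat tuples (with repeats)."""

    def _make(haps, name="pop", group="", panel=None):
        c = Counter(STRHaplotype(tuple(h)) for h in haps)
        return PopulationSample(name, c, group=group, panel=panel)

    return _make


@pytest.fixture
def make_dataset(make_pop):
    """Factory: dataset from {pop_name: [tuples]} plus optional group map."""

    def _make(pops: dict, groups: dict | None = None, L: int | None = None):
        first = next(iter(pops.values()))[0]
        L = L or len(first)
        panel = LocusPanel(tuple(f"DYS{i + 1:03d}" for i in range(L)))
        samples = [
            make_pop(haps, name=name, group=(groups or {}).get(name, ""), panel=panel)
            for name, haps in pops.items()
        ]
        return Dataset(panel, samples)

    return _make


@pytest.fixture(scope="session")
def default_scenario():
    from ystrpop import simulate_roma_scenario

    return simulate_roma_scenario(seed=0)
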