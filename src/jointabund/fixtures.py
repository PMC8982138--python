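"""Deterministic hand-sized fixtures shared by the test surfaces.

Fixtures are tiny worked examples stored as plain delimited text inside
the package, separate from the stochastic simulator: no RNG, no network.
Expected values carry provenance notes in the accompanying JSON files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .data import ConcentrationTable, CountTable, read_concentration_table, read_count_table

__all__ = ["Fixture", "load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("tiny_2x3", "single_taxon", "zero_heavy")


@dataclass(frozen=True)
class Fixture:
    """An immutable worked example: paired tables plus expected outputs."""

    name: str
    counts: CountTable
    concentrations: ConcentrationTable
    expected: dict

    @property
    def W(self):
        return self.counts.W

    @property
    def V(self):
        return self.concentrations.V


def load_fixture(name: str) -> Fixture:
    """Load a registered fixture by name.

    Available: ``tiny_2x3`` (n=2, q=3, qobs=2, the scaling-factor worked
    numbers), ``single_taxon`` (n=1, q=1, M=W closure), ``zero_heavy``
    (mostly-zero counts including a sample with no observed reads).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    base = resources.files("jointabund") / "fixtures_data"
    with resources.as_file(base / f"{name}_W.csv") as p:
        counts = read_count_table(p)
    with resources.as_file(base / f"{name}_V.csv") as p:
        conc = read_concentration_table(p)
    expected = json.loads((base / f"{name}_expected.json").read_text())
    return Fixture(name=name, counts=counts, concentrations=conc, expected=expected)
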