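"""Deterministic bilayer configurations for tests, examples and rendering.

Each fixture is a named, fully reproducible pattern: homogeneous states,
the two fully asymmetric layer pairings, a checkerboard, a single defector
island and a half/half CD|DC stripe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import BilayerState
from .errors import InvalidParameterError

__all__ = ["Fixture", "FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = (
    "all_C",
    "all_D",
    "layer_CD",
    "layer_DC",
    "checkerboard",
    "single_D_island",
    "stripe_CD_DC",
)


@dataclass(frozen=True)
class Fixture:
    name: str
    state: BilayerState
    description: str


def make_fixture(name: str, L: int) -> Fixture:
    """Build the named deterministic pattern on an L x L bilayer."""
    if name not in FIXTURE_NAMES:
        raise InvalidParameterError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if L < 2:
        raise InvalidParameterError(f"L must be >= 2, got {L}")
    plus = np.zeros((L, L), dtype=np.int8)
    minus = np.zeros((L, L), dtype=np.int8)
    if name == "all_C":
        plus[:], minus[:] = 1, 1
        desc = "both layers homogeneous cooperation (CC absorbing state)"
    elif name == "all_D":
        desc = "both layers homogeneous defection (DD absorbing state)"
    elif name == "layer_CD":
        plus[:] = 1
        desc = "layer +1 all C, layer -1 all D (fully asymmetric CD state)"
    elif name == "layer_DC":
        minus[:] = 1
        desc = "layer +1 all D, layer -1 all C (fully asymmetric DC state)"
    elif name == "checkerboard":
        idx = np.indices((L, L)).sum(axis=0) % 2 == 0
        plus[idx] = 1
        minus[idx] = 1
        desc = "identical checkerboards in both layers (aligned, rho = 1/2)"
    elif name == "single_D_island":
        plus[:], minus[:] = 1, 1
        c = L // 2
        plus[c, c] = 0
        minus[c, c] = 0
        desc = "one DD cell in an otherwise all-cooperator bilayer"
    else:  # stripe_CD_DC
        half = L // 2
        plus[:, :half] = 1
        minus[:, half:] = 1
        desc = "left half CD pairs, right half DC pairs (domain wall)"
    return Fixture(name=name, state=BilayerState(np.stack([minus, plus])), description=desc)
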