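"""EQ-5D-5L health states and value-set scoring.

An EQ-5D-5L health state records one of five impairment levels (1 = no
problems … 5 = extreme problems) on each of five dimensions — mobility,
self-care, usual activities, pain/discomfort, anxiety/depression — so
5**5 = 3,125 distinct states can be described.  A *value set* maps each
state to a preference weight ("utility") anchored at 1 for full health
("11111") and 0 for dead; states rated worse than death score below 0.

Value sets are pluggable.  Two additive sets ship with the package:

* ``toy`` — utility = 1 − 0.05·Σ(level − 1); range [0, 1]; used in tests.
* ``synthetic-au-range`` — a synthetic decrement table calibrated so the
  utility range is exactly [−0.676, 1], matching the range of the published
  Australian EQ-5D-5L value set.  The decrements themselves are invented;
  load the published tariff from a user-supplied file for real analyses.

User files are accepted in two CSV layouts: a full 3,125-row lookup
``state,utility`` or an additive decrement table
``dimension,level,decrement`` (decrement at level 1 must be 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

N_STATES = 5**5

FULL_HEALTH = "11111"


class ValueSetError(ValueError):
    """Raised when a value-set file violates the value-set contract."""


@dataclass(frozen=True)
class HealthState:
    """One EQ-5D-5L health state, e.g. ``HealthState.from_code("21345")``."""

    levels: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != 5:
            raise ValueError(f"expected 5 dimension levels, got {len(self.levels)}")
        for dim, lv in zip(DIMENSIONS, self.levels):
            if not (1 <= int(lv) <= 5):
                raise ValueError(f"level {lv!r} for dimension {dim!r} outside 1..5")

    @classmethod
    def from_code(cls, code: str) -> "HealthState":
        code = str(code).strip()
        if len(code) != 5 or not code.isdigit():
            raise ValueError(f"state code {code!r} is not a five-digit string")
        return cls(tuple(int(c) for c in code))  # levels validated in __post_init__

    @property
    def code(self) -> str:
        return "".join(str(lv) for lv in self.levels)


def enumerate_states() -> list[HealthState]:
    """All 3,125 health states in lexicographic code order ("11111" first)."""
    return [HealthState(levels) for levels in itertools.product(range(1, 6), repeat=5)]


@dataclass
class ValueSet:
    """A total mapping from the 3,125 EQ-5D-5L states to utilities.

    ``utilities`` is indexed by five-digit state code.  Anchors are enforced
    at construction: utility("11111") must be exactly 1 and every state must
    be present.  ``min_utility`` is the utility of the worst-valued state.
    """

    name: str
    utilities: dict[str, float]
    min_utility: float = field(init=False)
    max_utility: float = field(init=False)

    def __post_init__(self) -> None:
        codes = {s.code for s in enumerate_states()}
        missing = sorted(codes - set(self.utilities))
        if missing:
            raise ValueSetError(
                f"value set {self.name!r} incomplete: {len(missing)} states missing "
                f"(first missing: {missing[0]})"
            )
        extra = set(self.utilities) - codes
        if extra:
            raise ValueSetError(f"value set {self.name!r} has unknown states: {sorted(extra)[:3]}")
        if self.utilities[FULL_HEALTH] != 1.0:
            raise ValueSetError(
                f"value set {self.name!r} violates the full-health anchor: "
                f"utility('11111') = {self.utilities[FULL_HEALTH]!r}, expected 1.0"
            )
        vals = np.fromiter(self.utilities.values(), dtype=float, count=N_STATES)
        self.min_utility = float(vals.min())
        self.max_utility = float(vals.max())

    def score(self, state: HealthState | str) -> float:
        """Utility of ``state`` under this value set (pure lookup)."""
        if isinstance(state, str):
            state = HealthState.from_code(state)
        return self.utilities[state.code]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(codes, utilities) as parallel arrays sorted by utility.

        Used by the trial simulator to snap a latent continuous utility to
        the nearest representable state.
        """
        codes = np.array(list(self.utilities.keys()))
        utils = np.array(list(self.utilities.values()), dtype=float)
        order = np.argsort(utils, kind="stable")
        return codes[order], utils[order]


def score_state(state: HealthState | str, value_set: ValueSet) -> float:
    """Score one health state; returns a utility in [min_utility, 1]."""
    return value_set.score(state)


def _expand_decrements(table: pd.DataFrame, name: str) -> dict[str, float]:
    dec: dict[str, dict[int, float]] = {}
    for row in table.itertuples(index=False):
        dim = str(row.dimension).strip()
        if dim not in DIMENSIONS:
            raise ValueSetError(f"unknown dimension {dim!r} (expected one of {DIMENSIONS})")
        dec.setdefault(dim, {})[int(row.level)] = float(row.decrement)
    for dim in DIMENSIONS:
        levels = dec.get(dim, {})
        if sorted(levels) != [1, 2, 3, 4, 5]:
            raise ValueSetError(f"dimension {dim!r}: need decrements for levels 1..5")
        if levels[1] != 0.0:
            raise ValueSetError(f"dimension {dim!r}: level-1 decrement must be 0")
        steps = [levels[k] for k in range(1, 6)]
        if any(b < a for a, b in zip(steps, steps[1:])):
            raise ValueSetError(f"dimension {dim!r}: decrements must be non-decreasing in level")
    utilities = {}
    for state in enumerate_states():
        total = sum(dec[dim][lv] for dim, lv in zip(DIMENSIONS, state.levels))
        utilities[state.code] = 1.0 - total
    return utilities


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_value_set(path_or_name: str | Path) -> ValueSet:
    """Load a value set from a file or by bundled name.

    Bundled names: ``"toy"`` and ``"synthetic-au-range"``.  Files may be a
    full ``state,utility`` lookup (3,125 rows) or an additive
    ``dimension,level,decrement`` table.  Anchor and completeness are
    validated here, at load time, so scoring never fails later.
    """
    bundled = {"toy": "toy_valueset.csv", "synthetic-au-range": "synthetic_au_range_valueset.csv"}
    if str(path_or_name) in bundled:
        name = str(path_or_name)
        ref = resources.files("ceatrial.data") / bundled[name]
        with resources.as_file(ref) as p:
            table = _read_csv(p)
    else:
        path = Path(path_or_name)
        if not path.exists():
            raise FileNotFoundError(f"value-set file not found: {path}")
        name = path.stem
        table = _read_csv(path)

    cols = set(table.columns)
    if {"dimension", "level", "decrement"} <= cols:
        utilities = _expand_decrements(table, name)
    elif {"state", "utility"} <= cols:
        utilities = {
            str(s).strip(): float(u) for s, u in zip(table["state"], table["utility"])
        }
    else:
        raise ValueSetError(
            "unrecognised value-set layout: expected columns "
            "(dimension, level, decrement) or (state, utility)"
        )
    return ValueSet(name=name, utilities=utilities)


def toy_value_set() -> ValueSet:
    """The bundled toy additive set (range [0, 1])."""
    return load_value_set("toy")
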