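"""Survey cost accounting: fixed and variable costs per sampling method.

A method's fixed cost is a one-off investment (traps, recorders, storage)
charged once as soon as the method is used at all; its variable cost
accrues per sample unit (a survey night, a site-visit, a person-hour).
The cost of an allocation of sample units over methods is therefore

    cost = sum_m [ fixed_m * 1(n_m > 0) + variable_m * n_m ].

Currency is an opaque unit; time or person-hours can stand in for money
by setting fixed costs to zero and variable costs to effort per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = ["MethodCost", "CostModel", "Combination", "combination_cost", "cost_fraction", "CostError"]


class CostError(ValueError):
    pass


@dataclass(frozen=True)
class MethodCost:
    fixed: float = 0.0
    variable: float = 0.0
    unit_description: str = ""

    def __post_init__(self):
        if self.fixed < 0 or self.variable < 0:
            raise CostError("costs must be non-negative")


@dataclass(frozen=True)
class CostModel:
    """Per-method fixed and variable costs."""

    methods: Mapping[str, MethodCost]

    def __post_init__(self):
        object.__setattr__(self, "methods", dict(self.methods))

    def __getitem__(self, method: str) -> MethodCost:
        try:
            return self.methods[method]
        except KeyError:
            raise CostError(f"unknown method {method!r}") from None

    @classmethod
    def uniform(cls, methods, fixed: float = 0.0, variable: float = 1.0) -> "CostModel":
        """Equal costs for every method (e.g. one person-hour per sample)."""
        return cls({m: MethodCost(fixed, variable) for m in methods})

    @classmethod
    def from_yaml(cls, path) -> "CostModel":
        """Read ``method: {fixed, variable, unit_description}`` from YAML."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            {
                name: MethodCost(
                    float(spec.get("fixed", 0.0)),
                    float(spec.get("variable", 0.0)),
                    str(spec.get("unit_description", "")),
                )
                for name, spec in raw.items()
            }
        )

    def to_yaml(self, path) -> None:
        raw = {
            name: {
                "fixed": mc.fixed,
                "variable": mc.variable,
                "unit_description": mc.unit_description,
            }
            for name, mc in self.methods.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


@dataclass(frozen=True)
class Combination:
    """Allocation of sample units per method (a candidate protocol)."""

    counts: Mapping[str, int]

    def __post_init__(self):
        counts = {m: int(n) for m, n in self.counts.items()}
        if any(n < 0 for n in counts.values()):
            raise CostError("sample counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, method: str) -> int:
        return self.counts.get(method, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def key(self, methods=None) -> tuple:
        """Canonical (method-name-sorted) count tuple, for ordering and ties."""
        methods = sorted(self.counts) if methods is None else list(methods)
        return tuple(self[m] for m in methods)

    def add(self, method: str, k: int = 1) -> "Combination":
        counts = dict(self.counts)
        counts[method] = counts.get(method, 0) + k
        return Combination(counts)

    def contains(self, other: "Combination") -> bool:
        return all(self[m] >= n for m, n in other.counts.items())

    def __str__(self) -> str:
        return "+".join(f"{n}x{m}" for m, n in sorted(self.counts.items()) if n) or "empty"


def combination_cost(comb: Combination, cost_model: CostModel) -> float:
    """Total cost of an allocation: fixed costs of every method used plus
    variable costs times the number of sample units."""
    total = 0.0
    for method, n in comb.counts.items():
        mc = cost_model[method]
        if n > 0:
            total += mc.fixed + mc.variable * n
    return total


def cost_fraction(comb: Combination, full: Combination, cost_model: CostModel) -> float:
    """Cost of an allocation relative to a full scheme, in [0, 1]."""
    if not full.contains(comb):
        raise CostError("combination exceeds the full scheme")
    denom = combination_cost(full, cost_model)
    if denom == 0:
        raise CostError("full scheme has zero cost")
    return combination_cost(comb, cost_model) / denom
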