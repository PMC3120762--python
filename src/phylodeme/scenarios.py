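"""The ten candidate gene-flow models for a 3-deme colonization history.

Taking each deme in turn as the origin, a colonization history either
seeded the other two demes independently (``X>Y, X>Z``) or seeded one
which then seeded the other (``X>Y>Z``).  That yields nine constrained
hypotheses; the unconstrained "full model" with all six migration rates
free completes the candidate set.

Direction convention: a forward-time colonization edge ``X>Y`` means gene
flow from X into Y, which traced backward in time is lineage movement
from Y to X.  The scenario's mask therefore frees the backward rate
``M[Y, X]`` and pins every other off-diagonal entry to zero.  Every
constrained model has k = 5 free parameters (three deme sizes plus two
rates); the full model has k = 9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FULL_MODEL_NAME = "full model"


@dataclass(frozen=True)
class MigrationScenario:
    """One colonization hypothesis as a constraint mask over migration rates."""

    name: str
    kind: str                       # "independent", "sequential" or "full"
    origin: str | None              # origin deme label; None for the full model
    edges: tuple[tuple[str, str], ...]  # forward-time colonization edges (X, Y)

    def __post_init__(self) -> None:
        if self.kind not in ("independent", "sequential", "full"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "sequential":
            (a, b), (c, d) = self.edges
            if a != self.origin or b != c:
                raise ValueError("sequential edges must chain from the origin")
        if self.kind == "independent":
            if any(e[0] != self.origin for e in self.edges):
                raise ValueError("independent edges must both leave the origin")

    @property
    def k(self) -> int:
        """Free parameters: three deme sizes plus the free migration rates."""
        return 3 + self.n_free_rates

    @property
    def n_free_rates(self) -> int:
        return 6 if self.kind == "full" else len(self.edges)

    def backward_mask(self, deme_labels: tuple[str, ...]) -> np.ndarray:
        """Boolean matrix of free backward rates; ``mask[i, j]`` frees M[i->j]."""
        d = len(deme_labels)
        idx = {l: i for i, l in enumerate(deme_labels)}
        mask = np.zeros((d, d), dtype=bool)
        if self.kind == "full":
            mask[:] = True
            np.fill_diagonal(mask, False)
            return mask
        for x, y in self.edges:
            mask[idx[y], idx[x]] = True   # forward X>Y == backward Y->X
        return mask

    def free_entries(self, deme_labels: tuple[str, ...]) -> list[tuple[int, int]]:
        mask = self.backward_mask(deme_labels)
        return [(i, j) for i in range(len(deme_labels)) for j in range(len(deme_labels)) if mask[i, j]]

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind, "origin": self.origin,
                "edges": [list(e) for e in self.edges], "k": self.k}

    @classmethod
    def from_dict(cls, d: dict) -> "MigrationScenario":
        return cls(d["name"], d["kind"], d["origin"], tuple(tuple(e) for e in d["edges"]))


def enumerate_scenarios(deme_labels: tuple[str, ...] = ("F", "S", "A")) -> list[MigrationScenario]:
    """All nine constrained colonization hypotheses plus the full model.

    For each origin X the other two demes are listed in cyclic order of
    the label tuple, which reproduces the conventional names
    (``F>S, F>A`` / ``S>A, S>F`` / ``A>F, A>S`` for the independent
    models).  Only the 3-deme case is supported.
    """
    if len(deme_labels) != 3:
        raise ValueError("scenario enumeration is defined for exactly 3 demes")
    if len(set(deme_labels)) != 3:
        raise ValueError("deme labels must be distinct")
    out: list[MigrationScenario] = []
    d = 3
    for oi, origin in enumerate(deme_labels):
        c1 = deme_labels[(oi + 1) % d]
        c2 = deme_labels[(oi + 2) % d]
        out.append(MigrationScenario(
            f"{origin}>{c1}, {origin}>{c2}", "independent", origin,
            ((origin, c1), (origin, c2))))
        for first, second in ((c1, c2), (c2, c1)):
            out.append(MigrationScenario(
                f"{origin}>{first}>{second}", "sequential", origin,
                ((origin, first), (first, second))))
    out.append(MigrationScenario(FULL_MODEL_NAME, "full", None, ()))
    return out


def get_scenario(name: str, deme_labels: tuple[str, ...] = ("F", "S", "A")) -> MigrationScenario:
    for s in enumerate_scenarios(deme_labels):
        if s.name == name:
            return s
    raise KeyError(f"unknown scenario {name!r}")


def scenario_to_matrix(scenario: MigrationScenario,
                       deme_labels: tuple[str, ...] = ("F", "S", "A")) -> np.ndarray:
    """Constraint mask over backward migration rates (True = free)."""
    return scenario.backward_mask(deme_labels)
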