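"""Directional response gene sets and the set algebra that derives them.

A drought experiment on hybrid/parent trios yields, per genotype, the genes
that respond to water deficit (WD vs WW contrast; "drought response genes",
DRG) and to re-watering (RW vs WD; "re-watering response genes", RRG), each
split by direction.  Sets shared by both hybrids are the conserved sets
(CDRG / CRRG).  Intersecting conserved response sets with the over- and
underdominant inheritance classes yields the four headline sets:

* DODG — upregulated conserved drought-response genes that are common
  overdominant genes under water deficit;
* DUDG — downregulated conserved drought-response genes that are common
  underdominant genes under water deficit;
* RODG / RUDG — the re-watering analogues (built on RW-condition dominance).

Every derived :class:`GeneSet` records its provenance (the operation and
parent set names), so a :class:`ResponseSets` collection can re-derive and
audit each member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "GeneSet",
    "ResponseSets",
    "response_genes",
    "conserved",
    "conserved_dominance_overlap",
    "reset_accounting",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with a direction and a provenance record.

    ``provenance`` is ``("leaf", <description>)`` for primary sets, or
    ``(<op>, parent_name, parent_name, ...)`` with ``op`` one of
    ``intersection`` / ``union`` / ``difference`` for derived sets.
    """

    name: str
    direction: str  # "up" | "down" | "both"
    genes: frozenset
    provenance: tuple = ("leaf", "unspecified")

    def __post_init__(self):
        if self.direction not in ("up", "down", "both"):
            raise ValueError(f"invalid direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.genes)


_OPS = {
    "intersection": lambda sets: frozenset.intersection(*sets),
    "union": lambda sets: frozenset().union(*sets),
    "difference": lambda sets: sets[0].difference(*sets[1:]),
}


@dataclass
class ResponseSets:
    """A collection of named gene sets with auditable provenance."""

    sets: dict = field(default_factory=dict)

    def add(self, gs: GeneSet) -> GeneSet:
        if gs.name in self.sets:
            raise ValueError(f"duplicate set name {gs.name!r}")
        self.sets[gs.name] = gs
        return gs

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list:
        return list(self.sets)

    # -- derivation helpers -------------------------------------------------

    def derive(self, name: str, op: str, parents: Iterable[str],
               direction: str) -> GeneSet:
        """Apply a set operation to named parents and register the result."""
        parents = tuple(parents)
        if op not in _OPS:
            raise ValueError(f"unknown set operation {op!r}")
        members = _OPS[op]([self.sets[p].genes for p in parents])
        return self.add(GeneSet(name, direction, members, (op, *parents)))

    def rederive(self, name: str) -> frozenset:
        """Recompute a set's membership from its provenance record.

        Leaf sets return their stored membership.
        """
        gs = self.sets[name]
        op = gs.provenance[0]
        if op == "leaf":
            return gs.genes
        return _OPS[op]([self.sets[p].genes for p in gs.provenance[1:]])

    def audit(self) -> None:
        """Assert that every derived set equals its re-derivation."""
        for name, gs in self.sets.items():
            if self.rederive(name) != gs.genes:
                raise AssertionError(
                    f"set {name!r} does not re-derive from its provenance")

    def summary(self) -> dict:
        return {name: len(gs) for name, gs in self.sets.items()}


def response_genes(de_results: pd.DataFrame, label: str,
                   phase: str) -> tuple:
    """Directional response sets from a DE result table.

    Parameters
    ----------
    de_results
        Output of :func:`heterotx.diffexpr.call_de` for the contrast
        WD vs WW (``phase="drought"``) or RW vs WD (``phase="rewatering"``).
    label
        Genotype label used in the set names (e.g. ``"AB"``).
    phase
        ``"drought"`` (DRG) or ``"rewatering"`` (RRG).

    Returns
    -------
    (up, down) : tuple of GeneSet
    """
    if phase not in ("drought", "rewatering"):
        raise ValueError(f"unknown phase {phase!r}")
    prefix = "DRG" if phase == "drought" else "RRG"
    up = frozenset(de_results.loc[de_results["call"] == "up", "gene_id"])
    down = frozenset(de_results.loc[de_results["call"] == "down", "gene_id"])
    contrast = str(de_results["contrast"].iloc[0]) if len(de_results) else ""
    return (
        GeneSet(f"{prefix}_{label}_up", "up", up, ("leaf", f"de:{contrast}:up")),
        GeneSet(f"{prefix}_{label}_down", "down", down,
                ("leaf", f"de:{contrast}:down")),
    )


def conserved(set_a: GeneSet, set_b: GeneSet, name: str,
              direction_stratified: bool = True) -> GeneSet:
    """Intersection of two genotypes' response sets (the conserved set).

    With ``direction_stratified`` (default) the two inputs must carry the
    same direction, mirroring per-direction conserved-set bookkeeping;
    disabling it intersects on gene identity only and the result direction
    is ``"both"``.
    """
    if direction_stratified:
        if set_a.direction != set_b.direction:
            raise ValueError(
                "direction-stratified intersection requires matching "
                f"directions, got {set_a.direction!r} and {set_b.direction!r}")
        direction = set_a.direction
    else:
        direction = "both"
    return GeneSet(name, direction, set_a.genes & set_b.genes,
                   ("intersection", set_a.name, set_b.name))


def conserved_dominance_overlap(rs: ResponseSets, conserved_up: str,
                                conserved_down: str, common_over: str,
                                common_under: str, phase: str) -> dict:
    """Overlap conserved response sets with common dominance classes.

    For ``phase="drought"`` this yields DODG (conserved upregulated drought
    response ∩ common overdominant) and DUDG (conserved downregulated ∩
    common underdominant); for ``phase="rewatering"`` the analogous
    RODG / RUDG.  The results are registered in ``rs`` with full provenance.
    """
    if phase == "drought":
        over_name, under_name = "DODG", "DUDG"
    elif phase == "rewatering":
        over_name, under_name = "RODG", "RUDG"
    else:
        raise ValueError(f"unknown phase {phase!r}")
    over = rs.derive(over_name, "intersection", (conserved_up, common_over),
                     direction="up")
    under = rs.derive(under_name, "intersection",
                      (conserved_down, common_under), direction="down")
    return {over_name: over, under_name: under}


def reset_accounting(rs: ResponseSets, drg_up: str, drg_down: str,
                     rrg_up: str, rrg_down: str) -> pd.DataFrame:
    """Partition drought-response sets into reset vs persistent genes.

    A drought-upregulated gene is *reset* if it is downregulated after
    re-watering (and symmetrically for drought-downregulated genes);
    otherwise it is *persistent*.  Fractions are relative to the size of the
    corresponding drought-response set (NaN when that set is empty).
    """
    parts = {
        "reset_up_down": ("intersection", (drg_up, rrg_down), "up", drg_up),
        "persistent_up": ("difference", (drg_up, rrg_down), "up", drg_up),
        "reset_down_up": ("intersection", (drg_down, rrg_up), "down", drg_down),
        "persistent_down": ("difference", (drg_down, rrg_up), "down", drg_down),
    }
    rows = []
    for name, (op, parents, direction, denom) in parts.items():
        gs = rs.derive(name, op, parents, direction)
        total = len(rs[denom])
        rows.append({
            "partition": name,
            "count": len(gs),
            "fraction": len(gs) / total if total else float("nan"),
        })
    return pd.DataFrame(rows).set_index("partition")
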