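"""Transfection-group design and the stochastic-DMR inequality chains.

The study design has nine transfection groups crossing the dCas9
methyltransferase construct (DNMT3A or DNMT3B catalytic-domain fusion,
catalytically dead point mutants, or none), the transfected dose (0, 50 or
500 ng) and the gRNA set (uPA, TGFBR3, scrambled or none).  Group 9 is the
pUC19 mock-transfection control.

Authentic dCas9-methyltransferase DMRs must respond monotonically to
enzyme dose and gRNA presence.  That expectation is encoded as ordered
inequality chains over group mean methylation: a hypermethylated DMR in the
uPA comparison must satisfy

    level(9) <= level(5) <= level(7) <= level(1)
    level(2) <= level(1)
    level(6) <= level(2)

and a hypomethylated DMR the mirrored (>=) chains; the TGFBR3 comparison
swaps groups 7->8, 1->3 and 2->4.  Chains are plain data so arbitrary
designs can be expressed in configuration without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .errors import ConfigurationError

CONSTRUCTS = ("DNMT3A", "DNMT3B", "DNMT3A-E752A", "DNMT3B-E697A", "none")
DOSES = (0, 50, 500)
GRNA_SETS = ("uPA", "TGFBR3", "scrambled", "none")


@dataclass(frozen=True)
class GroupSpec:
    """One transfection group: construct, dose (ng) and gRNA set."""

    group_id: int
    construct: str
    dose: int
    grna_set: str

    def __post_init__(self) -> None:
        if self.construct not in CONSTRUCTS:
            raise ConfigurationError(f"unknown construct {self.construct!r}")
        if self.dose not in DOSES:
            raise ConfigurationError(f"dose must be one of {DOSES}, got {self.dose}")
        if self.grna_set not in GRNA_SETS:
            raise ConfigurationError(f"unknown gRNA set {self.grna_set!r}")


@dataclass
class GroupDesign:
    """An ordered set of transfection groups plus a replicate count."""

    groups: List[GroupSpec]
    replicates: int = 1

    def __post_init__(self) -> None:
        ids = [g.group_id for g in self.groups]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate group ids in design")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")

    def group(self, group_id: int) -> GroupSpec:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(f"no group {group_id} in design")

    def sample_ids(self, group_id: int) -> List[str]:
        self.group(group_id)
        return [f"g{group_id}_r{r + 1}" for r in range(self.replicates)]

    def all_sample_ids(self) -> Dict[int, List[str]]:
        return {g.group_id: self.sample_ids(g.group_id) for g in self.groups}


def default_design(replicates: int = 1) -> GroupDesign:
    """The nine-group transfection design of the study.

    1: DNMT3A 500 ng + uPA gRNAs 500 ng       2: DNMT3B 500 ng + uPA 500 ng
    3: DNMT3A 500 ng + TGFBR3 500 ng          4: DNMT3B 500 ng + TGFBR3 500 ng
    5: DNMT3A 500 ng only                     6: DNMT3B 500 ng only
    7: DNMT3A 50 ng + uPA 50 ng               8: DNMT3A 50 ng + TGFBR3 50 ng
    9: pUC19 control (no construct, no gRNA)
    """
    rows = [
        (1, "DNMT3A", 500, "uPA"),
        (2, "DNMT3B", 500, "uPA"),
        (3, "DNMT3A", 500, "TGFBR3"),
        (4, "DNMT3B", 500, "TGFBR3"),
        (5, "DNMT3A", 500, "none"),
        (6, "DNMT3B", 500, "none"),
        (7, "DNMT3A", 50, "uPA"),
        (8, "DNMT3A", 50, "TGFBR3"),
        (9, "none", 0, "none"),
    ]
    return GroupDesign(
        groups=[GroupSpec(*row) for row in rows], replicates=replicates
    )


@dataclass(frozen=True)
class ChainConstraint:
    """An ordered chain of group ids.

    For a hypermethylated DMR every consecutive pair (l, r) must satisfy
    level(l) <= level(r); for a hypomethylated DMR the mirrored level(l) >=
    level(r).  Inequalities are non-strict: exact ties pass.
    """

    group_ids: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.group_ids) < 2:
            raise ConfigurationError("a chain needs at least two groups")

    @property
    def comparisons(self) -> List[Tuple[int, int]]:
        return list(zip(self.group_ids[:-1], self.group_ids[1:]))


@dataclass
class FilterDesign:
    """The chain set of one comparison design (e.g. uPA or TGFBR3)."""

    name: str
    chains: List[ChainConstraint]

    def validate_against(self, design: GroupDesign) -> None:
        known = {g.group_id for g in design.groups}
        for chain in self.chains:
            missing = set(chain.group_ids) - known
            if missing:
                raise ConfigurationError(
                    f"filter design {self.name!r} references unknown groups {sorted(missing)}"
                )

    def chained_groups(self) -> List[int]:
        seen: List[int] = []
        for chain in self.chains:
            for gid in chain.group_ids:
                if gid not in seen:
                    seen.append(gid)
        return seen


UPA_FILTER = FilterDesign(
    name="uPA",
    chains=[
        ChainConstraint((9, 5, 7, 1)),
        ChainConstraint((2, 1)),
        ChainConstraint((6, 2)),
    ],
)

TGFBR3_FILTER = FilterDesign(
    name="TGFBR3",
    chains=[
        ChainConstraint((9, 5, 8, 3)),
        ChainConstraint((4, 3)),
        ChainConstraint((6, 4)),
    ],
)

BUILTIN_FILTERS = {"uPA": UPA_FILTER, "TGFBR3": TGFBR3_FILTER}
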