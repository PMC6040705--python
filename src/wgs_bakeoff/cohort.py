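"""Cohort design: sample roles and trio bindings.

The study structure this models is a small case cohort in which one case is
the child of two healthy sequenced parents; roles drive the Mendel checks,
the patients-vs-parents shared-duplication comparison and the parental-zero
rule of the loss-of-function prioritization.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class CohortDesign:
    cases: list[str]                      # includes the trio child
    parents: list[str]                    # healthy parents
    trio: tuple[str, str, str] | None = None  # (child, father, mother)
    shared_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trio is not None:
            child, father, mother = self.trio
            if child not in self.cases:
                raise ValueError("trio child must be listed among cases")
            for p in (father, mother):
                if p not in self.parents:
                    raise ValueError(f"trio parent {p!r} must be a healthy parent")
        overlap = set(self.cases) & set(self.parents)
        if overlap:
            raise ValueError(f"samples with both roles: {sorted(overlap)}")

    @property
    def samples(self) -> list[str]:
        return self.cases + self.parents

    def role(self, sample: str) -> str:
        if sample in self.cases:
            return "case"
        if sample in self.parents:
            return "parent"
        raise KeyError(f"unknown sample role: {sample!r}")

    def to_table(self, path: str | os.PathLike) -> None:
        rows = []
        trio_roles = {}
        if self.trio:
            child, father, mother = self.trio
            trio_roles = {child: "child", father: "father", mother: "mother"}
        for s in self.samples:
            rows.append({
                "sample": s,
                "role": self.role(s),
                "trio_role": trio_roles.get(s, "."),
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path: str | os.PathLike) -> "CohortDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cases = df.loc[df["role"] == "case", "sample"].tolist()
        parents = df.loc[df["role"] == "parent", "sample"].tolist()
        trio = None
        tr = df.set_index("trio_role")["sample"]
        if {"child", "father", "mother"} <= set(df["trio_role"]):
            trio = (tr["child"], tr["father"], tr["mother"])
        return cls(cases=cases, parents=parents, trio=trio)


def default_design() -> CohortDesign:
    """Ten-sample design: 8 cases, one of them a child of 2 healthy parents."""
    cases = ["trio_case1"] + [f"case{i}" for i in range(2, 9)]
    parents = ["trio_father", "trio_mother"]
    return CohortDesign(cases=cases, parents=parents,
                        trio=("trio_case1", "trio_father", "trio_mother"))
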