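"""Group-common / shared / group-unique CRE set algebra.

Given a motif x promoter incidence matrix and two disjoint promoter
groups (e.g. the two co-expression groups around a pair of tandem
duplicates), a motif is *common* to a group when it occurs in every
member promoter, *shared* when common to both groups, and *unique* to a
group when common there but not shared. Unique motifs are candidate
cis-elements for the group's distinctive expression pattern; within a
group they are ranked by total hit count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class PromoterGroup:
    """A labelled set of >= 2 member promoters."""

    label: str
    members: list[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"group {self.label!r} needs >= 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"group {self.label!r} has duplicate members")


@dataclass
class CREComparison:
    """Result of comparing two groups' common-motif sets."""

    label_a: str
    label_b: str
    common_a: set[str]
    common_b: set[str]

    @property
    def shared(self) -> set[str]:
        return self.common_a & self.common_b

    @property
    def unique_a(self) -> set[str]:
        return self.common_a - self.shared

    @property
    def unique_b(self) -> set[str]:
        return self.common_b - self.shared

    def summary(self) -> dict[str, int]:
        return {
            "common_a": len(self.common_a),
            "common_b": len(self.common_b),
            "shared": len(self.shared),
            "unique_a": len(self.unique_a),
            "unique_b": len(self.unique_b),
        }


def group_common(
    inc: pd.DataFrame,
    group: PromoterGroup,
    mode: str = "all_members",
    quorum: float = 1.0,
) -> set[str]:
    """Motifs present (count >= 1) in enough member promoters.

    ``all_members`` requires presence in every member; ``quorum``
    requires presence in at least ceil(quorum * |group|) members.
    """
    missing = [g for g in group.members if g not in inc.columns]
    if missing:
        raise KeyError(
            f"group {group.label!r} members missing from incidence: {missing}"
        )
    present = inc[group.members] >= 1
    if mode == "all_members":
        need = len(group.members)
    elif mode == "quorum":
        if not (0.0 < quorum <= 1.0):
            raise ValueError("quorum must be in (0, 1]")
        need = math.ceil(quorum * len(group.members))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    hits = present.sum(axis=1)
    return set(hits.index[hits >= need])


def compare_groups(
    common_a: set[str],
    common_b: set[str],
    label_a: str = "A",
    label_b: str = "B",
) -> CREComparison:
    """Shared and group-unique motif sets from two common sets.

    shared = A intersect B; unique(A) = A \\ shared, so
    |unique(A)| = |A| - |shared| always holds.
    """
    return CREComparison(
        label_a=label_a,
        label_b=label_b,
        common_a=set(common_a),
        common_b=set(common_b),
    )


def rank_frequency(
    inc: pd.DataFrame,
    motifs: set[str],
    group: PromoterGroup,
) -> list[tuple[str, int]]:
    """Motifs ranked by total hit count over the group's promoters.

    Order is non-increasing count, ties alphabetically by motif name.
    """
    unknown = motifs - set(inc.index)
    if unknown:
        raise KeyError(f"motifs not in incidence matrix: {sorted(unknown)}")
    missing = [g for g in group.members if g not in inc.columns]
    if missing:
        raise KeyError(f"group members missing from incidence: {missing}")
    totals = inc.loc[sorted(motifs), group.members].sum(axis=1)
    ranked = sorted(totals.items(), key=lambda mt: (-mt[1], mt[0]))
    return [(str(m), int(t)) for m, t in ranked]


def comparison_report(
    cmp: CREComparison,
    inc: pd.DataFrame,
    group_a: PromoterGroup,
    group_b: PromoterGroup,
) -> pd.DataFrame:
    """Per-motif table: membership flags plus per-group total counts."""
    rows = []
    for motif in inc.index:
        in_a = motif in cmp.common_a
        in_b = motif in cmp.common_b
        rows.append(
            {
                "motif": motif,
                "in_common_a": in_a,
                "in_common_b": in_b,
                "shared": motif in cmp.shared,
                "unique_a": motif in cmp.unique_a,
                "unique_b": motif in cmp.unique_b,
                "count_a": int(inc.loc[motif, group_a.members].sum()),
                "count_b": int(inc.loc[motif, group_b.members].sum()),
            }
        )
    return pd.DataFrame(rows)


def comparison_json(cmp: CREComparison) -> str:
    payload = {
        "groups": [cmp.label_a, cmp.label_b],
        "counts": cmp.summary(),
        "shared": sorted(cmp.shared),
        "unique_a": sorted(cmp.unique_a),
        "unique_b": sorted(cmp.unique_b),
    }
    return json.dumps(payload, indent=2)


def joint_presence_bound(
    consensus_degeneracy: int,
    consensus_length: int,
    promoter_length: int,
    gc: float,
    group_size: int,
    both_strands: bool = True,
) -> float:
    """Upper bound on P(a background motif is present in every promoter
    of a group) under the i.i.d. background model.

    Per-window match probability is bounded by degeneracy * p_max^L with
    p_max = max(GC/2, (1-GC)/2); a union bound over windows (and
    strands) bounds per-promoter presence, and independence across
    promoters gives the joint bound. Used to check that background
    contamination of unique-CRE sets stays within expectation.
    """
    p_base = max(gc / 2.0, (1.0 - gc) / 2.0)
    per_window = consensus_degeneracy * p_base**consensus_length
    windows = max(promoter_length - consensus_length + 1, 0)
    strands = 2 if both_strands else 1
    per_promoter = min(1.0, strands * windows * per_window)
    return per_promoter**group_size
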