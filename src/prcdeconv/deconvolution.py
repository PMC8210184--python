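"""Multi-bait set algebra: the core interactome deconvolution.

A single pull-down cannot tell which complex variant a prey belongs to.
Combining interactor sets across cell lines and baits can: preys shared by
both cell lines are disease- rather than line-specific; preys bound by the
hub bait but not the variant-defining partner bait are canonical-variant
candidates; chromatin-level (ChIP-MS) sets for the hub, the partner and the
catalytic histone mark separate catalytic-site binding from
catalytic-independent chromatin association.  All of these reduce to Venn
partitions of two or three sets, computed here exactly and reported with
their full region membership.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import BaitMismatchError
from .filtering import InteractorSet
from .synthetic import MEMBERSHIP_CATEGORIES


@dataclass(frozen=True)
class VennReport:
    """Exhaustive region partition of k named sets.

    ``regions`` maps each non-empty subset of labels (as a frozenset) to the
    elements belonging to exactly those sets.  Regions are pairwise disjoint
    and cover the union.
    """

    labels: tuple
    regions: Mapping

    @classmethod
    def from_sets(cls, named_sets: Mapping) -> "VennReport":
        labels = tuple(named_sets)
        if len(set(labels)) != len(labels):
            raise ValueError("set labels must be unique")
        sets = {k: frozenset(v) for k, v in named_sets.items()}
        regions = {}
        for r in range(1, len(labels) + 1):
            for combo in itertools.combinations(labels, r):
                key = frozenset(combo)
                inside = frozenset.intersection(*(sets[label] for label in combo))
                outside = frozenset().union(
                    *(sets[label] for label in labels if label not in key)
                )
                regions[key] = inside - outside
        return cls(labels=labels, regions=regions)

    def region(self, labels) -> frozenset:
        """Elements in exactly the given sets and no others."""
        if isinstance(labels, str):
            labels = (labels,)
        return self.regions[frozenset(labels)]

    def exclusive(self, label: str) -> frozenset:
        return self.region((label,))

    def in_set(self, label: str) -> frozenset:
        """All elements of one input set, reassembled from its regions."""
        return frozenset().union(
            *(v for k, v in self.regions.items() if label in k)
        )

    def union(self) -> frozenset:
        return frozenset().union(*self.regions.values())

    def counts(self) -> dict:
        return {self._key_str(k): len(v) for k, v in self.regions.items()}

    def _key_str(self, key: frozenset) -> str:
        return "&".join(lbl for lbl in self.labels if lbl in key)

    def to_json_dict(self, members: bool = True) -> dict:
        out = {"labels": list(self.labels), "counts": self.counts()}
        if members:
            out["members"] = {
                self._key_str(k): sorted(v) for k, v in self.regions.items()
            }
        return out


@dataclass(frozen=True)
class MembershipAssignment:
    """One complex-membership category per protein in the universe."""

    categories: pd.Series

    def __post_init__(self):
        if self.categories.index.duplicated().any():
            raise ValueError("assignment: duplicated protein IDs")
        bad = set(self.categories.unique()) - set(MEMBERSHIP_CATEGORIES)
        if bad:
            raise ValueError(f"unknown membership categories {sorted(bad)}")

    def members(self, category: str) -> frozenset:
        return frozenset(self.categories.index[self.categories == category])

    def counts(self) -> dict:
        return {c: int((self.categories == c).sum()) for c in MEMBERSHIP_CATEGORIES}

    def to_tsv(self, path) -> None:
        self.categories.rename("category").to_csv(
            path, sep="\t", index_label="protein_id"
        )

    @classmethod
    def from_tsv(cls, path) -> "MembershipAssignment":
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        df.index = df.index.astype(str)
        return cls(categories=df["category"])


def intersect_lines(set_a: InteractorSet, set_b: InteractorSet) -> VennReport:
    """Two-line Venn for one bait: line-exclusive and shared interactors."""
    if set_a.bait != set_b.bait:
        raise BaitMismatchError(
            f"cannot intersect lines across baits {set_a.bait!r} and {set_b.bait!r}"
        )
    if set_a.cell_line == set_b.cell_line:
        raise ValueError("intersect_lines needs two distinct cell lines")
    return VennReport.from_sets(
        {set_a.cell_line: set_a.proteins, set_b.cell_line: set_b.proteins}
    )


def compare_baits(
    shared_bait1, shared_bait2, labels: tuple = ("bait1", "bait2")
) -> VennReport:
    """Two-bait Venn of cross-line shared sets.

    The bait1-exclusive region holds canonical-variant candidates (bound to
    the hub but not the variant-defining partner), the shared region the
    common core.
    """
    return VennReport.from_sets(
        {labels[0]: frozenset(shared_bait1), labels[1]: frozenset(shared_bait2)}
    )


def chromatome_partition(
    hub_chrom,
    partner_chrom,
    mark_chrom,
    labels: tuple = ("BMI1", "RYBP", "H2AK119ub"),
):
    """Three-way chromatome Venn plus derived membership categories.

    ``chromatome_catalytic`` = hub ∩ mark (chromatin association at sites
    carrying the catalytic histone mark); ``chromatome_independent`` = hub
    minus partner minus mark (hub-specific chromatin association with no
    evidence of catalytic activity or the non-canonical variant).  Proteins
    matching neither pattern are left ``bait_independent_unassigned``.
    """
    hub = frozenset(hub_chrom)
    partner = frozenset(partner_chrom)
    mark = frozenset(mark_chrom)
    report = VennReport.from_sets(
        {labels[0]: hub, labels[1]: partner, labels[2]: mark}
    )
    catalytic = hub & mark
    independent = hub - partner - mark
    universe = sorted(hub | partner | mark)
    cats = pd.Series(
        "bait_independent_unassigned", index=pd.Index(universe, name="protein_id")
    )
    cats[cats.index.isin(catalytic)] = "chromatome_catalytic"
    cats[cats.index.isin(independent)] = "chromatome_independent"
    return report, MembershipAssignment(categories=cats)


def integrate_proteome_chromatome(proteome_only, chromatome_only) -> frozenset:
    """Proteins shared between a proteome set and a chromatome set."""
    return frozenset(proteome_only) & frozenset(chromatome_only)


def assign_membership(
    hub_set, partner_set, mark_set=frozenset(), universe=None
) -> MembershipAssignment:
    """Category per protein from the hub/partner/mark set triple.

    Categories follow the Venn regions with fixed precedence:
    ``shared_core`` (hub ∩ partner), ``noncanonical_only`` (partner only),
    ``chromatome_catalytic`` (hub ∩ mark, outside the partner set),
    ``canonical_only`` (hub only), everything else in the universe
    ``bait_independent_unassigned``.
    """
    hub = frozenset(hub_set)
    partner = frozenset(partner_set)
    mark = frozenset(mark_set)
    if universe is None:
        universe = hub | partner | mark
    universe = frozenset(universe)
    if not (hub | partner | mark) <= universe:
        raise ValueError("universe must contain all input sets")
    cats = pd.Series(
        "bait_independent_unassigned",
        index=pd.Index(sorted(universe), name="protein_id"),
    )
    cats[cats.index.isin(hub - partner - mark)] = "canonical_only"
    cats[cats.index.isin((hub & mark) - partner)] = "chromatome_catalytic"
    cats[cats.index.isin(partner - hub)] = "noncanonical_only"
    cats[cats.index.isin(hub & partner)] = "shared_core"
    return MembershipAssignment(categories=cats)


def recovery_metrics(assignment: MembershipAssignment, expected) -> pd.DataFrame:
    """Per-category precision and recall of an assignment vs ground truth.

    ``expected`` is a protein → category mapping over the same universe
    (e.g. the ``expected_category`` column of a synthetic ground truth,
    restricted to the assignment's universe).  Categories with no predicted
    members get NaN precision; with no true members, NaN recall.
    """
    if isinstance(expected, MembershipAssignment):
        expected = expected.categories
    expected = pd.Series(expected)
    pred = assignment.categories
    if set(pred.index) != set(expected.index):
        raise ValueError("assignment and truth must share the same protein universe")
    expected = expected.reindex(pred.index)
    rows = []
    for cat in MEMBERSHIP_CATEGORIES:
        p = pred == cat
        t = expected == cat
        tp = int((p & t).sum())
        n_pred, n_true = int(p.sum()), int(t.sum())
        rows.append(
            {
                "category": cat,
                "n_predicted": n_pred,
                "n_true": n_true,
                "precision": tp / n_pred if n_pred else np.nan,
                "recall": tp / n_true if n_true else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("category")
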