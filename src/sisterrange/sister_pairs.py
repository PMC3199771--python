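"""Sister-species (cherry) extraction and filtering.

A sister pair is an internal node whose two children are both terminal taxa.
Pairs carry the node support, the two pre-ultrametric branch lengths (the
denominator of the standardized tip contrast) and, once attached from a
timetree, the node age in Ma.  Pairs failing the support filter, containing an
excluded taxon, or missing range/trait data are kept in the output but marked
``excluded`` with a reason, so a run documents every cherry it saw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .phylo_io import PhyloTree

__all__ = ["SisterPair", "find_sister_pairs", "pair_ages", "pairs_to_frame"]

log = logging.getLogger(__name__)

#: Default posterior-probability threshold (0-100 scale) for accepting a pair.
DEFAULT_MIN_SUPPORT = 95.0


@dataclass
class SisterPair:
    species_a: str
    species_b: str
    support: float
    bl_a: float
    bl_b: float
    age: float | None = None
    excluded: bool = False
    exclusion_reason: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def species(self) -> tuple[str, str]:
        return (self.species_a, self.species_b)


def find_sister_pairs(
    tree: PhyloTree,
    min_support: float = DEFAULT_MIN_SUPPORT,
    exclusion_list: Iterable[str] = (),
    species_with_data: Iterable[str] | None = None,
) -> list[SisterPair]:
    """Return every cherry of *tree* as a :class:`SisterPair`.

    Parameters
    ----------
    tree:
        Rooted bifurcating tree; supports on the 0-100 scale.  Branch lengths
        of the two tip edges are recorded (use the pre-ultrametric tree so the
        contrast denominator is in substitutions/site).
    min_support:
        Pairs whose node support is below this (or missing) are marked
        excluded with reason ``low_support``.
    exclusion_list:
        Species labels excluded a priori (e.g. taxonomically unresolved
        subclades); a pair containing any of them is marked excluded.
    species_with_data:
        If given, both members must be in this set (range and trait data
        available), otherwise the pair is marked ``missing_data``.

    Species within each pair are ordered lexicographically, so the output is
    invariant to child-order rotations of the input tree.
    """
    excl = set(exclusion_list)
    have = None if species_with_data is None else set(species_with_data)
    pairs = []
    for node, left, right in tree.cherries():
        a, b = sorted(
            [(left.taxon.label, left.edge.length or 0.0),
             (right.taxon.label, right.edge.length or 0.0)]
        )
        support = tree.support(node)
        pair = SisterPair(
            species_a=a[0], species_b=b[0],
            support=0.0 if support is None else support,
            bl_a=a[1], bl_b=b[1],
        )
        if pair.support < min_support:
            pair.excluded, pair.exclusion_reason = True, "low_support"
        elif excl & {pair.species_a, pair.species_b}:
            pair.excluded, pair.exclusion_reason = True, "exclusion_list"
        elif have is not None and not {pair.species_a, pair.species_b} <= have:
            pair.excluded, pair.exclusion_reason = True, "missing_data"
        pairs.append(pair)
    pairs.sort(key=lambda p: p.species)
    n_inc = sum(not p.excluded for p in pairs)
    log.info("found %d cherries, %d included after filters", len(pairs), n_inc)
    return pairs


def pair_ages(pairs: Sequence[SisterPair], ultrametric_tree: PhyloTree) -> list[SisterPair]:
    """Attach node ages (Ma) from an ultrametric timetree to *pairs* in place.

    The age of a pair is the depth of the most recent common ancestor of its
    two species below the tips of the timetree.
    """
    if not ultrametric_tree.is_ultrametric:
        raise ValueError("pair ages require an ultrametric tree")
    present = set(ultrametric_tree.tip_labels)
    for pair in pairs:
        missing = {pair.species_a, pair.species_b} - present
        if missing:
            raise KeyError(f"species missing from ultrametric tree: {sorted(missing)}")
        node = ultrametric_tree.mrca([pair.species_a, pair.species_b])
        pair.age = ultrametric_tree.node_age(node)
    return list(pairs)


def pairs_to_frame(pairs: Sequence[SisterPair]) -> pd.DataFrame:
    """Tabulate pairs for CSV export."""
    return pd.DataFrame(
        {
            "species_a": [p.species_a for p in pairs],
            "species_b": [p.species_b for p in pairs],
            "support": [p.support for p in pairs],
            "age_ma": [p.age for p in pairs],
            "bl_a": [p.bl_a for p in pairs],
            "bl_b": [p.bl_b for p in pairs],
            "included": [not p.excluded for p in pairs],
            "exclusion_reason": [p.exclusion_reason for p in pairs],
        }
    )
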