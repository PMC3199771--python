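"""Tree and table input/output.

Trees are parsed with dendropy and wrapped in :class:`PhyloTree`, which fixes a
single indexing convention for the rest of the package: rooted, strictly
bifurcating, node supports on a 0-100 scale (posterior probabilities given on
0-1 are rescaled on read), and node ages measured from the tips of an
ultrametric tree.  Tabular inputs (traits, localities, climate) are plain CSV
read into pandas frames with light validation.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd

__all__ = [
    "PhyloTree",
    "read_tree",
    "read_trait_table",
    "read_locality_table",
    "read_climate_table",
]

#: Relative tolerance for calling a tree ultrametric (root-to-tip spread
#: divided by tree height).
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for structural problems in an input tree."""


class PhyloTree:
    """Rooted bifurcating tree with branch lengths, supports and node ages.

    Thin wrapper around a :class:`dendropy.Tree`.  Supports are normalised to
    the 0-100 posterior-probability scale; a missing support reads as ``None``
    and is treated as 0 by any support filter.  Ultrametricity is detected on
    construction and cached along with the tree height.
    """

    def __init__(self, tree: dendropy.Tree, *, resolve_polytomies: bool = False):
        self._tree = tree
        if resolve_polytomies:
            # Deterministic: dendropy resolves in child order with 0-length
            # branches, matching the documented policy.
            tree.resolve_polytomies(limit=2, update_bipartitions=False)
        self._validate()
        self._depths = self._compute_depths()
        tip_depths = [self._depths[lf] for lf in self.tips()]
        self.height = max(tip_depths) if tip_depths else 0.0
        spread = (max(tip_depths) - min(tip_depths)) if tip_depths else 0.0
        self.is_ultrametric = (
            self.height == 0.0 or spread <= ULTRAMETRIC_RTOL * self.height
        )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_string(
        cls,
        text: str,
        schema: str = "newick",
        support_scale: float = 100.0,
        resolve_polytomies: bool = False,
    ) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema=schema,
                rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except TreeError:
            raise
        except Exception as exc:  # dendropy raises schema-specific errors
            raise TreeError(f"tree parse failure: {exc}") from exc
        _attach_supports(tree, support_scale)
        return cls(tree, resolve_polytomies=resolve_polytomies)

    @classmethod
    def read(
        cls,
        path: str | Path,
        schema: str = "newick",
        support_scale: float = 100.0,
        resolve_polytomies: bool = False,
    ) -> "PhyloTree":
        return cls.from_string(
            Path(path).read_text(),
            schema=schema,
            support_scale=support_scale,
            resolve_polytomies=resolve_polytomies,
        )

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        labels = []
        for node in self._tree:
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                raise TreeError(
                    f"non-bifurcating node with {len(kids)} children; "
                    "pass resolve_polytomies=True to resolve deterministically"
                )
            if node.edge.length is not None and node.edge.length < 0:
                raise TreeError("negative branch length")
            if not kids:
                if node.taxon is None or not node.taxon.label:
                    raise TreeError("tip without a label")
                labels.append(node.taxon.label)
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")

    def _compute_depths(self) -> dict:
        depths = {}
        for node in self._tree.preorder_node_iter():
            bl = node.edge.length or 0.0
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + bl
        return depths

    # -- accessors ---------------------------------------------------------

    @property
    def root(self):
        return self._tree.seed_node

    def nodes(self):
        return list(self._tree.preorder_node_iter())

    def postorder(self):
        return self._tree.postorder_node_iter()

    def tips(self):
        return list(self._tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def depth(self, node) -> float:
        return self._depths[node]

    def node_age(self, node) -> float:
        """Age of *node* in the units of the branch lengths (Ma for a timetree).

        Defined as the distance from the node down to its descendant tips, so
        tips have age 0.  Requires an ultrametric tree.
        """
        if not self.is_ultrametric:
            raise TreeError("node ages are only defined on an ultrametric tree")
        age = self.height - self._depths[node]
        return 0.0 if abs(age) <= ULTRAMETRIC_RTOL * max(self.height, 1.0) else age

    def support(self, node) -> float | None:
        return getattr(node, "support", None)

    def cherries(self):
        """Internal nodes whose two children are both tips.

        Returns a list of ``(node, tip_left, tip_right)`` in postorder.
        """
        out = []
        for node in self._tree.postorder_internal_node_iter():
            kids = node.child_nodes()
            if len(kids) == 2 and all(k.is_leaf() for k in kids):
                out.append((node, kids[0], kids[1]))
        return out

    def mrca(self, labels: Iterable[str]):
        return self._tree.mrca(taxon_labels=list(labels))

    def find_tip(self, label: str):
        node = self._tree.find_node_with_taxon_label(label)
        if node is None:
            raise KeyError(f"tip {label!r} not in tree")
        return node

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        # Write supports back out as internal node labels so a round trip
        # preserves them.
        for node in self._tree.preorder_internal_node_iter():
            sup = getattr(node, "support", None)
            node.label = None if sup is None else format(sup, "g")
        txt = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        )
        return txt.strip() + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())


def _attach_supports(tree: dendropy.Tree, support_scale: float) -> None:
    if support_scale not in (1.0, 1, 100.0, 100):
        raise ValueError("support_scale must be 1 (posterior 0-1) or 100")
    factor = 100.0 if support_scale in (1.0, 1) else 1.0
    for node in tree.preorder_internal_node_iter():
        sup = None
        if node.label not in (None, ""):
            try:
                sup = float(node.label) * factor
            except ValueError:
                sup = None
        node.support = sup


def read_tree(
    path: str | Path,
    schema: str = "newick",
    support_scale: float = 100.0,
    resolve_polytomies: bool = False,
) -> PhyloTree:
    """Read a Newick or NEXUS tree into a :class:`PhyloTree`."""
    return PhyloTree.read(
        path,
        schema=schema,
        support_scale=support_scale,
        resolve_polytomies=resolve_polytomies,
    )


# -- tables ----------------------------------------------------------------


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a species trait table (columns ``species,svl_mm``, one row each).

    SVL is maximal male snout-vent length in mm and must be finite and
    positive.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["species", "svl_mm"], "trait table")
    if df["species"].duplicated().any():
        raise ValueError("trait table has duplicate species rows")
    svl = df["svl_mm"].to_numpy(float)
    if not all(math.isfinite(v) and v > 0 for v in svl):
        raise ValueError("svl_mm must be finite and > 0")
    return df


def read_locality_table(path: str | Path) -> pd.DataFrame:
    """Read point localities (columns ``species,x,y``), planar meters or lon/lat.

    An optional ``crs`` column (``planar_m`` or ``lonlat``) declares the
    coordinate mode; downstream geometry requires planar meters (see
    :func:`sisterrange.range_geometry.lonlat_to_planar`).
    """
    df = pd.read_csv(path)
    _require_columns(df, ["species", "x", "y"], "locality table")
    xy = df[["x", "y"]].to_numpy(float)
    if not pd.notna(xy).all() or not pd.DataFrame(xy).apply(
        lambda c: c.map(math.isfinite)
    ).to_numpy().all():
        raise ValueError("locality coordinates must be finite")
    return df


def read_climate_table(path: str | Path) -> pd.DataFrame:
    """Read per-locality climate values: ``species`` plus numeric columns."""
    df = pd.read_csv(path)
    if "species" not in df.columns or df.shape[1] < 3:
        raise ValueError("climate table needs 'species' plus >=2 numeric columns")
    value_cols = [c for c in df.columns if c != "species"]
    if df[value_cols].isna().any().any():
        raise ValueError("climate table contains missing values")
    return df


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} missing columns {missing}")
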