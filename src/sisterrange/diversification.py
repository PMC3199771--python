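"""Species-richness contrasts: trait-dependent diversification from tree shape.

At every internal node the two daughter clades are compared: the richness
contrast is

    RRD = ln(N_i / N_j)

with N the daughter tip counts and i the daughter whose reconstructed
(Felsenstein weighted-average) trait value is larger — so RRD is positive
exactly when the larger-trait clade is the more species-rich.  The matching
trait contrast is standardized by the lengthened branch-length variances from
the pruning pass, oriented the same way (large minus small, hence always
positive).  Regressing RRD on the trait contrast through the origin tests
whether the trait predicts clade richness; a negative slope means
small-trait clades diversify more.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .comparative_stats import RegressionResult, regression_through_origin
from .phylo_io import PhyloTree

__all__ = [
    "ancestral_states_bm",
    "RichnessContrast",
    "richness_contrasts",
    "diversification_test",
]

log = logging.getLogger(__name__)

#: Branch lengths below this are floored to keep pruning variances positive.
MIN_BRANCH_LENGTH = 1e-12


def ancestral_states_bm(tree: PhyloTree, trait: dict[str, float]):
    """Felsenstein pruning pass: ancestral estimates and lengthened variances.

    Tips carry their observed trait and the length of their subtending edge.
    Each internal node gets the inverse-variance weighted average of its two
    daughters,

        x = (x_l / v_l + x_r / v_r) / (1/v_l + 1/v_r),

    and its edge is lengthened by the pooled daughter variance,

        v' = v + v_l * v_r / (v_l + v_r),

    computed tips-to-root.  Returns ``(values, variances)`` keyed by node,
    where ``variances[node]`` is the lengthened v' used in contrast
    denominators.
    """
    values: dict = {}
    variances: dict = {}
    for node in tree.postorder():
        edge = max(node.edge.length or 0.0, 0.0)
        if node.is_leaf():
            label = node.taxon.label
            if label not in trait:
                raise KeyError(f"missing trait value for tip {label!r}")
            values[node] = float(trait[label])
            variances[node] = edge
        else:
            left, right = node.child_nodes()
            vl = max(variances[left], MIN_BRANCH_LENGTH)
            vr = max(variances[right], MIN_BRANCH_LENGTH)
            wl, wr = 1.0 / vl, 1.0 / vr
            values[node] = (wl * values[left] + wr * values[right]) / (wl + wr)
            variances[node] = edge + vl * vr / (vl + vr)
    return values, variances


@dataclass
class RichnessContrast:
    node_id: int
    n_large: int
    n_small: int
    rrd: float
    trait_contrast: float
    node_depth: float


def richness_contrasts(
    tree: PhyloTree, trait: dict[str, float], log10_trait: bool = True
) -> list[RichnessContrast]:
    """One richness contrast per internal node, oriented by reconstructed trait.

    Body sizes are ratio-scale, so the trait enters on log10 by default
    (``log10_trait=False`` for raw values).  Nodes whose daughters tie in
    reconstructed trait value are dropped (logged) rather than oriented
    arbitrarily.  The tree need not be ultrametric: only topology, branch
    lengths and tip counts enter.
    """
    if log10_trait:
        trait = {k: math.log10(v) for k, v in trait.items()}
    values, variances = ancestral_states_bm(tree, trait)

    tip_counts: dict = {}
    for node in tree.postorder():
        if node.is_leaf():
            tip_counts[node] = 1
        else:
            tip_counts[node] = sum(tip_counts[c] for c in node.child_nodes())

    out = []
    node_id = 0
    for node in tree.postorder():
        if node.is_leaf():
            continue
        left, right = node.child_nodes()
        x_l, x_r = values[left], values[right]
        if x_l == x_r:
            log.info("node %d dropped: reconstructed trait tie", node_id)
            node_id += 1
            continue
        big, small = (left, right) if x_l > x_r else (right, left)
        v_big = max(variances[big], MIN_BRANCH_LENGTH)
        v_small = max(variances[small], MIN_BRANCH_LENGTH)
        out.append(
            RichnessContrast(
                node_id=node_id,
                n_large=tip_counts[big],
                n_small=tip_counts[small],
                rrd=math.log(tip_counts[big] / tip_counts[small]),
                trait_contrast=(values[big] - values[small])
                / math.sqrt(v_big + v_small),
                node_depth=tree.depth(node),
            )
        )
        node_id += 1
    return out


def contrasts_to_frame(contrasts: list[RichnessContrast]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node_id": [c.node_id for c in contrasts],
            "n_large": [c.n_large for c in contrasts],
            "n_small": [c.n_small for c in contrasts],
            "rrd": [c.rrd for c in contrasts],
            "trait_contrast": [c.trait_contrast for c in contrasts],
            "node_depth": [c.node_depth for c in contrasts],
        }
    )


def diversification_test(
    contrasts: list[RichnessContrast],
) -> tuple[RegressionResult, float, float]:
    """Through-origin regression of RRD on the trait contrast.

    Returns ``(regression, r, p_r)`` where r is the plain Pearson correlation
    between RRD and trait contrast with its two-sided p — both views the
    richness-contrast literature reports.
    """
    if len(contrasts) < 3:
        raise ValueError("need at least 3 richness contrasts")
    rrd = np.array([c.rrd for c in contrasts])
    tc = np.array([c.trait_contrast for c in contrasts])
    reg = regression_through_origin(rrd, pd.DataFrame({"trait_contrast": tc}))
    if np.ptp(rrd) == 0 or np.ptp(tc) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(tc, rrd)
    return reg, float(r), float(p)
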