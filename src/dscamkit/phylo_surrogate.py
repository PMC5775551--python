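"""Distance-based clustering trees over cassette/gene identity matrices.

Percent-identity matrices are converted to distances d = (100 − id)/100
and clustered with neighbor-joining, which is exact on additive distance
matrices (it reproduces every path distance).  This is a deliberately
lightweight distance-based surrogate for full maximum-likelihood tree
inference with bootstrap support: it answers the questions asked of the
trees here — are burst cassettes monophyletic, and are cassette trees
shallower than gene trees — without an external phylogenetics stack.
Rooting on a designated outgroup label is optional.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

logger = logging.getLogger("dscamkit")


def to_distance(matrix: pd.DataFrame) -> DistanceMatrix:
    """Identity matrix (%) -> distance matrix with d = (100 − identity)/100."""
    values = matrix.to_numpy(float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("identity matrix must be square")
    if not np.allclose(values, values.T):
        raise ValueError("identity matrix must be symmetric")
    d = (100.0 - values) / 100.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(l) for l in matrix.index])


def nj_tree(dm: DistanceMatrix, outgroup: Optional[str] = None) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero.

    With an outgroup the tree is rooted on the edge leading to that tip;
    otherwise the arbitrary basal trichotomy NJ produces is kept.
    """
    if len(dm.ids) < 3:
        raise ValueError("nj_tree needs >= 3 labels")
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            logger.warning("negative branch length %.4g clamped to 0", node.length)
            node.length = 0.0
    if outgroup is not None:
        tip = tree.find(outgroup)
        tree = tree.root_at(tip.parent, reset=True)
    return tree


def is_monophyletic(tree: TreeNode, labels: Sequence[str]) -> bool:
    """True when ``labels`` form a clade (exactly the tips under their LCA)."""
    wanted = set(labels)
    lca = tree.lca([tree.find(l) for l in labels])
    tips = {t.name for t in lca.tips()} if not lca.is_tip() else {lca.name}
    return tips == wanted


def mean_root_to_tip(tree: TreeNode) -> float:
    """Mean path length from the root to every tip."""
    depths = [tip.accumulate_to_ancestor(tree.root()) for tip in tree.tips()]
    return float(np.mean(depths))


def compare_clusterings(cassette_tree: TreeNode, gene_tree: TreeNode) -> dict:
    """Mean root-to-tip depth of each tree and their ratio.

    Recent cassette duplication bursts make the cassette tree shallower
    than the gene tree, so a ratio < 1 indicates cassette turnover on a
    faster timescale than gene duplication.
    """
    dc = mean_root_to_tip(cassette_tree)
    dg = mean_root_to_tip(gene_tree)
    return {
        "cassette_mean_depth": dc,
        "gene_mean_depth": dg,
        "depth_ratio": dc / dg if dg else float("nan"),
    }
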