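"""Deterministic toy fixtures: random additive trees, distance matrices, site panels.

Used by the test suite and as quick-start inputs; everything is generated from
a seed, so fixtures are reproducible byte-for-byte and nothing needs shipping.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .phylosim import SitePanel, sample_site_panel

__all__ = [
    "random_additive_tree",
    "tree_distance_matrix",
    "toy_panel",
    "write_fixture",
]


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator, min_len: float = 0.1, max_len: float = 2.0
) -> TreeNode:
    """A random binary tree with positive branch lengths (hence additive distances)."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        a, b = nodes[j], nodes[i]  # pop higher index first
        a.length = float(rng.uniform(min_len, max_len))
        b.length = float(rng.uniform(min_len, max_len))
        parent.extend([b, a])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    nodes[0].length = float(rng.uniform(min_len, max_len))
    nodes[1].length = float(rng.uniform(min_len, max_len))
    root.extend(nodes)
    return root


def tree_distance_matrix(tree: TreeNode) -> pd.DataFrame:
    """Exact tip-to-tip path-length (additive) distances of a tree."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def toy_panel(n_sites: int = 50, seed: int = 0, **kwargs) -> SitePanel:
    """A small editing-site panel (half neutral, half deleterious)."""
    half = n_sites // 2
    return sample_site_panel(n_sites - half, half, seed=seed, **kwargs)


def write_fixture(kind: str, path: str | Path, seed: int = 0, **params) -> Path:
    """Write a toy fixture to disk: ``toy-tree`` (newick), ``toy-distance`` (TSV),
    ``toy-panel`` (TSV)."""
    path = Path(path)
    rng = np.random.default_rng(seed)
    if kind == "toy-tree":
        tree = random_additive_tree(params.get("n_taxa", 6), rng)
        buf = io.StringIO()
        tree.write(buf)
        path.write_text(buf.getvalue())
    elif kind == "toy-distance":
        tree = random_additive_tree(params.get("n_taxa", 6), rng)
        tree_distance_matrix(tree).to_csv(path, sep="\t")
    elif kind == "toy-panel":
        toy_panel(params.get("n_sites", 50), seed=rng).to_frame().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return path
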