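"""Independent oracles used to cross-check the package implementations.

Deliberately coded against different libraries / from first principles:
UniFrac is computed from a dendropy re-parse of the Newick text with
explicit enumeration of every branch's descendant leaf set, and the BH
adjustment is the textbook backward pass over sorted p values.
"""

from __future__ import annotations

import dendropy
import numpy as np


def _branches(newick: str):
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        rooting="force-rooted",
    )
    out = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        leaves = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        out.append((length, leaves))
    return out


def unweighted_unifrac_brute(newick: str, a: dict, b: dict) -> float:
    present_a = {t for t, c in a.items() if c > 0}
    present_b = {t for t, c in b.items() if c > 0}
    unique = union = 0.0
    for length, leaves in _branches(newick):
        in_a = bool(leaves & present_a)
        in_b = bool(leaves & present_b)
        if in_a or in_b:
            union += length
        if in_a != in_b:
            unique += length
    return unique / union


def weighted_unifrac_brute(newick: str, a: dict, b: dict, normalized: bool = True) -> float:
    total_a = sum(a.values())
    total_b = sum(b.values())
    num = den = 0.0
    for length, leaves in _branches(newick):
        pa = sum(a.get(t, 0) for t in leaves) / total_a
        pb = sum(b.get(t, 0) for t in leaves) / total_b
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    return num / den if normalized else num


def bh_adjust_brute(p: list[float]) -> list[float]:
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def random_community(rng: np.random.Generator, taxa: list[str], sparsity: float = 0.5) -> dict:
    """A random community supported on a nonempty subset of ``taxa``."""
    present = rng.random(len(taxa)) > sparsity
    if not present.any():
        present[rng.integers(len(taxa))] = True
    counts = rng.integers(1, 200, size=len(taxa))
    return {t: int(c) for t, c, keep in zip(taxa, counts, present) if keep}
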