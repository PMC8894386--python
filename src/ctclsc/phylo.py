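"""Shared/private mutation partitioning and maximum-parsimony lesion trees.

Lesions of a patient are compared as sets of somatic variants keyed by
(chromosome, position, ref, alt), nonsynonymous-only by default.  Small
phylogenies are built by exhaustive search over rooted topologies with a
germline (all-reference) root, scoring each topology with Fitch small
parsimony on binary presence/absence characters; branch lengths count the
mutation gains/losses assigned to each branch, so for two lesions the stem
carries the shared mutations and each leaf branch its private ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GERMLINE = "germline"
MAX_LESIONS = 8

VariantKey = tuple  # (chrom, pos, ref, alt)


def variant_sets(
    variants: pd.DataFrame, effects: set[str] = frozenset({"nonsynonymous"})
) -> dict[str, set[VariantKey]]:
    """Per-lesion variant-key sets from a variant table, filtered by effect."""
    sub = variants[variants["effect"].isin(effects)]
    out: dict[str, set[VariantKey]] = {}
    for sample, grp in sub.groupby("sample"):
        out[str(sample)] = {
            (r.chrom, int(r.pos), r.ref, r.alt) for r in grp.itertuples(index=False)
        }
    return out


@dataclass
class SharedPrivatePartition:
    shared: set            # variants present in every lesion
    private: dict          # lesion -> variants unique to that lesion
    partial: set           # variants in >1 but not all lesions
    shared_fraction_per_lesion: dict
    shared_fraction_of_union: float
    private_fraction_per_lesion: dict


def shared_private(variants_by_lesion: Mapping[str, Iterable[VariantKey]]) -> SharedPrivatePartition:
    """Exact set partition of lesion variants into shared/private/partial."""
    sets = {k: set(v) for k, v in variants_by_lesion.items()}
    if len(sets) < 2:
        raise ValueError("need at least 2 lesions")
    for lesion, s in sets.items():
        if not s:
            raise ValueError(f"lesion {lesion} has no variants; fractions undefined")
    union = set().union(*sets.values())
    shared = set.intersection(*sets.values())
    private = {}
    for lesion, s in sets.items():
        others = set().union(*(v for k, v in sets.items() if k != lesion))
        private[lesion] = s - others
    partial = union - shared - set().union(*private.values())
    return SharedPrivatePartition(
        shared=shared,
        private=private,
        partial=partial,
        shared_fraction_per_lesion={k: len(shared) / len(s) for k, s in sets.items()},
        shared_fraction_of_union=len(shared) / len(union),
        private_fraction_per_lesion={k: len(private[k]) / len(s) for k, s in sets.items()},
    )


@dataclass
class LesionTree:
    """Rooted parsimony tree with mutation-count branch lengths."""

    leaves: list[str]               # lesion ids (germline is the root taxon)
    topology: object                # nested tuples of lesion ids
    branch_lengths: dict            # frozen subtree signature -> change count
    newick: str
    parsimony_score: int
    all_optimal: list[str] = field(default_factory=list)  # newicks of ties


def _rooted_topologies(leaves: list[str]):
    """All rooted binary leaf-labeled topologies, in deterministic order."""

    def insert(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for sub in insert(left, leaf):
                yield (sub, right)
            for sub in insert(right, leaf):
                yield (left, sub)

    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t for base in trees for t in insert(base, leaf)]
    return trees


def _fitch_cost(tree, leaf_masks: dict[str, np.ndarray], weights: np.ndarray):
    """Total weighted Fitch parsimony cost of a topology (vectorized over
    variant presence patterns; state sets are 2-bit masks)."""

    def rec(node):
        if not isinstance(node, tuple):
            return leaf_masks[node], 0.0
        lm, lc = rec(node[0])
        rm, rc = rec(node[1])
        inter = lm & rm
        need_union = inter == 0
        mask = np.where(need_union, lm | rm, inter)
        return mask, lc + rc + float((need_union * weights).sum())

    _, cost = rec(tree)
    return cost


def _assign_branches(tree, leaf_states: dict[str, np.ndarray]):
    """Fitch traceback with a germline-rooted state preference; returns
    change counts per branch keyed by the child subtree."""

    masks: dict[int, np.ndarray] = {}
    nodes: list = []

    def down(node):
        nodes.append(node)
        if not isinstance(node, tuple):
            masks[id(node)] = np.where(leaf_states[node] > 0, 2, 1)
            return masks[id(node)]
        lm, rm = down(node[0]), down(node[1])
        inter = lm & rm
        masks[id(node)] = np.where(inter == 0, lm | rm, inter)
        return masks[id(node)]

    down(tree)
    # the full-tree root carries the germline state (all-absent); any
    # conflict with the lesion subtree is a change on the stem branch
    n_vars = next(iter(leaf_states.values())).shape[0]
    root_state = np.zeros(n_vars, dtype=int)
    lengths: dict = {}

    def up(node, parent_state):
        mask = masks[id(node)]
        has_parent = (mask >> parent_state) & 1  # parent state in own set?
        state = np.where(has_parent, parent_state, np.where(mask & 1, 0, 1))
        lengths[_signature(node)] = int((state != parent_state).sum())
        if isinstance(node, tuple):
            up(node[0], state)
            up(node[1], state)

    up(tree, root_state)
    return lengths


def _signature(node) -> frozenset:
    if not isinstance(node, tuple):
        return frozenset([node])
    return _signature(node[0]) | _signature(node[1])


def _newick(node, lengths) -> str:
    if not isinstance(node, tuple):
        return f"{node}:{lengths[_signature(node)]}"
    return (
        f"({_newick(node[0], lengths)},{_newick(node[1], lengths)})"
        f":{lengths[_signature(node)]}"
    )


def build_parsimony_tree(presence: pd.DataFrame) -> LesionTree:
    """Maximum-parsimony tree of lesions rooted at an all-zero germline.

    ``presence`` is lesions x variants with 0/1 entries.  All rooted
    topologies are scored by Fitch small parsimony; the first optimum in
    deterministic enumeration order is returned with per-branch change
    counts, and the newicks of every optimal topology are reported.
    Limited to 8 lesions (exhaustive search).
    """
    lesions = sorted(presence.index)
    if len(lesions) < 2:
        raise ValueError("need at least 2 lesions")
    if len(lesions) > MAX_LESIONS:
        raise ValueError(
            f"{len(lesions)} lesions exceed the exhaustive-search limit of "
            f"{MAX_LESIONS}; a heuristic search is out of scope"
        )
    mat = presence.loc[lesions].to_numpy()
    if not np.isin(mat, [0, 1]).all():
        raise ValueError("presence matrix must be binary")

    # collapse identical presence patterns, weight by multiplicity
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    leaf_masks = {
        lesion: np.where(patterns[i] > 0, 2, 1) for i, lesion in enumerate(lesions)
    }
    germ_mask = np.ones(patterns.shape[1], dtype=int)  # state {0}

    best_cost, best_trees = np.inf, []
    for topo in _rooted_topologies(lesions):
        sub_mask_cost = _fitch_cost(topo, leaf_masks, weights.astype(float))
        # add germline as sibling of the whole lesion subtree
        def rec_mask(node):
            if not isinstance(node, tuple):
                return leaf_masks[node]
            lm, rm = rec_mask(node[0]), rec_mask(node[1])
            inter = lm & rm
            return np.where(inter == 0, lm | rm, inter)

        top_mask = rec_mask(topo)
        inter = top_mask & germ_mask
        root_cost = float(((inter == 0) * weights).sum())
        cost = sub_mask_cost + root_cost
        if cost < best_cost - 1e-9:
            best_cost, best_trees = cost, [topo]
        elif abs(cost - best_cost) <= 1e-9:
            best_trees.append(topo)

    leaf_states = {
        lesion: np.repeat(patterns[i], weights) for i, lesion in enumerate(lesions)
    }

    def finish(topo):
        lengths = _assign_branches(topo, leaf_states)
        lengths[frozenset([GERMLINE])] = 0  # root carries the germline state
        return f"({GERMLINE}:0,{_newick(topo, lengths)});", lengths

    newicks = [finish(t)[0] for t in best_trees]
    newick, lengths = finish(best_trees[0])
    return LesionTree(
        leaves=lesions,
        topology=best_trees[0],
        branch_lengths=lengths,
        newick=newick,
        parsimony_score=int(round(best_cost)),
        all_optimal=newicks,
    )


def presence_matrix(variants_by_lesion: Mapping[str, Iterable[VariantKey]]) -> pd.DataFrame:
    """Binary lesions x variants matrix from per-lesion variant sets."""
    sets = {k: set(v) for k, v in variants_by_lesion.items()}
    union = sorted(set().union(*sets.values()))
    data = {
        lesion: [1 if v in s else 0 for v in union] for lesion, s in sets.items()
    }
    return pd.DataFrame.from_dict(data, orient="index",
                                  columns=[str(v) for v in union])
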