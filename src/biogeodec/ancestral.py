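"""Marginal ancestral range probabilities at every node of the chronogram.

A standard two-pass (down–up) algorithm: the pruning downpass gives, for
each node, the likelihood of the data in its subtree conditional on each
range state; the uppass carries the complementary "outside" likelihood
rootward-to-tipward through the cladogenesis table and the branch
transition matrices.  The product, renormalized per node, is the marginal
posterior of the range at that node under the fitted model and the flat
root prior.

Two "single most probable area" conventions are emitted for every node:
the maximum-a-posteriori (MAP) range state, and the single area with the
largest summed probability over all ranges containing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .range_evolution import DecLikelihood

__all__ = ["AncestralEstimates", "ancestral_marginals"]


@dataclass
class AncestralEstimates:
    """Per-node marginal range probabilities and MAP summaries.

    ``probs[v]`` is the posterior over the state space (null state always 0)
    for node ``v``; ``map_state[v]`` the MAP range state index (ties broken
    by the deterministic state ordering: smallest range first, then
    lexicographic); ``map_area[v]`` the argmax area of the per-area summed
    mass.
    """

    engine: DecLikelihood
    probs: np.ndarray  # (n_nodes, n_states)
    map_state: np.ndarray
    map_area: np.ndarray

    @property
    def tree(self):
        return self.engine.tree

    def area_mass(self) -> np.ndarray:
        """(n_nodes, n_areas) summed probability of ranges containing each area."""
        space = self.engine.space
        n_areas = space.n_areas
        contains = np.zeros((space.n_states, n_areas))
        for i in range(1, space.n_states):
            for a in space.areas_of(int(space.states[i])):
                contains[i, a] = 1.0
        return self.probs @ contains

    def to_dataframe(self, top_k: int = 3) -> pd.DataFrame:
        space, codes = self.engine.space, self.engine.geog.areas
        rows = []
        for v in range(self.tree.n_nodes):
            order = np.argsort(-self.probs[v], kind="stable")[:top_k]
            rows.append(
                {
                    "node": v,
                    "age_Ma": float(self.tree.ages[v]),
                    "is_tip": self.tree.is_tip(v),
                    "label": self.tree.labels[v] if self.tree.is_tip(v) else "",
                    "map_range": space.label(int(self.map_state[v]), codes),
                    "map_area": codes[int(self.map_area[v])],
                    **{
                        f"state_{k + 1}": f"{space.label(int(i), codes)}:{self.probs[v, i]:.4f}"
                        for k, i in enumerate(order)
                    },
                }
            )
        return pd.DataFrame(rows)


def ancestral_marginals(engine: DecLikelihood, d: float, e: float) -> AncestralEstimates:
    """Marginal posterior of the range at every node under given (d, e).

    Raises if the data are impossible under the parameters (all-zero
    partials at the root).
    """
    tree, space, cl = engine.tree, engine.space, engine.clado
    props = engine.propagators(d, e)
    node_partials, branch_top, _ = engine.downpass(d, e)
    n_states = space.n_states

    root_post = node_partials[tree.root] * engine.root_prior()
    if root_post.sum() <= 0:
        raise ValueError("data are impossible under the supplied parameters")

    outside = {tree.root: engine.root_prior()}
    probs = np.zeros((tree.n_nodes, n_states))
    for v in reversed(tree.postorder):  # preorder
        if tree.is_tip(v):
            continue
        l, r = tree.children[v]
        o = outside[v]
        # outside likelihood of each daughter's start state at the node,
        # summing over the parent state and the sibling's subtree
        contrib = o[cl.anc] * cl.weight
        top_l = np.zeros(n_states)
        np.add.at(top_l, cl.left, contrib * branch_top[r][cl.right])
        top_r = np.zeros(n_states)
        np.add.at(top_r, cl.right, contrib * branch_top[l][cl.left])
        for child, top in ((l, top_l), (r, top_r)):
            vec = top
            for dt, s in reversed(engine.segments[child]):  # old end -> young end
                vec = props[s].apply_transpose(vec, dt)
            tot = vec.sum()
            outside[child] = vec / tot if tot > 0 else vec

    for v in range(tree.n_nodes):
        post = node_partials[v] * outside[v] if v != tree.root else root_post
        tot = post.sum()
        if tot <= 0:
            raise ValueError(f"all-zero marginal at node {v}: data impossible there")
        probs[v] = post / tot

    map_state = np.argmax(probs, axis=1)
    # per-area summed mass, argmax with ties going to the first (alphabetical) area
    contains = np.zeros((n_states, space.n_areas))
    for i in range(1, n_states):
        for a in space.areas_of(int(space.states[i])):
            contains[i, a] = 1.0
    map_area = np.argmax(probs @ contains, axis=1)
    return AncestralEstimates(engine, probs, map_state, map_area)
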