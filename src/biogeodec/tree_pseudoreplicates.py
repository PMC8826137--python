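"""Pseudoreplicated chronograms: dating-uncertainty jitter and missing-taxon grafts.

The stochastic-mapping replicates are run over a *set* of trees rather
than a single chronogram, to propagate divergence-time uncertainty and
the effect of unsampled taxa into the event counts.  Node ages are
perturbed multiplicatively (lognormal factors with a chosen coefficient
of variation), with parent-older-than-child order restored by clamping;
missing taxa are grafted at a uniform-random age on a uniform-random
branch within a stated attachment clade, each with a user-supplied range
(ranges of unsampled species cannot be invented).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .geoio import Chronogram, GeographyTable, GeoIOError

__all__ = ["GraftSpec", "TreeSet", "jitter_node_ages", "graft_missing_tips", "make_tree_set"]


@dataclass
class GraftSpec:
    """One missing taxon to add: its label, range, and attachment clade.

    ``clade`` is a list of existing tip labels; the taxon is attached on a
    branch within (or on the stem of) their most recent common ancestor.
    ``range_bits`` is the 0/1 presence string over the geography's areas.
    """

    label: str
    range_bits: str
    clade: list


@dataclass
class TreeSet:
    """A list of pseudoreplicated chronograms plus their provenance."""

    trees: list
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def jitter_node_ages(tree: Chronogram, cv: float, rng) -> Chronogram:
    """Perturb internal node ages by lognormal multiplicative factors.

    Each internal age is multiplied by ``exp(cv * z)``, ``z ~ N(0, 1)``;
    children are clamped strictly below their parent so the tree stays a
    valid chronogram. ``cv = 0`` returns an identical tree.
    """
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    rng = np.random.default_rng(rng)
    ages = tree.ages.copy()
    if cv > 0:
        for v in reversed(tree.postorder):  # preorder: root first
            if tree.is_tip(v):
                continue
            proposal = tree.ages[v] * np.exp(cv * rng.standard_normal())
            p = tree.parent[v]
            if p >= 0:
                proposal = min(proposal, ages[p] * (1.0 - 1e-9))
            ages[v] = max(proposal, 1e-12)
    return Chronogram(tree.parent.copy(), ages, tree.labels, tree.children)


def graft_missing_tips(tree: Chronogram, specs: list[GraftSpec], rng) -> Chronogram:
    """Attach each spec'd tip at a uniform-random age on a random clade branch.

    Candidate branches are those of every node in the attachment clade's
    subtree plus the clade's stem branch; the attachment age is uniform
    along the chosen branch and the new tip extends to the present, so the
    result remains ultrametric. An empty spec list returns the tree
    unchanged.
    """
    if not specs:
        return tree
    rng = np.random.default_rng(rng)
    dtree = tree.to_dendropy()
    node_age = {}
    for nd in dtree.postorder_node_iter():
        node_age[nd] = 0.0 if nd.is_leaf() else node_age[nd.child_nodes()[0]] + (
            nd.child_nodes()[0].edge.length
        )
    label_of = {nd.taxon.label: nd for nd in dtree.leaf_node_iter()}
    for spec in specs:
        missing = [l for l in spec.clade if l not in label_of]
        if missing:
            raise GeoIOError(f"graft clade refers to unknown tips: {missing}")
        if spec.label in label_of:
            raise GeoIOError(f"grafted tip {spec.label!r} already exists")
        mrca = dtree.mrca(taxa=[label_of[l].taxon for l in set(spec.clade)])
        candidates = [nd for nd in mrca.preorder_iter()]
        # candidate branches: stem of the clade plus every internal branch
        candidates = [nd for nd in candidates if nd.parent_node is not None or nd is mrca]
        candidates = [nd for nd in candidates if nd.parent_node is not None]
        if not candidates:
            raise GeoIOError(f"clade of {spec.label!r} offers no branch to graft onto")
        host = candidates[rng.integers(len(candidates))]
        lo, hi = node_age[host], node_age[host.parent_node]
        attach_age = float(rng.uniform(lo, hi))
        parent = host.parent_node
        new_int = dendropy.Node()
        parent.remove_child(host)
        parent.add_child(new_int)
        new_int.add_child(host)
        new_leaf = dendropy.Node()
        new_leaf.taxon = dtree.taxon_namespace.new_taxon(label=spec.label)
        new_int.add_child(new_leaf)
        new_int.edge.length = node_age[parent] - attach_age
        host.edge.length = attach_age - node_age[host]
        new_leaf.edge.length = attach_age
        node_age[new_int] = attach_age
        node_age[new_leaf] = 0.0
        label_of[spec.label] = new_leaf
    return Chronogram.from_dendropy(dtree)


def extend_geography(geog: GeographyTable, specs: list[GraftSpec]) -> GeographyTable:
    """Geography table extended with the grafted taxa's supplied ranges."""
    presence = dict(geog.presence)
    for spec in specs:
        bits = spec.range_bits
        if len(bits) != geog.n_areas or set(bits) - {"0", "1"}:
            raise GeoIOError(f"bad range bits {bits!r} for grafted tip {spec.label!r}")
        mask = sum(1 << i for i, b in enumerate(bits) if b == "1")
        if mask == 0:
            raise GeoIOError(f"grafted tip {spec.label!r} must occupy at least one area")
        presence[spec.label] = mask
    return GeographyTable(list(geog.areas), presence)


def make_tree_set(
    tree: Chronogram,
    n: int,
    jitter_cv: float = 0.0,
    graft_specs: list[GraftSpec] | None = None,
    seed=None,
) -> TreeSet:
    """``n`` pseudoreplicates: jitter then graft, seed-deterministically."""
    specs = graft_specs or []
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    trees = []
    for child in ss.spawn(n):
        rng = np.random.default_rng(child)
        t = jitter_node_ages(tree, jitter_cv, rng)
        t = graft_missing_tips(t, specs, rng)
        trees.append(t)
    return TreeSet(
        trees,
        provenance={
            "n": n,
            "jitter_cv": jitter_cv,
            "grafts": [s.label for s in specs],
            "seed": seed,
        },
    )
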