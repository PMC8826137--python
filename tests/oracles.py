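"""Independent brute-force oracles for small instances.

Everything here is written from the model definition using frozensets and
explicit enumeration — deliberately sharing no code with the package's
bitmask/pruning implementation — so it can serve as an independent check
of the likelihood, the ancestral marginals and the rate matrices on
instances small enough to enumerate (≤4 tips, ≤3 areas).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm


def all_ranges(n_areas, max_size=None):
    """Nonempty subsets ordered by (size, lexicographic), null first."""
    max_size = max_size or n_areas
    out = [frozenset()]
    for k in range(1, max_size + 1):
        for combo in itertools.combinations(range(n_areas), k):
            out.append(frozenset(combo))
    return out


def naive_rate_matrix(ranges, d, e, mult):
    """Generator over `ranges` built directly from the process definition."""
    n = len(ranges)
    Q = np.zeros((n, n))
    idx = {r: i for i, r in enumerate(ranges)}
    max_size = max(len(r) for r in ranges)
    for r in ranges:
        if not r:
            continue
        i = idx[r]
        if len(r) < max_size:
            for b in range(mult.shape[0]):
                if b in r:
                    continue
                grown = r | {b}
                if grown in idx:
                    Q[i, idx[grown]] += d * sum(mult[a, b] for a in r)
        for a in r:
            Q[i, idx[r - {a}]] += e
    for i in range(n):
        Q[i, i] = -Q[i].sum()
    return Q


def naive_clado(r, family):
    """Allowed (left, right, weight) cladogenetic events, from the definition."""
    r = frozenset(r)
    if family == "BAYAREALIKE" or len(r) == 1:
        return [(r, r, 1.0)]
    events = []
    if family == "DEC":
        seen = set()
        for a in r:
            for pair in [(frozenset([a]), r), (r, frozenset([a])),
                         (frozenset([a]), r - {a}), (r - {a}, frozenset([a]))]:
                if pair not in seen:
                    seen.add(pair)
                    events.append(pair)
    elif family == "DIVALIKE":
        for k in range(1, len(r)):
            for combo in itertools.combinations(sorted(r), k):
                left = frozenset(combo)
                events.append((left, r - left))
    else:
        raise ValueError(family)
    w = 1.0 / len(events)
    return [(l, rr, w) for l, rr in events]


def _branch_prob(ranges, d, e, epochs, young_age, old_age):
    """Transition matrix down one branch (parent row, child column)."""
    n = len(ranges)
    P = np.eye(n)
    # walk from the old end toward the present, multiplying slice matrices
    cuts = [old_age]
    for b in sorted((float(x) for x in epochs.boundaries[1:-1]), reverse=True):
        if young_age < b < old_age:
            cuts.append(b)
    cuts.append(young_age)
    for hi, lo in zip(cuts[:-1], cuts[1:]):
        s = epochs.slice_index(0.5 * (hi + lo))
        Q = naive_rate_matrix(ranges, d, e, epochs.multipliers[s])
        P = P @ expm(Q * (hi - lo))
    return P


def brute_force(tree, geog, d, e, family, epochs, max_range_size=None):
    """Total data probability and per-node state sums by full enumeration.

    Sums over every assignment of a range to every node and every allowed
    cladogenetic outcome at every internal node.  Returns (likelihood,
    marginals) where marginals[node] maps each range to its joint
    probability mass (unnormalized).
    """
    ranges = all_ranges(geog.n_areas, max_range_size)
    idx = {r: i for i, r in enumerate(ranges)}
    nonempty = [r for r in ranges if r]
    tip_obs = {}
    for t in range(tree.n_tips):
        lab = tree.labels[t]
        tip_obs[t] = frozenset(
            i for i in range(geog.n_areas) if geog.presence[lab] >> i & 1
        )
    internals = [v for v in tree.postorder if not tree.is_tip(v)]
    P_branch = {
        v: _branch_prob(ranges, d, e, epochs, float(tree.ages[v]),
                        float(tree.ages[tree.parent[v]]))
        for v in range(tree.n_nodes) if v != tree.root
    }
    total = 0.0
    node_mass = {v: {r: 0.0 for r in ranges} for v in range(tree.n_nodes)}
    prior = 1.0 / len(nonempty)

    clado_options = {}
    for v in internals:
        clado_options[v] = {r: naive_clado(r, family) for r in nonempty}

    def rec(order, assignment, weight):
        nonlocal total
        if weight == 0.0:
            return
        if not order:
            total += weight
            for v, r in assignment.items():
                node_mass[v][r] += weight
            return
        v = order[0]
        rest = order[1:]
        lnode, rnode = tree.children[v]
        for l_range, r_range, w in clado_options[v][assignment[v]]:
            # enumerate child endpoint states
            l_states = [tip_obs[lnode]] if tree.is_tip(lnode) else nonempty
            r_states = [tip_obs[rnode]] if tree.is_tip(rnode) else nonempty
            for ls in l_states:
                pl = P_branch[lnode][idx[l_range], idx[ls]]
                if pl == 0.0:
                    continue
                for rs in r_states:
                    pr = P_branch[rnode][idx[r_range], idx[rs]]
                    if pr == 0.0:
                        continue
                    assignment[lnode] = ls
                    assignment[rnode] = rs
                    rec(rest, assignment, weight * w * pl * pr)

    # preorder over internal nodes so parents are assigned before children
    preorder_internals = [v for v in reversed(tree.postorder) if not tree.is_tip(v)]
    for root_state in nonempty:
        rec(preorder_internals, {tree.root: root_state}, prior)
    return total, node_mass
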