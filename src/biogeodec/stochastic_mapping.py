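"""Biogeographic stochastic mapping (BSM).

Samples complete range-evolution histories — cladogenetic events at every
node and anagenetic expansion/contraction events along every branch —
conditional on the observed tip ranges, under a fitted DEC-family model.

The sampler is the standard conditional scheme: the root state is drawn
from its joint posterior, cladogenetic events are drawn node-by-node
conditional on the ancestor state and the daughters' partial likelihoods,
branch endpoints are drawn from the endpoint-conditioned transition
probabilities, and the path within each epoch-homogeneous branch segment
is drawn by uniformization (with a forward-simulation rejection fallback
for numerically awkward segments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .range_evolution import DecLikelihood

__all__ = [
    "BioHistory",
    "EventCounts",
    "StochasticMapper",
    "sample_histories",
    "classify_and_count",
    "summarize_flows",
]


@dataclass
class BioHistory:
    """One sampled (or forward-simulated) biogeographic history.

    ``start_state[v]`` is the state at the *top* of node v's branch (just
    after the parent's cladogenetic event); ``node_state[v]`` the state at
    the node itself (the ancestor state immediately before its own
    cladogenetic event; the observed range for tips).  Anagenetic events
    are ``(branch, age, kind, from_state, to_state)`` with kind
    ``expansion``/``contraction``; cladogenetic events are
    ``(node, age, kind, anc, left, right)``.
    """

    space: object
    area_codes: list
    node_state: np.ndarray
    start_state: np.ndarray
    anagenetic: list = field(default_factory=list)
    cladogenetic: list = field(default_factory=list)
    flagged_null: list = field(default_factory=list)

    def events_on(self, branch: int):
        """Anagenetic events on one branch, oldest first."""
        ev = [x for x in self.anagenetic if x[0] == branch]
        ev.sort(key=lambda x: -x[1])
        return ev

    def trajectory(self, branch: int, old_age: float, young_age: float):
        """Piecewise-constant (old_age, young_age, state) segments along a branch."""
        segs = []
        cur_age, cur_state = old_age, int(self.start_state[branch])
        for _, age, _, _, to_state in self.events_on(branch):
            segs.append((cur_age, age, cur_state))
            cur_age, cur_state = age, int(to_state)
        segs.append((cur_age, young_age, cur_state))
        return segs

    def state_on_branch_at(self, branch: int, old_age: float, young_age: float, age: float) -> int:
        for hi, lo, st in self.trajectory(branch, old_age, young_age):
            if lo <= age <= hi:
                return st
        raise ValueError(f"age {age} outside branch [{young_age}, {old_age}]")

    def _label(self, idx: int) -> str:
        return self.space.label(int(idx), self.area_codes)

    def to_event_log(self, tree, replicate: int = 0) -> pd.DataFrame:
        rows = []
        for branch, age, kind, a, b in self.anagenetic:
            rows.append((replicate, branch, age, kind, self._label(a), self._label(b)))
        for node, age, kind, anc, left, right in self.cladogenetic:
            rows.append(
                (replicate, node, age, kind, self._label(anc),
                 f"{self._label(left)}|{self._label(right)}")
            )
        df = pd.DataFrame(
            rows,
            columns=["replicate", "branch_id", "age_Ma", "event_type", "range_before",
                     "range_after"],
        )
        return df.sort_values("age_Ma", ascending=False, kind="stable").reset_index(drop=True)


class StochasticMapper:
    """Draws BSM samples for one likelihood engine at fixed (d, e)."""

    def __init__(self, engine: DecLikelihood, d: float, e: float, seed=None,
                 max_rejections: int = 1000):
        if getattr(engine, "condition_survival", False):
            raise ValueError("stochastic mapping requires an unconditioned likelihood engine")
        self.engine = engine
        self.d, self.e = float(d), float(e)
        self.rng = np.random.default_rng(seed)
        self.max_rejections = max_rejections
        tree = engine.tree
        props = engine.propagators(self.d, self.e)
        self.node_partials, self.branch_top, _ = engine.downpass(self.d, self.e)
        # per-branch segment matrices (stored old end -> young end) and the
        # suffix products used for sampling states at epoch boundaries
        self.seg_info: dict[int, list] = {}
        self.suffix: dict[int, list] = {}
        n = engine.space.n_states
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            segs = engine.segments[v]  # young -> old
            old_to_young = []
            age_top = tree.ages[tree.parent[v]]
            for dt, s in reversed(segs):
                old_to_young.append((dt, s, props[s].matrix(dt), age_top))
                age_top -= dt
            self.seg_info[v] = old_to_young
            suf = [None] * (len(old_to_young) + 1)
            suf[-1] = np.eye(n)
            for i in range(len(old_to_young) - 1, -1, -1):
                suf[i] = old_to_young[i][2] @ suf[i + 1]
            self.suffix[v] = suf
        # uniformization machinery per slice
        self.Qs = [props[s].Q for s in range(engine.epochs.n_slices)]
        self.mu = [float(max(0.0, -np.diag(Q).min())) * 1.02 for Q in self.Qs]
        self.R = [
            np.eye(n) + Q / m if m > 0 else np.eye(n) for Q, m in zip(self.Qs, self.mu)
        ]
        self._Rpow = [[np.eye(n)] for _ in self.Qs]
        # events grouped by ancestor state for node sampling
        cl = engine.clado
        self.events_by_anc: dict[int, tuple] = {}
        for g in range(1, engine.space.n_states):
            sel = cl.anc == g
            self.events_by_anc[g] = (cl.left[sel], cl.right[sel], cl.weight[sel], cl.kind[sel])

    # -- helpers ------------------------------------------------------------

    def _rpow(self, s: int, k: int) -> np.ndarray:
        pows = self._Rpow[s]
        while len(pows) <= k:
            pows.append(pows[-1] @ self.R[s])
        return pows[k]

    def _draw(self, probs: np.ndarray) -> int:
        tot = probs.sum()
        if tot <= 0:
            raise RuntimeError("zero-probability choice during stochastic mapping")
        return int(self.rng.choice(len(probs), p=probs / tot))

    def _sample_segment(self, s: int, t: float, a: int, b: int, Pab: float, age_old: float):
        """Endpoint-conditioned path within one epoch-homogeneous segment."""
        mu = self.mu[s]
        if mu <= 0.0 or t <= 0.0:
            if a != b:
                raise RuntimeError("endpoint change with zero rates or zero duration")
            return []
        mut = mu * t
        target = self.rng.uniform() * Pab
        n_max = int(mut + 12 * np.sqrt(mut) + 40)
        pois = np.exp(-mut)
        cum, n_jumps = 0.0, None
        for k in range(n_max + 1):
            if k > 0:
                pois *= mut / k
            cum += pois * self._rpow(s, k)[a, b]
            if cum >= target:
                n_jumps = k
                break
        if n_jumps is None:
            return self._reject_segment(s, t, a, b, age_old)
        # state sequence by backward sampling through powers of R
        states = [a]
        cur = a
        for k in range(1, n_jumps + 1):
            probs = self.R[s][cur, :] * self._rpow(s, n_jumps - k)[:, b]
            cur = self._draw(probs)
            states.append(cur)
        taus = np.sort(self.rng.uniform(0.0, t, size=n_jumps))
        events = []
        cur = a
        for st, tau in zip(states[1:], taus):
            if st != cur:
                events.append((age_old - float(tau), cur, int(st)))
                cur = int(st)
        return events

    def _reject_segment(self, s: int, t: float, a: int, b: int, age_old: float):
        """Forward-simulation fallback, accepting paths that end at ``b``."""
        Q = self.Qs[s]
        for _ in range(self.max_rejections):
            cur, tau, events = a, 0.0, []
            while True:
                rate = -Q[cur, cur]
                if rate <= 0:
                    break
                tau += self.rng.exponential(1.0 / rate)
                if tau >= t:
                    break
                probs = Q[cur, :].clip(min=0.0)
                nxt = self._draw(probs)
                events.append((age_old - tau, cur, nxt))
                cur = nxt
            if cur == b:
                return events
        raise RuntimeError(
            f"could not sample an endpoint-conditioned path ({a}->{b}, t={t:.4g}) "
            f"after {self.max_rejections} rejections"
        )

    def _sample_branch(self, v: int, h: int, x: int, history: BioHistory):
        """Path along branch v from start state h (old end) to x (young end)."""
        info = self.seg_info[v]
        suf = self.suffix[v]
        cur = h
        boundary_states = []
        for i in range(len(info) - 1):
            probs = info[i][2][cur, :] * suf[i + 1][:, x]
            nxt = self._draw(probs)
            boundary_states.append(nxt)
            cur = nxt
        cur = h
        space = self.engine.space
        for i, (dt, s, P, age_old) in enumerate(info):
            end = boundary_states[i] if i < len(info) - 1 else x
            for age, frm, to in self._sample_segment(s, dt, cur, end, float(P[cur, end]),
                                                     age_old):
                m_from, m_to = int(space.states[frm]), int(space.states[to])
                kind = "expansion" if m_to & ~m_from else "contraction"
                history.anagenetic.append((v, age, kind, frm, to))
            cur = end

    # -- public API ---------------------------------------------------------

    def sample(self) -> BioHistory:
        engine, tree, space = self.engine, self.engine.tree, self.engine.space
        history = BioHistory(
            space=space,
            area_codes=engine.geog.areas,
            node_state=np.full(tree.n_nodes, -1, dtype=int),
            start_state=np.full(tree.n_nodes, -1, dtype=int),
        )
        root_probs = engine.root_prior() * self.node_partials[tree.root]
        g = self._draw(root_probs)
        history.node_state[tree.root] = g
        history.start_state[tree.root] = g
        for v in reversed(tree.postorder):  # preorder over internals
            if tree.is_tip(v):
                continue
            g = int(history.node_state[v])
            l, r = tree.children[v]
            left, right, w, kind = self.events_by_anc[g]
            probs = w * self.branch_top[l][left] * self.branch_top[r][right]
            k = self._draw(probs)
            history.cladogenetic.append(
                (v, float(tree.ages[v]), str(kind[k]), g, int(left[k]), int(right[k]))
            )
            for child, h in ((l, int(left[k])), (r, int(right[k]))):
                history.start_state[child] = h
                # endpoint at the child node, conditioned on the data below it
                M = self.suffix[child][0]
                probs = M[h, :] * self.node_partials[child]
                x = self._draw(probs)
                history.node_state[child] = x
                self._sample_branch(child, h, x, history)
        obs = engine.tip_state
        assert np.array_equal(history.node_state[: tree.n_tips], obs), (
            "BSM produced tip ranges that differ from the observations"
        )
        return history

    def sample_many(self, n: int) -> list[BioHistory]:
        return [self.sample() for _ in range(n)]


def sample_histories(engine: DecLikelihood, d: float, e: float, n: int, seed=None,
                     max_rejections: int = 1000) -> list[BioHistory]:
    return StochasticMapper(engine, d, e, seed=seed, max_rejections=max_rejections).sample_many(n)


# ---------------------------------------------------------------------------
# Event counting
# ---------------------------------------------------------------------------


@dataclass
class EventCounts:
    """Per-time-bin dispersal and in situ speciation counts for one history.

    ``edges`` ascend from 0 (present) to at least the root age; bin ``i``
    spans ``[edges[i], edges[i+1])``.  ``d_pair[i, a, b]`` is the
    (fractionally attributed) number of dispersals from area ``a`` into
    ``b`` within the bin; ``speciation[i, x]`` the in situ speciation
    count; ``contraction[i, a]`` the number of area losses.
    """

    edges: np.ndarray
    d_pair: np.ndarray
    speciation: np.ndarray
    contraction: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def df(self) -> np.ndarray:
        """Dispersals out of each area per bin (source totals)."""
        return self.d_pair.sum(axis=2)

    @property
    def dt(self) -> np.ndarray:
        """Dispersals into each area per bin (destination totals)."""
        return self.d_pair.sum(axis=1)

    @property
    def total_pair(self) -> np.ndarray:
        return self.d_pair.sum(axis=0)


def _bin_of(edges: np.ndarray, age: float) -> int:
    i = int(np.searchsorted(edges, age, side="right")) - 1
    return min(max(i, 0), len(edges) - 2)


def classify_and_count(
    history: BioHistory,
    edges: np.ndarray,
    source_attribution: str = "fractional",
    speciation_rule: str = "retained",
) -> EventCounts:
    """Tally a history's events into time bins.

    A range expansion adding area ``b`` from prior range ``G`` counts one
    dispersal into ``b``; its source mass is split ``1/|G|`` over the
    occupied areas (``source_attribution="fractional"``, which conserves
    totals) or given fully to every occupied area (``"full"``).  A
    cladogenetic event counts as in situ speciation in ``X`` when the
    ancestor occupies ``X`` and at least one daughter retains ``X``
    (``speciation_rule="retained"``) or when both daughters retain it
    (``"both"``).
    """
    if source_attribution not in ("fractional", "full"):
        raise ValueError("source_attribution must be 'fractional' or 'full'")
    if speciation_rule not in ("retained", "both"):
        raise ValueError("speciation_rule must be 'retained' or 'both'")
    space = history.space
    A = space.n_areas
    edges = np.asarray(edges, dtype=float)
    nb = len(edges) - 1
    d_pair = np.zeros((nb, A, A))
    spec = np.zeros((nb, A))
    contr = np.zeros((nb, A))
    for _, age, kind, frm, to in history.anagenetic:
        i = _bin_of(edges, age)
        m_from, m_to = int(space.states[frm]), int(space.states[to])
        if kind == "expansion":
            b = (m_to & ~m_from).bit_length() - 1
            sources = space.areas_of(m_from)
            share = 1.0 / len(sources) if source_attribution == "fractional" else 1.0
            for a in sources:
                d_pair[i, a, b] += share
        else:
            a = (m_from & ~m_to).bit_length() - 1
            contr[i, a] += 1.0
    for _, age, _, anc, left, right in history.cladogenetic:
        i = _bin_of(edges, age)
        m_anc = int(space.states[anc])
        m_l, m_r = int(space.states[left]), int(space.states[right])
        keep = (m_l | m_r) if speciation_rule == "retained" else (m_l & m_r)
        for x in space.areas_of(m_anc & keep):
            spec[i, x] += 1.0
    return EventCounts(edges, d_pair, spec, contr)


@dataclass
class FlowSummary:
    """Cross-history averages of the pairwise dispersal flows."""

    area_codes: list
    pair_mean: np.ndarray  # (A, A)
    pair_q25: np.ndarray
    pair_q75: np.ndarray

    @property
    def df_mean(self) -> np.ndarray:
        return self.pair_mean.sum(axis=1)

    @property
    def dt_mean(self) -> np.ndarray:
        return self.pair_mean.sum(axis=0)

    def pair_table(self) -> pd.DataFrame:
        rows = []
        A = len(self.area_codes)
        for a in range(A):
            for b in range(A):
                if a == b:
                    continue
                rows.append(
                    {
                        "source": self.area_codes[a],
                        "dest": self.area_codes[b],
                        "mean": self.pair_mean[a, b],
                        "q25": self.pair_q25[a, b],
                        "q75": self.pair_q75[a, b],
                    }
                )
        return pd.DataFrame(rows)

    def role_table(self) -> pd.DataFrame:
        """Per area: total out/in flow and its largest partner each way."""
        rows = []
        A = len(self.area_codes)
        off = ~np.eye(A, dtype=bool)
        for x in range(A):
            out_row = np.where(off[x], self.pair_mean[x], -np.inf)
            in_col = np.where(off[:, x], self.pair_mean[:, x], -np.inf)
            rows.append(
                {
                    "area": self.area_codes[x],
                    "emigration_mean": self.df_mean[x],
                    "immigration_mean": self.dt_mean[x],
                    "top_destination": self.area_codes[int(np.argmax(out_row))],
                    "top_origin": self.area_codes[int(np.argmax(in_col))],
                }
            )
        return pd.DataFrame(rows)


def summarize_flows(counts: list[EventCounts], area_codes) -> FlowSummary:
    if not counts:
        raise ValueError("need at least one history")
    totals = np.stack([c.total_pair for c in counts])
    return FlowSummary(
        list(area_codes),
        totals.mean(axis=0),
        np.quantile(totals, 0.25, axis=0),
        np.quantile(totals, 0.75, axis=0),
    )
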