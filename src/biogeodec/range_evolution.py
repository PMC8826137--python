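"""Dispersal–extinction–cladogenesis (DEC) likelihood over geographic ranges.

The state of a lineage is the set of areas it occupies (its *range*).
Anagenetic evolution along branches is a continuous-time Markov chain:

* range expansion ``G -> G ∪ {b}`` at rate ``d * Σ_{a∈G} m[a][b]`` where
  ``m`` is the dispersal-multiplier matrix of the time slice the branch
  segment falls in;
* range contraction ``G -> G \\ {a}`` at rate ``e`` per occupied area;
  single-area ranges contract into the absorbing null range.

At speciation nodes a cladogenetic event distributes the ancestral range
over the two daughters; the three model families (DEC, DIVALIKE,
BAYAREALIKE) differ only in which events they allow.  Event weights are
uniform over the allowed events (an optional founder-event weight ``j``
adds jump-dispersal events; it is 0 by default).

The tree likelihood is computed by Felsenstein pruning with per-node
rescaling; branches are split at epoch boundaries and propagated with the
slice-specific matrix exponential.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm as _scipy_expm
from scipy.optimize import minimize

from .geoio import Chronogram, EpochModel, GeographyTable

__all__ = [
    "RangeStateSpace",
    "CladoTable",
    "cladogenesis_events",
    "build_rate_matrix",
    "transition_probabilities",
    "DecLikelihood",
    "FitResult",
    "fit_ml",
    "model_selection",
    "FAMILIES",
]

FAMILIES = ("DEC", "DIVALIKE", "BAYAREALIKE")

_LNL_IMPOSSIBLE = -np.inf


class RangeStateSpace:
    """Ordered enumeration of geographic ranges (area subsets) as bitmasks.

    State 0 is the null (empty) range, kept internally as the absorbing
    target of extirpation from single-area ranges; it is never observed at
    tips.  Nonempty states are ordered by range size, then lexicographically
    by area indices, so the ordering is deterministic and independent of
    the data.
    """

    def __init__(self, n_areas: int, max_range_size: int | None = None):
        if n_areas < 1:
            raise ValueError("need at least one area")
        max_range_size = n_areas if max_range_size is None else int(max_range_size)
        if not 1 <= max_range_size <= n_areas:
            raise ValueError("max_range_size must be in [1, n_areas]")
        self.n_areas = int(n_areas)
        self.max_range_size = max_range_size
        masks = [0]
        for size in range(1, max_range_size + 1):
            for combo in itertools.combinations(range(n_areas), size):
                masks.append(sum(1 << i for i in combo))
        self.states = np.array(masks, dtype=np.int64)
        self.index = {int(m): i for i, m in enumerate(masks)}
        self.n_states = len(masks)
        self.sizes = np.array([int(m).bit_count() for m in masks])

    @property
    def n_nonempty(self) -> int:
        return self.n_states - 1

    def areas_of(self, mask: int) -> tuple:
        return tuple(i for i in range(self.n_areas) if mask >> i & 1)

    def label(self, state_index: int, area_codes) -> str:
        mask = int(self.states[state_index])
        if mask == 0:
            return "-"
        return "".join(area_codes[i] for i in self.areas_of(mask))

    def state_of_label(self, label: str, area_codes) -> int:
        mask = sum(1 << list(area_codes).index(ch) for ch in label) if label != "-" else 0
        return self.index[mask]

    def __len__(self):
        return self.n_states

    def __repr__(self):
        return (
            f"<RangeStateSpace: {self.n_areas} areas, max range {self.max_range_size}, "
            f"{self.n_nonempty} nonempty states>"
        )


def build_state_space(n_areas: int, max_range_size: int | None = None) -> RangeStateSpace:
    return RangeStateSpace(n_areas, max_range_size)


# ---------------------------------------------------------------------------
# Anagenetic rate matrix
# ---------------------------------------------------------------------------


def build_rate_matrix(
    space: RangeStateSpace, d: float, e: float, multipliers: np.ndarray
) -> np.ndarray:
    """Dense anagenetic generator over the full state space (null included).

    ``multipliers`` is the area×area dispersal-multiplier matrix of one time
    slice.  Expansion ``G -> G∪{b}`` has rate ``d * Σ_{a∈G} m[a, b]``;
    every contraction has rate ``e``; the null range is absorbing.  Rows
    sum to zero.
    """
    m = np.asarray(multipliers, dtype=float)
    if m.shape != (space.n_areas, space.n_areas):
        raise ValueError("multiplier matrix does not match the number of areas")
    n = space.n_states
    Q = np.zeros((n, n))
    for i in range(1, n):
        G = int(space.states[i])
        occ = space.areas_of(G)
        # expansions (respecting the range-size cap)
        if len(occ) < space.max_range_size:
            for b in range(space.n_areas):
                if G >> b & 1:
                    continue
                j = space.index[G | (1 << b)]
                Q[i, j] += d * float(m[list(occ), b].sum())
        # contractions; single-area ranges fall into the null range
        for a in occ:
            j = space.index[G & ~(1 << a)]
            Q[i, j] += e
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """Row-stochastic ``exp(Q t)`` (scaling-and-squaring on the dense matrix)."""
    if t < 0:
        raise ValueError("elapsed time must be nonnegative")
    if t == 0:
        return np.eye(Q.shape[0])
    P = _scipy_expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


class SlicePropagator:
    """Fast repeated evaluation of ``exp(Q t) @ v`` for one slice's generator.

    Uses the eigendecomposition of Q when it is numerically trustworthy
    (checked against the reconstruction of Q itself), otherwise falls back
    to scipy's expm per requested duration.
    """

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self._cache: dict[float, np.ndarray] = {}
        self._use_eig = False
        try:
            lam, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            err = np.max(np.abs((V * lam) @ Vinv - Q))
            scale = max(1.0, np.max(np.abs(Q)))
            if err < 1e-9 * scale:
                self._lam, self._V, self._Vinv = lam, V, Vinv
                self._use_eig = True
        except np.linalg.LinAlgError:
            pass

    def apply(self, v: np.ndarray, t: float) -> np.ndarray:
        """``exp(Q t) @ v`` for a vector (or column-stacked matrix) v."""
        if t == 0:
            return v.copy()
        if self._use_eig:
            w = self._Vinv @ v
            if v.ndim == 1:
                w = np.exp(self._lam * t) * w
            else:
                w = np.exp(self._lam * t)[:, None] * w
            out = np.real(self._V @ w)
            np.clip(out, 0.0, None, out=out)
            return out
        return self.matrix(t) @ v

    def apply_transpose(self, v: np.ndarray, t: float) -> np.ndarray:
        """``exp(Q t).T @ v`` — rootward quantities pushed tipward."""
        if t == 0:
            return v.copy()
        if self._use_eig:
            w = np.exp(self._lam * t) * (self._V.T @ v)
            out = np.real(self._Vinv.T @ w)
            np.clip(out, 0.0, None, out=out)
            return out
        return self.matrix(t).T @ v

    def matrix(self, t: float) -> np.ndarray:
        P = self._cache.get(t)
        if P is None:
            P = transition_probabilities(self.Q, t)
            self._cache[t] = P
        return P


# ---------------------------------------------------------------------------
# Cladogenesis
# ---------------------------------------------------------------------------


@dataclass
class CladoTable:
    """Flat arrays of allowed cladogenetic events for one model family.

    ``anc[k], left[k], right[k]`` are state indices and ``weight[k]`` the
    event probability given the ancestral state (weights sum to 1 within
    each ancestor).  ``kind[k]`` classifies the event (``sympatry-copy``,
    ``subset-sympatry``, ``vicariance``, ``founder``).
    """

    anc: np.ndarray
    left: np.ndarray
    right: np.ndarray
    weight: np.ndarray
    kind: np.ndarray

    def events_for(self, anc_index: int):
        sel = self.anc == anc_index
        return list(zip(self.left[sel], self.right[sel], self.weight[sel], self.kind[sel]))


def cladogenesis_events(
    ancestor_mask: int, family: str, space: RangeStateSpace, founder_weight: float = 0.0
) -> list[tuple[int, int, float, str]]:
    """Allowed (left_mask, right_mask, weight, kind) events for one ancestor range.

    DEC: single-area ranges copy; widespread ranges split by subset sympatry
    (one daughter a single occupied area, the other the full range) or
    strict vicariance (one daughter a single area, the other the rest).
    DIVALIKE: copy for single areas, otherwise every vicariant bipartition.
    BAYAREALIKE: the range is copied unchanged, whatever its size.
    Weights are uniform over the allowed events; founder events (one
    daughter jumps to an unoccupied single area) get relative weight
    ``founder_weight`` against 1 for each standard event.
    """
    G = int(ancestor_mask)
    if G == 0:
        raise ValueError("ancestor range must be nonempty")
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    occ = space.areas_of(G)
    events: list[tuple[int, int, str]] = []
    if family == "BAYAREALIKE":
        events.append((G, G, "sympatry-copy"))
    elif len(occ) == 1:
        events.append((G, G, "sympatry-copy"))
    elif family == "DEC":
        seen = set()
        for a in occ:
            s = 1 << a
            for pair in ((s, G), (G, s)):
                if pair not in seen:
                    seen.add(pair)
                    events.append((*pair, "subset-sympatry"))
        for a in occ:
            s = 1 << a
            rest = G & ~s
            for pair in ((s, rest), (rest, s)):
                if pair not in seen:
                    seen.add(pair)
                    events.append((*pair, "vicariance"))
    else:  # DIVALIKE: every ordered vicariant bipartition
        for sub in range(1, 1 << space.n_areas):
            if sub & ~G or sub == G:
                continue
            if (sub & G) != sub:
                continue
            events.append((sub, G & ~sub, "vicariance"))
    rel = [1.0] * len(events)
    if founder_weight > 0:
        for b in range(space.n_areas):
            if G >> b & 1:
                continue
            s = 1 << b
            events.append((s, G, "founder"))
            events.append((G, s, "founder"))
            rel.extend([founder_weight, founder_weight])
    total = float(sum(rel))
    return [(l, r, w / total, kind) for (l, r, kind), w in zip(events, rel)]


def build_clado_table(
    space: RangeStateSpace, family: str, founder_weight: float = 0.0
) -> CladoTable:
    anc, left, right, weight, kind = [], [], [], [], []
    for i in range(1, space.n_states):
        for l, r, w, k in cladogenesis_events(
            int(space.states[i]), family, space, founder_weight
        ):
            anc.append(i)
            left.append(space.index[l])
            right.append(space.index[r])
            weight.append(w)
            kind.append(k)
    return CladoTable(
        np.array(anc), np.array(left), np.array(right), np.array(weight), np.array(kind)
    )


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


class DecLikelihood:
    """Pruning-algorithm likelihood engine for one (tree, geography, family).

    Precomputes tip states, per-branch epoch segments and the cladogenesis
    table; ``loglike(d, e)`` is then cheap to call repeatedly during
    optimization.  The root is averaged under a uniform prior over the
    nonempty states of the space.
    """

    def __init__(
        self,
        tree: Chronogram,
        geog: GeographyTable,
        family: str = "DEC",
        epochs: EpochModel | None = None,
        space: RangeStateSpace | None = None,
        founder_weight: float = 0.0,
        condition_survival: bool = False,
    ):
        geog.check_against(tree)
        self.tree = tree
        self.geog = geog
        self.family = family
        self.space = space or RangeStateSpace(geog.n_areas)
        self.epochs = epochs or EpochModel.uniform(geog.n_areas)
        if self.epochs.n_areas != geog.n_areas:
            raise ValueError("epoch model and geography disagree on the number of areas")
        if tree.root_age > self.epochs.boundaries[0] + 1e-9:
            raise ValueError(
                f"root age {tree.root_age:g} Ma exceeds the oldest slice boundary "
                f"{self.epochs.boundaries[0]:g} Ma"
            )
        self.founder_weight = founder_weight
        # survival conditioning: every branch kernel is censored against the
        # null range and renormalized, matching data generated by a forward
        # process in which lineages are conditioned on never going extinct
        self.condition_survival = condition_survival
        self.clado = build_clado_table(self.space, family, founder_weight)
        self.tip_state = np.array(
            [self.space.index[geog.presence[lab]] for lab in tree.labels]
        )
        self.segments = {
            v: self.epochs.segments(tree.ages[v], tree.ages[tree.parent[v]])
            for v in range(tree.n_nodes)
            if v != tree.root
        }
        self._prop_cache: dict[tuple[float, float], list[SlicePropagator]] = {}

    # -- propagators --------------------------------------------------------

    def propagators(self, d: float, e: float) -> list[SlicePropagator]:
        key = (float(d), float(e))
        props = self._prop_cache.get(key)
        if props is None:
            props = []
            for s in range(self.epochs.n_slices):
                Q = build_rate_matrix(self.space, d, e, self.epochs.multipliers[s])
                if self.condition_survival:
                    Q = Q.copy()
                    Q[:, 0] = 0.0  # censor paths through the null range (leaky generator)
                props.append(SlicePropagator(Q))
            if len(self._prop_cache) > 8:
                self._prop_cache.clear()
            self._prop_cache[key] = props
        return props

    def propagate_branch(self, partials: np.ndarray, node: int, props) -> np.ndarray:
        """Carry tip-side partials from a node to the bottom of its parent."""
        v = partials
        for dt, s in self.segments[node]:
            v = props[s].apply(v, dt)
        if self.condition_survival:
            surv = np.zeros_like(partials)
            surv[1:] = 1.0
            for dt, s in self.segments[node]:
                surv = props[s].apply(surv, dt)
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.where(surv > 0, v / surv, 0.0)
        return v

    # -- pruning ------------------------------------------------------------

    def downpass(self, d: float, e: float):
        """Per-node partials and log-scalers; returns (node_partials, branch_top, log_scale).

        ``node_partials[v]`` is the (rescaled) likelihood of the data below
        node ``v`` given each state at ``v``; ``branch_top[v]`` the same
        quantity propagated to the top of ``v``'s branch.  The sum of
        ``log_scale`` restores the absolute scale.
        """
        props = self.propagators(d, e)
        tree = self.tree
        node_partials: dict[int, np.ndarray] = {}
        branch_top: dict[int, np.ndarray] = {}
        log_scale = 0.0
        cl = self.clado
        for v in tree.postorder:
            if tree.is_tip(v):
                part = np.zeros(self.space.n_states)
                part[self.tip_state[v]] = 1.0
            else:
                l, r = tree.children[v]
                part = np.zeros(self.space.n_states)
                np.add.at(
                    part,
                    cl.anc,
                    cl.weight * branch_top[l][cl.left] * branch_top[r][cl.right],
                )
            tot = part.sum()
            if tot > 0:
                part = part / tot
                log_scale += np.log(tot)
            node_partials[v] = part
            if v != tree.root:
                branch_top[v] = self.propagate_branch(part, v, props)
        return node_partials, branch_top, log_scale

    def loglike(self, d: float, e: float) -> float:
        node_partials, _, log_scale = self.downpass(d, e)
        root = node_partials[self.tree.root]
        avg = root[1:].sum() / self.space.n_nonempty
        if avg <= 0 or not np.isfinite(avg):
            return _LNL_IMPOSSIBLE
        return float(np.log(avg) + log_scale)

    def root_prior(self) -> np.ndarray:
        pi = np.zeros(self.space.n_states)
        pi[1:] = 1.0 / self.space.n_nonempty
        return pi


def tree_log_likelihood(
    tree: Chronogram,
    geog: GeographyTable,
    d: float,
    e: float,
    family: str = "DEC",
    epochs: EpochModel | None = None,
    space: RangeStateSpace | None = None,
) -> float:
    return DecLikelihood(tree, geog, family, epochs, space).loglike(d, e)


# ---------------------------------------------------------------------------
# ML fitting and model selection
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """One fitted range-evolution model, plus model-selection annotations."""

    family: str
    constrained: bool
    lnL: float
    n_params: int
    d: float
    e: float
    j: float = 0.0
    converged: bool = True
    aic: float = np.nan
    aicc: float = np.nan
    delta_aic: float = np.nan
    delta_aicc: float = np.nan
    aic_weight: float = np.nan
    aicc_weight: float = np.nan

    @property
    def label(self) -> str:
        return f"{self.family}{'+constrained' if self.constrained else ''}"

    def to_dict(self) -> dict:
        return {
            "model": self.family,
            "constraint": "constrained" if self.constrained else "unconstrained",
            "LnL": self.lnL,
            "numparams": self.n_params,
            "d": self.d,
            "e": self.e,
            "j": self.j,
            "AIC": self.aic,
            "dAIC": self.delta_aic,
            "AIC_wt": self.aic_weight,
            "AICc": self.aicc,
            "dAICc": self.delta_aicc,
            "AICc_wt": self.aicc_weight,
        }


DEFAULT_START = (0.01, 0.01)
DEFAULT_BOUNDS = ((1e-9, 5.0), (1e-9, 5.0))


def optimize_engine(
    engine: DecLikelihood,
    constrained: bool,
    start: tuple = DEFAULT_START,
    bounds: tuple = DEFAULT_BOUNDS,
) -> FitResult:
    """Bounded L-BFGS-B maximization of (d, e) from a fixed start point.

    The search runs on log-rates (same start point and box bounds), which
    evens out the scale of the two parameters near the lower bound.
    """

    def nll(z):
        v = engine.loglike(np.exp(z[0]), np.exp(z[1]))
        return 1e12 if not np.isfinite(v) else -v

    res = minimize(
        nll,
        np.log(np.asarray(start, dtype=float)),
        method="L-BFGS-B",
        bounds=[(np.log(lo), np.log(hi)) for lo, hi in bounds],
    )
    d_hat, e_hat = map(float, np.exp(res.x))
    lnl = engine.loglike(d_hat, e_hat)
    # the optimizer must not end below its own start point
    lnl_start = engine.loglike(*start)
    converged = bool(res.success)
    if lnl_start > lnl:
        d_hat, e_hat, lnl, converged = start[0], start[1], lnl_start, False
    return FitResult(
        family=engine.family, constrained=constrained, lnL=lnl, n_params=2,
        d=d_hat, e=e_hat, converged=converged,
    )


def fit_ml(
    tree: Chronogram,
    geog: GeographyTable,
    family: str = "DEC",
    epochs: EpochModel | None = None,
    space: RangeStateSpace | None = None,
    start: tuple = DEFAULT_START,
    bounds: tuple = DEFAULT_BOUNDS,
) -> FitResult:
    """Maximum-likelihood fit of (d, e) by bounded L-BFGS-B from a fixed start."""
    engine = DecLikelihood(tree, geog, family, epochs, space)
    constrained = epochs is not None and not np.all(epochs.multipliers == 1.0)
    return optimize_engine(engine, constrained, start, bounds)


def model_selection(fits: list[FitResult], n_obs: int) -> list[FitResult]:
    """Annotate fits with AIC, AICc, deltas and Akaike weights.

    AIC = 2k − 2lnL; AICc adds the small-sample correction
    ``2k(k+1)/(n_obs − k − 1)``; weights are ``exp(−Δ/2)`` normalized over
    the compared set.  ``n_obs`` is the number of tips by convention.
    """
    if not fits:
        raise ValueError("need at least one fit")
    out = []
    for f in fits:
        k = f.n_params
        aic = 2 * k - 2 * f.lnL
        if n_obs > k + 1:
            aicc = aic + 2 * k * (k + 1) / (n_obs - k - 1)
        else:
            aicc = np.nan
        out.append(replace(f, aic=aic, aicc=aicc))
    out = akaike_weights(out)
    return out


def akaike_weights(fits: list[FitResult]) -> list[FitResult]:
    """Fill deltas and weights from already-computed AIC/AICc columns."""
    aics = np.array([f.aic for f in fits])
    aiccs = np.array([f.aicc for f in fits])
    d_aic = aics - np.nanmin(aics)
    w_aic = np.exp(-0.5 * d_aic)
    w_aic /= w_aic.sum()
    if np.all(np.isfinite(aiccs)):
        d_aicc = aiccs - np.nanmin(aiccs)
        w_aicc = np.exp(-0.5 * d_aicc)
        w_aicc /= w_aicc.sum()
    else:
        d_aicc = np.full(len(fits), np.nan)
        w_aicc = np.full(len(fits), np.nan)
    return [
        replace(f, delta_aic=da, delta_aicc=dc, aic_weight=wa, aicc_weight=wc)
        for f, da, dc, wa, wc in zip(fits, d_aic, d_aicc, w_aic, w_aicc)
    ]


def comparison_table(fits: list[FitResult]) -> pd.DataFrame:
    """Model-comparison table (one row per fitted scenario)."""
    return pd.DataFrame([f.to_dict() for f in fits])
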