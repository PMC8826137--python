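"""Rate-through-time statistics over stochastic-mapping replicates.

For each time bin ``t1`` (with older edge ``t0``) and each area ``X``:

* in situ speciation rate        ``λ_X(t1) = s_X(t1) / L_X(t0)``
* colonization rate (pairwise)   ``c_XtoY(t1) = d_XtoY(t1) / Br(t1)``
* emigration rate                ``E_X(t1) = df_X(t1) / Br(t1)``
* immigration rate               ``I_X(t1) = dt_X(t1) / Br(t1)``

where ``s_X`` counts in situ speciation events, ``d_XtoY``/``df_X``/``dt_X``
the (fractionally attributed) dispersal counts, ``L_X(t0)`` the lineages
occupying ``X`` at the bin's older edge, and ``Br(t1)`` the total branch
length (lineage-Myr) of the whole tree within the bin.  Rates are computed
per replicate history and summarized across replicates by the median and
the 0.25/0.75 quantiles.  Bins with a zero denominator are emitted as
missing (NaN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geoio import Chronogram
from .stochastic_mapping import BioHistory, EventCounts, classify_and_count

__all__ = [
    "branch_length_in_bin",
    "lineages_in_area_at",
    "RateBinSeries",
    "rates_through_time",
    "relay_summary",
    "changeovers",
]


def branch_length_in_bin(tree: Chronogram, lo: float, hi: float) -> float:
    """Total lineage-Myr of the tree inside the age interval [lo, hi]."""
    if hi <= lo:
        return 0.0
    total = 0.0
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        total += max(0.0, min(hi, tree.ages[p]) - max(lo, tree.ages[v]))
    return total


def lineages_in_area_at(history: BioHistory, tree: Chronogram, age: float) -> np.ndarray:
    """Per-area count of lineages alive at ``age`` whose range contains the area.

    A branch is alive at an age strictly below its parent node and at or
    above its child node; multi-area ranges count once in each occupied
    area.
    """
    space = history.space
    counts = np.zeros(space.n_areas)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0 or not (tree.ages[v] <= age < tree.ages[p]):
            continue
        st = history.state_on_branch_at(v, float(tree.ages[p]), float(tree.ages[v]), age)
        for a in space.areas_of(int(space.states[st])):
            counts[a] += 1
    return counts


def _area_branch_length_in_bin(
    history: BioHistory, tree: Chronogram, lo: float, hi: float
) -> np.ndarray:
    """Per-area lineage-Myr restricted to segments whose range contains the area."""
    space = history.space
    out = np.zeros(space.n_areas)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        for seg_hi, seg_lo, st in history.trajectory(
            v, float(tree.ages[p]), float(tree.ages[v])
        ):
            ov = max(0.0, min(hi, seg_hi) - max(lo, seg_lo))
            if ov > 0:
                for a in space.areas_of(int(space.states[st])):
                    out[a] += ov
    return out


@dataclass
class RateBinSeries:
    """Per-replicate, per-bin rates with cross-replicate quartile summaries.

    Arrays are indexed ``[replicate, bin, ...]`` with bin 0 the youngest
    (spanning ``[edges[0], edges[1]]``).
    """

    area_codes: list
    edges: np.ndarray
    lam: np.ndarray  # (R, nb, A) in situ speciation rate
    c: np.ndarray  # (R, nb, A, A) colonization rate
    E: np.ndarray  # (R, nb, A) emigration rate
    I: np.ndarray  # (R, nb, A) immigration rate
    L: np.ndarray  # (R, nb, A) lineage counts at the bin's older edge
    Br: np.ndarray  # (R, nb) lineage-Myr per bin

    @property
    def n_replicates(self) -> int:
        return self.lam.shape[0]

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def _summarize(self, arr: np.ndarray):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            med = np.nanmedian(arr, axis=0)
            q25 = np.nanquantile(arr, 0.25, axis=0)
            q75 = np.nanquantile(arr, 0.75, axis=0)
        return med, q25, q75

    def median(self, statistic: str) -> np.ndarray:
        return self._summarize(getattr(self, statistic))[0]

    def mean(self, statistic: str) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            return np.nanmean(getattr(self, statistic), axis=0)

    def summary(self) -> pd.DataFrame:
        """Long-format table: bin, area [, dest], statistic, median, q25, q75."""
        rows = []
        mids = 0.5 * (self.edges[:-1] + self.edges[1:])
        for stat in ("lam", "E", "I"):
            med, q25, q75 = self._summarize(getattr(self, stat))
            for i in range(self.n_bins):
                for a, code in enumerate(self.area_codes):
                    rows.append(
                        {"bin_mid_Ma": mids[i], "area": code, "dest": "", "statistic": stat,
                         "median": med[i, a], "q25": q25[i, a], "q75": q75[i, a]}
                    )
        med, q25, q75 = self._summarize(self.c)
        for i in range(self.n_bins):
            for a, ca in enumerate(self.area_codes):
                for b, cb in enumerate(self.area_codes):
                    if a == b:
                        continue
                    rows.append(
                        {"bin_mid_Ma": mids[i], "area": ca, "dest": cb, "statistic": "c",
                         "median": med[i, a, b], "q25": q25[i, a, b], "q75": q75[i, a, b]}
                    )
        return pd.DataFrame(rows)


def rates_through_time(
    histories: list[BioHistory],
    trees,
    bin_width: float = 0.5,
    source_attribution: str = "fractional",
    speciation_rule: str = "retained",
    area_restricted_br: bool = False,
) -> RateBinSeries:
    """The four per-bin rate statistics for every replicate history.

    ``trees`` is either one chronogram shared by all histories or a list
    parallel to ``histories`` (pseudoreplicated trees).  With
    ``area_restricted_br`` the denominator of c/E/I becomes the per-area
    occupied branch length instead of the whole-tree branch length.
    """
    if not histories:
        raise ValueError("need at least one history")
    if isinstance(trees, Chronogram):
        trees = [trees] * len(histories)
    if len(trees) != len(histories):
        raise ValueError("need one tree per history (or a single shared tree)")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    area_codes = histories[0].area_codes
    A = len(area_codes)
    max_root = max(t.root_age for t in trees)
    nb = int(np.ceil(max_root / bin_width - 1e-12))
    edges = bin_width * np.arange(nb + 1)
    R = len(histories)
    lam = np.full((R, nb, A), np.nan)
    c = np.full((R, nb, A, A), np.nan)
    E = np.full((R, nb, A), np.nan)
    I = np.full((R, nb, A), np.nan)
    L = np.zeros((R, nb, A))
    Br = np.zeros((R, nb))
    for r, (h, tree) in enumerate(zip(histories, trees)):
        counts: EventCounts = classify_and_count(
            h, edges, source_attribution=source_attribution, speciation_rule=speciation_rule
        )
        for i in range(nb):
            lo, hi = edges[i], edges[i + 1]
            Br[r, i] = branch_length_in_bin(tree, lo, hi)
            t0 = min(hi, tree.root_age - 1e-9)
            if t0 >= lo:
                L[r, i] = lineages_in_area_at(h, tree, t0)
            if area_restricted_br:
                denom = _area_branch_length_in_bin(h, tree, lo, hi)
                with np.errstate(divide="ignore", invalid="ignore"):
                    c[r, i] = np.where(denom[:, None] > 0,
                                       counts.d_pair[i] / denom[:, None], np.nan)
                    E[r, i] = np.where(denom > 0, counts.df[i] / denom, np.nan)
                    I[r, i] = np.where(denom > 0, counts.dt[i] / denom, np.nan)
            elif Br[r, i] > 0:
                c[r, i] = counts.d_pair[i] / Br[r, i]
                E[r, i] = counts.df[i] / Br[r, i]
                I[r, i] = counts.dt[i] / Br[r, i]
            occupied = L[r, i] > 0
            lam[r, i, occupied] = counts.speciation[i, occupied] / L[r, i, occupied]
    return RateBinSeries(list(area_codes), edges, lam, c, E, I, L, Br)


def relay_summary(series: RateBinSeries, aggregate: str = "median") -> pd.DataFrame:
    """Contiguous intervals over which each area holds the maximum rate.

    For each of the three per-area statistics (λ, E, I) the cross-replicate
    summary (``aggregate``: the median, matching the ribbon plots, or the
    mean, which keeps information from sparse low-count bins whose median
    is degenerate at zero) is compared across areas bin by bin, oldest bin
    first; runs of a single winning area form the "relay" phases.  Ties
    are reported explicitly as slash-joined area codes; all-missing bins
    carry no winner and break phases.
    """
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    rows = []
    edges = series.edges
    for stat in ("lam", "E", "I"):
        med = getattr(series, aggregate)(stat)  # (nb, A)
        winners = []
        for i in range(series.n_bins - 1, -1, -1):  # oldest bin first
            vals = med[i]
            if np.all(np.isnan(vals)) or np.nanmax(vals) <= 0:
                winners.append((i, None))
                continue
            top = np.nanmax(vals)
            best = [series.area_codes[a] for a in range(len(vals))
                    if not np.isnan(vals[a]) and vals[a] == top]
            winners.append((i, "/".join(best)))
        run_area, run_start = None, None
        for i, area in winners:
            if area != run_area:
                if run_area is not None:
                    rows.append({"statistic": stat, "area": run_area,
                                 "old_age_Ma": edges[run_start + 1], "young_age_Ma": edges[i + 1]})
                run_area, run_start = area, i
        if run_area is not None:
            rows.append({"statistic": stat, "area": run_area,
                         "old_age_Ma": edges[run_start + 1], "young_age_Ma": edges[0]})
    df = pd.DataFrame(rows, columns=["statistic", "area", "old_age_Ma", "young_age_Ma"])
    return df[df["area"].notna()].reset_index(drop=True)


def changeovers(phases: pd.DataFrame, statistic: str) -> list[tuple[float, str, str]]:
    """(age, from_area, to_area) at each phase boundary of one statistic."""
    sub = phases[phases["statistic"] == statistic].reset_index(drop=True)
    out = []
    for i in range(1, len(sub)):
        out.append(
            (float(sub.loc[i, "old_age_Ma"]), str(sub.loc[i - 1, "area"]), str(sub.loc[i, "area"]))
        )
    return out
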