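"""Model/Results objects tying the pieces together.

``RangeEvolutionModel`` is built from a chronogram and a geography table
(plus the model family and optional epoch constraints); ``fit()`` returns
a ``RangeEvolutionResults`` carrying the estimates, likelihood,
information criteria and a ``summary()`` table, with ancestral-state
estimation and stochastic mapping hanging off the results object.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import range_evolution as _re
from .ancestral import AncestralEstimates, ancestral_marginals
from .geoio import (
    Chronogram,
    EpochModel,
    GeographyTable,
    read_chronogram,
    read_geography,
    read_multipliers,
)
from .range_evolution import DecLikelihood, FitResult
from .stochastic_mapping import sample_histories

__all__ = ["RangeEvolutionModel", "RangeEvolutionResults", "compare_fits"]


class RangeEvolutionModel:
    """DEC-family range-evolution model for one tree + geography dataset.

    Parameters
    ----------
    tree : Chronogram
        Ultrametric chronogram (ages in Ma).
    geography : GeographyTable
        Tip ranges over the ordered area codes.
    family : {"DEC", "DIVALIKE", "BAYAREALIKE"}
        Cladogenetic model family.
    epochs : EpochModel, optional
        Time-stratified dispersal multipliers; omitted means the
        unconstrained (all-ones, single-slice) model.
    max_range_size : int, optional
        Cap on the number of areas per range (default: all areas).
    founder_weight : float
        Relative weight of founder (jump-dispersal) cladogenesis; 0 by
        default, which reproduces the three classic families.
    """

    def __init__(
        self,
        tree: Chronogram,
        geography: GeographyTable,
        family: str = "DEC",
        epochs: EpochModel | None = None,
        max_range_size: int | None = None,
        founder_weight: float = 0.0,
        condition_survival: bool = False,
    ):
        space = _re.RangeStateSpace(geography.n_areas, max_range_size)
        self.engine = DecLikelihood(
            tree, geography, family, epochs, space, founder_weight,
            condition_survival=condition_survival,
        )
        self.tree = tree
        self.geography = geography
        self.family = family
        self.epochs = self.engine.epochs
        self.constrained = epochs is not None and not np.all(epochs.multipliers == 1.0)

    @classmethod
    def from_files(
        cls,
        tree_path,
        geography_path,
        family: str = "DEC",
        multipliers_path=None,
        **kwargs,
    ) -> "RangeEvolutionModel":
        tree = read_chronogram(tree_path)
        geog = read_geography(geography_path)
        epochs = read_multipliers(multipliers_path) if multipliers_path else None
        return cls(tree, geog, family=family, epochs=epochs, **kwargs)

    # -- statsmodels-ish API -------------------------------------------------

    def loglike(self, params) -> float:
        d, e = params
        return self.engine.loglike(float(d), float(e))

    def fit(self, start=_re.DEFAULT_START, bounds=_re.DEFAULT_BOUNDS) -> "RangeEvolutionResults":
        """Maximum-likelihood estimate of (d, e); deterministic given config."""
        fr = _re.optimize_engine(self.engine, self.constrained, start, bounds)
        return RangeEvolutionResults(self, fr)

    def fit_fixed(self, d: float, e: float) -> "RangeEvolutionResults":
        """Results object at user-supplied parameters (no optimization)."""
        fr = FitResult(
            family=self.family, constrained=self.constrained,
            lnL=self.engine.loglike(d, e), n_params=2, d=float(d), e=float(e),
        )
        return RangeEvolutionResults(self, fr)


class RangeEvolutionResults:
    """Fitted (or fixed-parameter) range-evolution model results."""

    def __init__(self, model: RangeEvolutionModel, fit: FitResult):
        self.model = model
        self.fit_result = fit

    # estimates ------------------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        return np.array([self.fit_result.d, self.fit_result.e])

    @property
    def d(self) -> float:
        return self.fit_result.d

    @property
    def e(self) -> float:
        return self.fit_result.e

    @property
    def llf(self) -> float:
        return self.fit_result.lnL

    @property
    def df_model(self) -> int:
        return self.fit_result.n_params

    @property
    def nobs(self) -> int:
        return self.model.tree.n_tips

    @property
    def aic(self) -> float:
        return 2 * self.df_model - 2 * self.llf

    @property
    def aicc(self) -> float:
        k, n = self.df_model, self.nobs
        return self.aic + 2 * k * (k + 1) / (n - k - 1)

    def summary(self) -> str:
        f = self.fit_result
        lines = [
            "Range evolution model results",
            "=" * 46,
            f"family:          {f.family}",
            f"constraint:      {'constrained' if f.constrained else 'unconstrained'}",
            f"tips (n_obs):    {self.nobs}",
            f"areas:           {''.join(self.model.geography.areas)}",
            f"states:          {self.model.engine.space.n_nonempty} (+ null)",
            f"log-likelihood:  {self.llf:.4f}",
            f"d (dispersal):   {f.d:.6g}  events/lineage/Myr",
            f"e (extirpation): {f.e:.6g}  events/lineage/Myr",
            f"AIC:             {self.aic:.4f}",
            f"AICc:            {self.aicc:.4f}",
            f"converged:       {f.converged}",
        ]
        return "\n".join(lines)

    # downstream analyses ----------------------------------------------------
    def ancestral_states(self) -> AncestralEstimates:
        return ancestral_marginals(self.model.engine, self.d, self.e)

    def stochastic_maps(self, n: int, seed=None, max_rejections: int = 1000):
        return sample_histories(
            self.model.engine, self.d, self.e, n, seed=seed, max_rejections=max_rejections
        )

    # persistence ------------------------------------------------------------
    def to_json(self, path=None, inputs: dict | None = None) -> str:
        payload = {
            "family": self.fit_result.family,
            "constrained": self.fit_result.constrained,
            "lnL": self.llf,
            "n_params": self.df_model,
            "n_obs": self.nobs,
            "d": self.d,
            "e": self.e,
            "j": self.fit_result.j,
            "AIC": self.aic,
            "AICc": self.aicc,
            "converged": self.fit_result.converged,
            "inputs": inputs or {},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def compare_fits(fits, n_obs: int) -> pd.DataFrame:
    """Model-comparison table with AIC/AICc deltas and Akaike weights.

    ``fits`` may mix ``RangeEvolutionResults`` and raw ``FitResult``
    objects (or dicts with keys lnL/n_params/family/constrained, as read
    from fit JSON files).
    """
    raw = []
    for f in fits:
        if isinstance(f, RangeEvolutionResults):
            raw.append(f.fit_result)
        elif isinstance(f, FitResult):
            raw.append(f)
        else:
            raw.append(
                FitResult(
                    family=f["family"],
                    constrained=bool(f.get("constrained", False)),
                    lnL=float(f["lnL"]),
                    n_params=int(f.get("n_params", 2)),
                    d=float(f.get("d", np.nan)),
                    e=float(f.get("e", np.nan)),
                )
            )
    annotated = _re.model_selection(raw, n_obs)
    return _re.comparison_table(annotated)
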