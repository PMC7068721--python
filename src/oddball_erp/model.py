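"""Model/Results facades over the library.

:class:`OutcomeModel` is the hierarchical outcome-association model
(screened anthropometric predictor, then the delta-P3 marker) with a
statsmodels-flavoured ``fit()`` returning an :class:`OutcomeResults`
object; :class:`OddballStudy` wraps a whole simulated study run the same
way.
"""
from __future__ import annotations

import pandas as pd

from .pipeline import RunConfig, StudyResults, run_pipeline
from .stats import HierarchicalResult, hierarchical_regression


class OutcomeResults:
    """Fitted outcome model: coefficient table, R-squared change and the
    screening log, with ``summary()`` and a marker-vs-outcome plot."""

    def __init__(self, model: "OutcomeModel", res: HierarchicalResult):
        self.model = model
        self._res = res
        self.params = res.params
        self.bse = res.params / res.tvalues.replace(0, float("nan")) \
            if hasattr(res.tvalues, "replace") else res.params / res.tvalues
        self.tvalues = res.tvalues
        self.pvalues = res.pvalues
        self.rsquared_null = res.rsq_null
        self.rsquared = res.rsq_full
        self.rsquared_change = res.rsq_change
        self.f_change = res.f_change
        self.p_change = res.p_change
        self.selected_predictor = res.selected_predictor
        self.screening = res.screening
        self.nobs = res.n

    def summary(self) -> str:
        return self._res.summary()

    def plot(self, ax=None):
        """Scatter of the marker against the outcome with the
        marginal fit line."""
        import matplotlib.pyplot as plt
        import numpy as np

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.data
        ax.scatter(df[self.model.marker], df[self.model.outcome],
                   s=18, alpha=0.7)
        x = np.linspace(df[self.model.marker].min(),
                        df[self.model.marker].max(), 50)
        b = np.polyfit(df[self.model.marker], df[self.model.outcome], 1)
        ax.plot(x, np.polyval(b, x), color="C3")
        ax.set_xlabel("delta-P3 (uV)")
        ax.set_ylabel("outcome composite")
        return ax


class OutcomeModel:
    """Hierarchical regression of the outcome composite on a screened
    anthropometric predictor plus the delta-P3 marker (model_id 1:
    size at 5 months; 2: growth between ages)."""

    def __init__(self, data: pd.DataFrame, model_id: int = 1,
                 outcome: str = "outcome", marker: str = "delta_p3",
                 candidates: list[str] | None = None):
        self.data = data
        self.model_id = model_id
        self.outcome = outcome
        self.marker = marker
        self.candidates = candidates

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, model_id: int = 1,
                       **kw) -> "OutcomeModel":
        return cls(data, model_id=model_id, **kw)

    def fit(self) -> OutcomeResults:
        res = hierarchical_regression(
            self.data, self.model_id, outcome=self.outcome,
            marker=self.marker, candidates=self.candidates)
        return OutcomeResults(self, res)


class OddballStudy:
    """A full simulated oddball study as a fittable model: construct
    from a :class:`RunConfig` (or keyword overrides), call ``fit()`` to
    simulate, preprocess, measure and analyse; the returned
    :class:`StudyResults` carries tables, ANOVA/regression results and
    ``summary()``."""

    def __init__(self, config: RunConfig | None = None, **overrides):
        if config is None:
            config = RunConfig(**overrides)
        self.config = config

    @classmethod
    def from_yaml(cls, path) -> "OddballStudy":
        return cls(RunConfig.from_yaml(path))

    def fit(self, write: bool = False) -> StudyResults:
        return run_pipeline(self.config, write=write)
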