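"""Scikit-learn-style estimator wrapping the per-type error-model fitting.

``RareVariantDetector.fit`` consumes a normal-panel matrix of per-100k read
error rates (samples x substitution types) and fits one null model per type;
``predict`` flags anomalies — observed events per 100,000 reads at or above
each type's threshold — in new samples.  The estimator composes with sklearn
tooling (``get_params``/``set_params``, ``fit`` returning ``self``, fitted
attributes with trailing underscores).
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .error_model import (
    ALPHA_DEFAULT,
    RATIO_CUTOFF_DEFAULT,
    ErrorModel,
    ErrorPanelMatrix,
    fit_type,
)

__all__ = ["RareVariantDetector", "build_models"]


class RareVariantDetector(BaseEstimator):
    """Anomaly detector for rare variants against panel-of-normals error rates.

    Parameters
    ----------
    alpha:
        Per-test significance level for each single detection (default 2e-5,
        i.e. one expected false positive per 50,000 tests); no multiplicity
        correction unless ``bonferroni=True``.
    ratio_cutoff:
        Variance/mean ratio above which the negative binomial replaces the
        Poisson (default 1.2).
    ddof:
        Delta degrees of freedom for the panel variance; 0 is the
        method-of-moments (population) convention.
    excluded_types:
        Type labels withheld from fitting (known germline SNPs).  When
        fitting from an :class:`ErrorPanelMatrix` its own exclusion list is
        used instead.
    bonferroni:
        Divide alpha by the number of fitted types (off by default, matching
        the per-test convention).

    Attributes
    ----------
    models_ : dict[str, ErrorModel]
        Fitted null model per type label.
    thresholds_ : pandas.Series
        Calling threshold (events per 100,000 reads) per type.
    category_counts_ : dict[str, int]
        Number of types per model family.
    feature_names_in_ : ndarray of type labels seen during fit.
    """

    def __init__(
        self,
        alpha: float = ALPHA_DEFAULT,
        ratio_cutoff: float = RATIO_CUTOFF_DEFAULT,
        ddof: int = 0,
        excluded_types: tuple[str, ...] | None = None,
        bonferroni: bool = False,
    ):
        self.alpha = alpha
        self.ratio_cutoff = ratio_cutoff
        self.ddof = ddof
        self.excluded_types = excluded_types
        self.bonferroni = bonferroni

    # ------------------------------------------------------------------ fit
    def _coerce_panel(self, X) -> pd.DataFrame:
        """Return a samples x types DataFrame of per-100k rates."""
        if isinstance(X, ErrorPanelMatrix):
            return X.fitting_rates().T
        if isinstance(X, pd.DataFrame):
            frame = X
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be a 2-D samples x types matrix")
            frame = pd.DataFrame(
                arr, columns=[f"type_{j}" for j in range(arr.shape[1])]
            )
        excluded = set(self.excluded_types or ())
        keep = [c for c in frame.columns if c not in excluded]
        return frame[keep]

    def fit(self, X, y=None) -> "RareVariantDetector":
        """Fit one null error model per substitution type.

        ``X`` is an :class:`ErrorPanelMatrix` or a samples x types matrix of
        events per 100,000 reads (rows = panel samples).
        """
        frame = self._coerce_panel(X)
        if frame.shape[1] == 0:
            raise ValueError("no substitution types left to fit")
        if np.isnan(frame.to_numpy()).any():
            raise ValueError("panel rates contain missing values")
        alpha = self.alpha / frame.shape[1] if self.bonferroni else self.alpha
        models: dict[str, ErrorModel] = {}
        for label in frame.columns:
            models[str(label)] = fit_type(
                frame[label].to_numpy(),
                alpha=alpha,
                ratio_cutoff=self.ratio_cutoff,
                ddof=self.ddof,
            )
        self.models_ = models
        self.thresholds_ = pd.Series(
            {lab: m.threshold for lab, m in models.items()}, name="threshold"
        )
        self.category_counts_ = dict(Counter(m.kind for m in models.values()))
        self.feature_names_in_ = np.asarray(list(frame.columns), dtype=object)
        self.n_features_in_ = frame.shape[1]
        self.effective_alpha_ = alpha
        return self

    # -------------------------------------------------------------- predict
    def _coerce_events(self, X) -> pd.DataFrame:
        check_is_fitted(self, "models_")
        if isinstance(X, pd.Series):
            X = X.to_frame().T
        if isinstance(X, pd.DataFrame):
            missing = [c for c in X.columns if str(c) not in self.models_]
            if missing:
                raise ValueError(f"no fitted model for types: {missing[:5]}")
            return X
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        if arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {arr.shape[1]} columns, expected {self.n_features_in_}"
            )
        return pd.DataFrame(arr, columns=self.feature_names_in_)

    def decision_function(self, X) -> pd.DataFrame:
        """Observed events per 100,000 reads minus the type's threshold."""
        frame = self._coerce_events(X)
        thresholds = np.array([self.models_[str(c)].threshold for c in frame.columns])
        return frame - thresholds

    def predict(self, X) -> pd.DataFrame:
        """Boolean anomaly matrix: events per 100,000 reads >= threshold."""
        return self.decision_function(X) >= 0

    def tail_probability(self, X) -> pd.DataFrame:
        """Realized upper-tail probability P(X >= observed) per cell, with the
        observed events per 100,000 reads rounded up to the next integer."""
        frame = self._coerce_events(X)
        out = frame.copy().astype(float)
        for c in frame.columns:
            model = self.models_[str(c)]
            out[c] = [model.tail_geq(int(np.ceil(v))) for v in frame[c]]
        return out

    # ------------------------------------------------------------ reporting
    def summary(self) -> pd.DataFrame:
        """One row per fitted type: family, parameters, moments, threshold."""
        check_is_fitted(self, "models_")
        rows = []
        for label, m in self.models_.items():
            rows.append(
                {
                    "type": label,
                    "kind": m.kind,
                    "lambda": m.lam,
                    "r": m.r,
                    "p": m.p,
                    "mean": m.mean,
                    "variance": m.variance,
                    "ratio": (m.variance / m.mean) if m.mean > 0 else np.nan,
                    "threshold": m.threshold,
                    "realized_size": m.realized_size,
                }
            )
        return pd.DataFrame(rows).set_index("type")


def build_models(
    panel: ErrorPanelMatrix,
    alpha: float = ALPHA_DEFAULT,
    ratio_cutoff: float = RATIO_CUTOFF_DEFAULT,
    ddof: int = 0,
    bonferroni: bool = False,
) -> tuple[dict[str, ErrorModel], dict[str, int]]:
    """Fit all per-type models from a normal panel.

    Thin wrapper over :class:`RareVariantDetector`; returns the label ->
    model map and the per-family category counts.
    """
    det = RareVariantDetector(
        alpha=alpha, ratio_cutoff=ratio_cutoff, ddof=ddof, bonferroni=bonferroni
    ).fit(panel)
    return det.models_, det.category_counts_
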