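"""High-level scikit-learn-style estimator tying the pipeline together.

``CoregulatoryNetworkClassifier`` runs the full workflow: candidate
filtering against the four-engine panel, structural and functional
scoring, hierarchy construction, and CLG model fitting on the top
``n_con`` interactions. After :meth:`fit`, ``connections_`` holds the
full scored hierarchy and :meth:`get_network` materialises the fitted
network for inspection.

Example
-------
>>> from coremir import synthetic
>>> from coremir.estimator import CoregulatoryNetworkClassifier
>>> spec = synthetic.make_spec(seed=7)
>>> panel, _ = synthetic.make_panel(spec)
>>> data = synthetic.sample_expression(spec)
>>> clf = CoregulatoryNetworkClassifier(engines=panel, n_con=5)
>>> clf.fit(data.matrix, data.class_vector)          # doctest: +ELLIPSIS
CoregulatoryNetworkClassifier(...)
>>> clf.predict(data.matrix).shape
(600,)
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import clg
from .engines_io import EngineTable, ExpressionDataset, build_candidate_pool
from .functional import CmiConfig, functional_scores
from .hierarchy import build_hierarchy
from .structural import build_consistency_matrix, structural_scores


class CoregulatoryNetworkClassifier(BaseEstimator, ClassifierMixin):
    """miRNA-mRNA coregulatory network classifier.

    Parameters
    ----------
    engines:
        Four-engine panel of :class:`~coremir.engines_io.EngineTable`.
    n_con:
        Number of top-ranked interactions in the fitted network.
    precision:
        Grid resolution for the conditional-mutual-information
        estimation.
    mode, weight, ties:
        Hierarchy construction settings; ``weight`` is the structural
        share in ``weighted`` mode.
    feature_roles:
        Optional explicit mapping feature -> {"mirna", "mrna"}; by
        default roles are inferred from the ``hsa-`` prefix.
    """

    def __init__(
        self,
        engines: Sequence[EngineTable] | None = None,
        n_con: int = 10,
        precision: int = 100,
        mode: str = "alternative",
        weight: float = 0.5,
        ties: str = "isolated",
        feature_roles: dict[str, str] | None = None,
    ) -> None:
        self.engines = engines
        self.n_con = n_con
        self.precision = precision
        self.mode = mode
        self.weight = weight
        self.ties = ties
        self.feature_roles = feature_roles

    # -- helpers ---------------------------------------------------------

    def _dataset(self, X: pd.DataFrame, y: np.ndarray | None) -> ExpressionDataset:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with named miRNA/mRNA columns")
        if self.feature_roles is not None:
            roles = pd.Series({c: self.feature_roles[c] for c in X.columns})
        else:
            roles = pd.Series(
                ["mirna" if str(c).lower().startswith("hsa-") else "mrna" for c in X.columns],
                index=X.columns,
            )
        if y is None:
            y = np.zeros(len(X), dtype=int)
        return ExpressionDataset(matrix=X, feature_roles=roles, class_vector=np.asarray(y))

    # -- estimator API ---------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "CoregulatoryNetworkClassifier":
        if self.engines is None:
            raise ValueError("engines panel is required for fitting")
        y = np.asarray(y, dtype=int)
        data = self._dataset(X, y)
        self.pool_ = build_candidate_pool(data, self.engines)
        self.cmatrix_ = build_consistency_matrix(self.engines)
        si = structural_scores(self.pool_, self.cmatrix_)
        cfg = CmiConfig(precision=self.precision)
        fi = functional_scores(data, self.pool_, si, cfg)
        self.ranking_ = build_hierarchy(
            self.pool_, si, fi, mode=self.mode, weight=self.weight, ties=self.ties
        )
        k = min(self.n_con, len(self.ranking_))
        self.topology_ = clg.build_topology(self.ranking_, k)
        self.params_ = clg.fit_parameters(self.topology_, data)
        self.classes_ = np.array(self.params_.classes)
        return self

    @property
    def connections_(self) -> pd.DataFrame:
        """Scored interaction hierarchy (available after fit)."""
        self._check_fitted()
        return self.ranking_.to_frame()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return clg.predict_proba(self.params_, self.topology_, X)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return clg.predict(self.params_, self.topology_, X)

    def get_network(self, metadata: dict | None = None):
        """Annotated bipartite graph document of the fitted network."""
        from .export import build_document

        self._check_fitted()
        return build_document(self.topology_, self.ranking_, metadata)

    def _check_fitted(self) -> None:
        if not hasattr(self, "ranking_"):
            raise RuntimeError("estimator is not fitted; call fit(X, y) first")
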