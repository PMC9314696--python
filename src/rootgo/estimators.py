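"""Scikit-learn style estimators wrapping the package's three
fit/predict-shaped operations.

* :class:`GoSemanticClustering` — agglomerative clustering of genes by GO
  semantic distance (a :class:`~sklearn.base.ClusterMixin`: ``fit`` exposes
  ``labels_``);
* :class:`TrendClassifier` — rule-based assignment of root expression-trend
  groups from an :class:`~rootgo.expression.ExpressionStudy`;
* :class:`RootTypeClassifier` — the dual-marker qPCR root-type caller
  (``fit`` freezes the calibrator Cts, ``predict`` calls roots).

All three follow the estimator contract (``get_params``/``set_params``,
trailing-underscore fitted attributes, ``sklearn.clone`` compatibility) so
they compose with sklearn model-selection utilities; the module-level
functions in :mod:`rootgo.semantic_clustering`, :mod:`rootgo.expression`
and :mod:`rootgo.marker_stats` are thin wrappers over the same code paths.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.exceptions import NotFittedError

from . import expression, marker_stats, semantic_clustering
from .ontology import AnnotationSet, OntologyGraph


def _check_fitted(est, attrs):
    for a in attrs:
        if not hasattr(est, a):
            raise NotFittedError(
                f"{type(est).__name__} is not fitted yet; call fit first"
            )


class GoSemanticClustering(ClusterMixin, BaseEstimator):
    """Average-linkage clustering of genes by closest-common-parent distance.

    Parameters
    ----------
    graph, annotations:
        The ontology and the (unpropagated) gene annotations.
    namespace:
        Ontology namespace to cluster within.
    theta:
        Cut height of the dendrogram, in ccp hops.
    aggregation:
        ``"best_pair"`` (minimum over term pairs) or ``"best_match_average"``.
    coverage_fraction:
        Minimum fraction of member genes a head term must cover.

    Attributes
    ----------
    labels_ : ndarray of shape (n_genes,)
        Cluster index per input gene; -1 for genes without annotations in
        the namespace.
    clusters_ : list of GeneCluster
    unannotated_ : list of str
    """

    def __init__(
        self,
        graph: OntologyGraph = None,
        annotations: AnnotationSet = None,
        namespace: str = "biological_process",
        theta: float = 4.0,
        aggregation: str = "best_pair",
        coverage_fraction: float = 1.0,
    ):
        self.graph = graph
        self.annotations = annotations
        self.namespace = namespace
        self.theta = theta
        self.aggregation = aggregation
        self.coverage_fraction = coverage_fraction

    def fit(self, X, y=None):
        """Cluster a sequence of gene identifiers."""
        if self.graph is None or self.annotations is None:
            raise ValueError("graph and annotations must be provided")
        genes = [str(g) for g in X]
        result = semantic_clustering.cluster_genes(
            self.annotations,
            self.graph,
            genes,
            self.namespace,
            theta=self.theta,
            aggregation=self.aggregation,
            coverage_fraction=self.coverage_fraction,
        )
        self.clusters_ = result.clusters
        self.unannotated_ = result.unannotated
        label_of = {
            g: i for i, c in enumerate(result.clusters) for g in c.genes
        }
        self.labels_ = np.array([label_of.get(g, -1) for g in genes])
        self.n_clusters_ = len(result.clusters)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class TrendClassifier(BaseEstimator):
    """Root expression-trend classifier (FR_UP / SR_D / SR_EQ / SR_UP).

    ``fit`` stores the study; ``predict`` classifies gene identifiers by
    the dominance-then-signed-R^2 rule of
    :func:`rootgo.expression.classify_trend`.
    """

    def __init__(self, threshold: float = expression.SIGNED_R2_THRESHOLD):
        self.threshold = threshold

    def fit(self, X: expression.ExpressionStudy, y=None):
        if not isinstance(X, expression.ExpressionStudy):
            raise TypeError("TrendClassifier.fit expects an ExpressionStudy")
        self.study_ = X
        return self

    def predict(self, genes) -> np.ndarray:
        _check_fitted(self, ["study_"])
        return np.array([
            expression.classify_trend(self.study_, g, self.threshold).group
            for g in genes
        ])

    def calls(self, genes) -> list[expression.TrendCall]:
        _check_fitted(self, ["study_"])
        return [
            expression.classify_trend(self.study_, g, self.threshold)
            for g in genes
        ]


class RootTypeClassifier(BaseEstimator):
    """Dual-marker qPCR root-type caller.

    ``fit`` computes the per-gene calibrator Cts from a training
    :class:`~rootgo.marker_stats.QpcrTable`; ``predict`` returns PFR/PSR/
    ambiguous calls for each (plant, root) of a table against those frozen
    calibrators.
    """

    def __init__(
        self,
        marker_fr: str = marker_stats.MARKER_FR,
        marker_sr: str = marker_stats.MARKER_SR,
        reference: str = marker_stats.REFERENCE_GENE,
        tau: float = 0.0,
        calibrator: str = "global_mean",
    ):
        self.marker_fr = marker_fr
        self.marker_sr = marker_sr
        self.reference = reference
        self.tau = tau
        self.calibrator = calibrator

    def fit(self, X: marker_stats.QpcrTable, y=None):
        if not isinstance(X, marker_stats.QpcrTable):
            raise TypeError("RootTypeClassifier.fit expects a QpcrTable")
        genes = (self.marker_fr, self.marker_sr, self.reference)
        cal = {g: X.calibrator_ct(g) for g in genes}
        if self.calibrator == "pfr_mean":
            provisional = marker_stats.call_all_roots(
                X, self.marker_fr, self.marker_sr, self.reference,
                self.tau, cal,
            )
            pfr = [(c.plant_id, c.root_id) for c in provisional
                   if c.call == "PFR"]
            if pfr:
                cal = {g: X.calibrator_ct(g, pfr) for g in genes}
        elif self.calibrator != "global_mean":
            raise ValueError(f"unknown calibrator mode {self.calibrator!r}")
        self.calibrator_ct_ = cal
        return self

    def calls(self, X: marker_stats.QpcrTable) -> list[marker_stats.RootTypeCall]:
        _check_fitted(self, ["calibrator_ct_"])
        return marker_stats.call_all_roots(
            X, self.marker_fr, self.marker_sr, self.reference,
            self.tau, self.calibrator_ct_,
        )

    def predict(self, X: marker_stats.QpcrTable) -> np.ndarray:
        return np.array([c.call for c in self.calls(X)])

    def decision_function(self, X: marker_stats.QpcrTable) -> np.ndarray:
        """Per-root log2 marker ratio (positive leans PFR)."""
        return np.array([c.log2_ratio for c in self.calls(X)])
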