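"""K-nearest-neighbor linking of query spectra to gene cluster families.

The training matrix holds one fingerprint row per BGC, labelled with its GCF.
A query MS/MS fingerprint is placed in the same feature space and its k
nearest BGC rows are retrieved; the ordered sequence of their GCF labels —
repetitions preserved, since several neighbors often belong to the same
family — is the prediction (the true label counting as found if it appears
among the first n labels).  A Jaccard co-occurrence index between the
binarized query and neighbor fingerprints acts as a confidence filter: a
link is retained only when some neighbor shares at least the threshold
fraction of its presence/absence pattern with the query, i.e. when the
metabolite is found among the same samples that contain the candidate BGCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin

from .fingerprints import binarize

__all__ = [
    "LinkerConfig",
    "NeighborHit",
    "LinkResult",
    "GCFLinkClassifier",
    "knn_link",
    "jaccard_index",
    "apply_cooccurrence_filter",
    "link_dataset",
    "write_results",
]

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock", "cosine-distance": "cosine"}


@dataclass(frozen=True)
class LinkerConfig:
    """KNN and filter parameters (k >= 1; threshold in [0, 1])."""

    k: int = 3
    distance_metric: str = "euclidean"
    jaccard_threshold: float = 0.7
    apply_threshold: bool = True
    jaccard_scope: str = "all-features"
    similarity_cutoff: float = 0.7

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.distance_metric not in _METRICS:
            raise ValueError(f"unknown distance metric {self.distance_metric!r}")
        if not 0.0 <= self.jaccard_threshold <= 1.0:
            raise ValueError("jaccard_threshold must be in [0, 1]")
        if self.jaccard_scope not in ("all-features", "strains-only"):
            raise ValueError(f"unknown jaccard scope {self.jaccard_scope!r}")


@dataclass(frozen=True)
class NeighborHit:
    """One training BGC retrieved as a nearest neighbor."""

    bgc_id: str
    gcf_label: str
    distance: float
    jaccard: float = float("nan")


@dataclass
class LinkResult:
    """Ranked GCF candidates for one query spectrum."""

    spectrum_id: str
    neighbors: list[NeighborHit] = field(default_factory=list)
    retained: bool = True

    @property
    def ranked_gcfs(self) -> list[str]:
        """Neighbor GCF labels nearest-first, repetitions preserved."""
        return [n.gcf_label for n in self.neighbors]


def jaccard_index(
    a: np.ndarray | pd.Series,
    b: np.ndarray | pd.Series,
    cutoff: float = 0.7,
    scope: str = "all-features",
    n_similarity_columns: int | None = None,
) -> float:
    """Jaccard co-occurrence index of two fingerprints.

    Both fingerprints are binarized at ``cutoff`` and the index is
    |intersection| / |union| of their presence bits.  ``scope`` selects all
    feature columns (similarities plus class/substructure bits, the default)
    or the strain similarity columns only; two all-zero patterns score 0.
    """
    ba = binarize(np.asarray(a, dtype=float), cutoff, n_similarity_columns) > 0
    bb = binarize(np.asarray(b, dtype=float), cutoff, n_similarity_columns) > 0
    if scope == "strains-only":
        n = n_similarity_columns if n_similarity_columns is not None else ba.shape[-1]
        ba, bb = ba[..., :n], bb[..., :n]
    elif scope != "all-features":
        raise ValueError(f"unknown jaccard scope {scope!r}")
    union = int(np.sum(ba | bb))
    if union == 0:
        return 0.0
    return int(np.sum(ba & bb)) / union


class GCFLinkClassifier(ClassifierMixin, BaseEstimator):
    """KNN classifier from MS/MS fingerprints to gene cluster families.

    Parameters
    ----------
    n_neighbors : int
        Number of BGC neighbors to retrieve (k, default 3).
    metric : str
        ``"euclidean"`` (default), ``"manhattan"`` or ``"cosine-distance"``.
    jaccard_threshold : float
        Co-occurrence confidence cutoff, default 0.7.
    apply_threshold : bool
        When True, queries whose neighbors all fall below the threshold are
        flagged not retained (excluded from precision denominators).
    jaccard_scope : str
        ``"all-features"`` or ``"strains-only"``.
    similarity_cutoff : float
        Binarization cutoff used by the Jaccard index, default 0.7.

    Ties in distance are broken by ascending bgc_id.  ``predict`` returns the
    top-1 family per query for scikit-learn compatibility; :meth:`link`
    returns the full ranked results.
    """

    def __init__(
        self,
        n_neighbors: int = 3,
        metric: str = "euclidean",
        jaccard_threshold: float = 0.7,
        apply_threshold: bool = True,
        jaccard_scope: str = "all-features",
        similarity_cutoff: float = 0.7,
    ) -> None:
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.jaccard_threshold = jaccard_threshold
        self.apply_threshold = apply_threshold
        self.jaccard_scope = jaccard_scope
        self.similarity_cutoff = similarity_cutoff

    def fit(self, X: pd.DataFrame, y: Sequence[str], n_similarity_columns: int | None = None):
        """Store the training matrix.

        ``X`` is the BGC fingerprint matrix indexed by bgc_id; ``y`` the
        row-aligned GCF labels; ``n_similarity_columns`` how many leading
        columns are similarity (strain) columns (default: all of them).
        """
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.metric not in _METRICS:
            raise ValueError(f"unknown distance metric {self.metric!r}")
        if len(X) != len(y):
            raise ValueError("X and y must be row-aligned")
        order = np.argsort(np.asarray(X.index, dtype=object), kind="stable")
        self.X_ = np.asarray(X, dtype=float)[order]
        self.ids_ = np.asarray(X.index, dtype=object)[order]
        self.labels_ = np.asarray(y, dtype=object)[order]
        self.columns_ = tuple(X.columns)
        self.classes_ = np.unique(self.labels_)
        self.n_features_in_ = len(self.columns_)
        self.n_similarity_columns_ = (
            n_similarity_columns if n_similarity_columns is not None else len(self.columns_)
        )
        return self

    def _check_query(self, X: pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            for i, (qc, tc) in enumerate(zip(X.columns, self.columns_)):
                if qc != tc:
                    raise ValueError(
                        f"feature-space mismatch at column {i}: query {qc!r} vs training {tc!r}"
                    )
            if len(X.columns) != len(self.columns_):
                raise ValueError(
                    f"feature-space mismatch: query has {len(X.columns)} columns, "
                    f"training has {len(self.columns_)}"
                )
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {arr.shape[1]} features, training has {self.n_features_in_}"
            )
        return arr

    def kneighbors(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Distances and training-row indices of the k nearest BGCs per query."""
        arr = self._check_query(X)
        d = cdist(arr, self.X_, metric=_METRICS[self.metric])
        k = min(self.n_neighbors, self.X_.shape[0])
        # stable argsort on rows sorted by bgc_id == tie-break by ascending bgc_id
        idx = np.argsort(d, axis=1, kind="stable")[:, :k]
        return np.take_along_axis(d, idx, axis=1), idx

    def link(self, X: pd.DataFrame) -> list[LinkResult]:
        """Full ranked link results, with Jaccard scores and retention flags."""
        arr = self._check_query(X)
        ids = (
            [str(i) for i in X.index]
            if isinstance(X, pd.DataFrame)
            else [f"query_{i}" for i in range(arr.shape[0])]
        )
        dists, idx = self.kneighbors(arr)
        results = []
        for r, sid in enumerate(ids):
            all_zero = not np.any(arr[r])
            hits = []
            any_pass = False
            for dist, t in zip(dists[r], idx[r]):
                jac = jaccard_index(
                    arr[r],
                    self.X_[t],
                    cutoff=self.similarity_cutoff,
                    scope=self.jaccard_scope,
                    n_similarity_columns=self.n_similarity_columns_,
                )
                any_pass = any_pass or jac >= self.jaccard_threshold
                hits.append(
                    NeighborHit(
                        bgc_id=str(self.ids_[t]),
                        gcf_label=str(self.labels_[t]),
                        distance=float(dist),
                        jaccard=jac,
                    )
                )
            if all_zero:
                warnings.warn(
                    f"query {sid!r} has an all-zero fingerprint: no co-occurrence "
                    "evidence; link not retained"
                )
                retained = False
            elif self.apply_threshold:
                retained = any_pass
            else:
                retained = True
            results.append(LinkResult(spectrum_id=sid, neighbors=hits, retained=retained))
        return results

    def predict(self, X) -> np.ndarray:
        """Top-1 GCF label per query."""
        _, idx = self.kneighbors(X)
        return self.labels_[idx[:, 0]]


def knn_link(
    query: pd.Series | np.ndarray,
    training: pd.DataFrame,
    labels: Sequence[str],
    cfg: LinkerConfig | None = None,
    spectrum_id: str = "query",
    n_similarity_columns: int | None = None,
) -> LinkResult:
    """Rank the k nearest training BGCs for one query fingerprint.

    Returns a :class:`LinkResult` without the co-occurrence filter applied
    (all neighbor Jaccard scores are computed; ``retained`` reflects only the
    all-zero-query rule).  Apply :func:`apply_cooccurrence_filter` for the
    filtered result.
    """
    cfg = cfg or LinkerConfig()
    clf = _classifier(cfg).fit(training, labels, n_similarity_columns=n_similarity_columns)
    clf.apply_threshold = False
    frame = _as_frame(query, training.columns, spectrum_id)
    return clf.link(frame)[0]


def _classifier(cfg: LinkerConfig) -> GCFLinkClassifier:
    return GCFLinkClassifier(
        n_neighbors=cfg.k,
        metric=cfg.distance_metric,
        jaccard_threshold=cfg.jaccard_threshold,
        apply_threshold=cfg.apply_threshold,
        jaccard_scope=cfg.jaccard_scope,
        similarity_cutoff=cfg.similarity_cutoff,
    )


def _as_frame(query, columns, spectrum_id: str) -> pd.DataFrame:
    if isinstance(query, pd.Series):
        return query.to_frame(name=spectrum_id).T[list(columns)]
    return pd.DataFrame(np.asarray(query, dtype=float)[None, :], index=[spectrum_id], columns=columns)


def apply_cooccurrence_filter(
    result: LinkResult, cfg: LinkerConfig | None = None
) -> LinkResult:
    """Set ``retained`` from the neighbors' Jaccard co-occurrence scores.

    Retained iff any neighbor's Jaccard index reaches the threshold; when the
    threshold is not applied every result stays retained (except those already
    flagged for an all-zero query).
    """
    cfg = cfg or LinkerConfig()
    if not result.retained and not result.neighbors:
        return result
    if not cfg.apply_threshold:
        return result
    any_pass = any(n.jaccard >= cfg.jaccard_threshold for n in result.neighbors)
    return LinkResult(
        spectrum_id=result.spectrum_id,
        neighbors=result.neighbors,
        retained=result.retained and any_pass,
    )


def link_dataset(
    queries: pd.DataFrame,
    training: pd.DataFrame,
    labels: Sequence[str],
    cfg: LinkerConfig | None = None,
    n_similarity_columns: int | None = None,
) -> list[LinkResult]:
    """Link every query fingerprint; results ordered by spectrum_id."""
    cfg = cfg or LinkerConfig()
    if len(queries) == 0:
        return []
    clf = _classifier(cfg).fit(training, labels, n_similarity_columns=n_similarity_columns)
    ordered = queries.loc[sorted(queries.index, key=str)]
    return clf.link(ordered)


def write_results(results: Sequence[LinkResult], path) -> None:
    """Write link results as TSV: one row per (query, neighbor rank)."""
    rows = []
    for r in results:
        for rank, n in enumerate(r.neighbors, start=1):
            rows.append(
                {
                    "spectrum_id": r.spectrum_id,
                    "rank": rank,
                    "bgc_id": n.bgc_id,
                    "gcf_label": n.gcf_label,
                    "distance": n.distance,
                    "jaccard": n.jaccard,
                    "retained": r.retained,
                }
            )
    pd.DataFrame(
        rows,
        columns=["spectrum_id", "rank", "bgc_id", "gcf_label", "distance", "jaccard", "retained"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
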