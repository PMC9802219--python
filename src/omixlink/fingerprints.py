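"""Similarity fingerprints for BGCs and MS/MS spectra.

A fingerprint is a feature vector indexed by the dataset's samples: for a
BGC, each sample column holds the maximum pairwise similarity between the BGC
and the BGCs of that genome; for an MS/MS spectrum, the maximum modified
cosine score against the spectra of that sample's metabolome.  Values below
the similarity cutoff (default 0.7) are set to 0 — a sub-cutoff score means
the cluster/metabolite is likely absent from that sample — so nonzero
similarity entries lie in [0.7, 1.0] and zeros encode absence (dense vectors,
as the KNN distance requires).  Optional binary blocks append
biosynthetic-class and substructure presence/absence features.

BGC fingerprints form the training matrix (rows labelled with GCFs); spectrum
fingerprints, built over the same sample columns, form the query matrix.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .network import BgcRecord, SimilarityTable
from .similarity import CosineParams, max_cosine_to_metabolome
from .spectra import Metabolome, Spectrum

__all__ = [
    "DEFAULT_CLASS_VOCABULARY",
    "FeatureSpace",
    "FingerprintConfig",
    "BgcFingerprinter",
    "SpectrumFingerprinter",
    "bgc_fingerprint",
    "spectrum_fingerprint",
    "assemble_training_matrix",
    "binarize",
    "read_feature_table",
    "write_matrix",
    "read_matrix",
]

# Default biosynthetic-class vocabulary (12 columns). Hybrid clusters set the
# bit of every constituent class (a PKS/NRPS hybrid is 1 in both PKS and NRPS);
# combinations not reducible to the named classes use "hybrid-other".
DEFAULT_CLASS_VOCABULARY: tuple[str, ...] = (
    "PKS",
    "NRPS",
    "terpene",
    "siderophore",
    "RiPP",
    "phosphonate",
    "oligosaccharide",
    "phenolic",
    "other",
    "minor",
    "unknown",
    "hybrid-other",
)


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered column layout shared by training and query matrices."""

    sample_columns: tuple[str, ...]
    class_columns: tuple[str, ...] = ()
    substructure_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cols = self.columns
        if len(cols) != len(set(cols)):
            raise ValueError("feature-space column names must be unique")

    @property
    def columns(self) -> tuple[str, ...]:
        return self.sample_columns + self.class_columns + self.substructure_columns

    @property
    def n_samples(self) -> int:
        return len(self.sample_columns)

    @property
    def width(self) -> int:
        return len(self.columns)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "sample_columns": list(self.sample_columns),
                    "class_columns": list(self.class_columns),
                    "substructure_columns": list(self.substructure_columns),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "FeatureSpace":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tuple(d["sample_columns"]),
            tuple(d.get("class_columns", ())),
            tuple(d.get("substructure_columns", ())),
        )


@dataclass(frozen=True)
class FingerprintConfig:
    """Fingerprint construction options.

    ``apply_cutoff_to_spectra`` controls whether spectral similarity columns
    are zeroed below the cutoff like BGC columns are (default yes: query
    fingerprints carry the same kind of features as training ones).
    """

    similarity_cutoff: float = 0.7
    use_class_features: bool = False
    use_substructure_features: bool = False
    apply_cutoff_to_spectra: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.similarity_cutoff <= 1.0:
            raise ValueError("similarity_cutoff must be in (0, 1]")


def _feature_bits(names: Iterable[str], vocabulary: Sequence[str]) -> np.ndarray:
    present = set(names)
    return np.array([1.0 if v in present else 0.0 for v in vocabulary])


class BgcFingerprinter(TransformerMixin, BaseEstimator):
    """Build BGC similarity fingerprints over the dataset's genomes.

    Parameters
    ----------
    similarity_cutoff : float
        Similarity values below this are set to 0 (absence). Default 0.7.
    use_class_features, use_substructure_features : bool
        Append binary presence/absence blocks from each record's annotation
        sets.
    class_vocabulary, substructure_vocabulary : sequence of str or None
        Column vocabularies for the binary blocks; the class vocabulary
        defaults to :data:`DEFAULT_CLASS_VOCABULARY`.

    After ``fit`` the transformer exposes ``feature_space_``, ``genomes_``
    (genome_id -> member bgc_ids) and ``similarities_``.
    """

    def __init__(
        self,
        similarity_cutoff: float = 0.7,
        use_class_features: bool = False,
        use_substructure_features: bool = False,
        class_vocabulary: Sequence[str] | None = None,
        substructure_vocabulary: Sequence[str] | None = None,
    ) -> None:
        self.similarity_cutoff = similarity_cutoff
        self.use_class_features = use_class_features
        self.use_substructure_features = use_substructure_features
        self.class_vocabulary = class_vocabulary
        self.substructure_vocabulary = substructure_vocabulary

    def _vocabularies(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        classes = (
            tuple(self.class_vocabulary)
            if self.class_vocabulary is not None
            else DEFAULT_CLASS_VOCABULARY
        ) if self.use_class_features else ()
        subs = (
            tuple(self.substructure_vocabulary or ())
            if self.use_substructure_features
            else ()
        )
        return classes, subs

    def fit(
        self,
        X: Sequence[BgcRecord],
        y=None,
        similarities: SimilarityTable | None = None,
        sample_columns: Sequence[str] | None = None,
    ):
        if similarities is None:
            raise ValueError("BgcFingerprinter.fit requires similarities=")
        if not 0.0 < self.similarity_cutoff <= 1.0:
            raise ValueError("similarity_cutoff must be in (0, 1]")
        genomes: dict[str, list[str]] = {}
        for rec in X:
            genomes.setdefault(rec.genome_id, []).append(rec.bgc_id)
        if sample_columns is not None:
            # allow genomes without any BGC (their columns warn and stay 0)
            for g in sample_columns:
                genomes.setdefault(g, [])
            columns = tuple(sample_columns)
        else:
            columns = tuple(sorted(genomes))
        classes, subs = self._vocabularies()
        self.genomes_ = {g: sorted(members) for g, members in genomes.items()}
        self.similarities_ = similarities
        self.feature_space_ = FeatureSpace(
            sample_columns=columns,
            class_columns=classes,
            substructure_columns=subs,
        )
        self.n_features_in_ = self.feature_space_.width
        return self

    def transform(self, X: Sequence[BgcRecord]) -> pd.DataFrame:
        """Fingerprint each BGC record; rows indexed by bgc_id."""
        space: FeatureSpace = self.feature_space_
        sims = self.similarities_
        cutoff = self.similarity_cutoff
        rows = np.zeros((len(X), space.width))
        ids = []
        n_samples = space.n_samples
        for i, rec in enumerate(X):
            if rec.genome_id not in self.genomes_:
                raise ValueError(
                    f"BGC {rec.bgc_id!r}: genome {rec.genome_id!r} is not a sample column"
                )
            for j, genome in enumerate(space.sample_columns):
                members = self.genomes_.get(genome, [])
                if not members:
                    warnings.warn(f"genome {genome!r} has zero BGCs; column set to 0")
                    continue
                best = max(sims.get(rec.bgc_id, other) for other in members)
                rows[i, j] = best if best >= cutoff else 0.0
            k = n_samples
            if space.class_columns:
                rows[i, k : k + len(space.class_columns)] = _feature_bits(
                    rec.classes, space.class_columns
                )
                k += len(space.class_columns)
            if space.substructure_columns:
                rows[i, k:] = _feature_bits(rec.substructures, space.substructure_columns)
            ids.append(rec.bgc_id)
        return pd.DataFrame(rows, index=pd.Index(ids, name="owner_id"), columns=space.columns)


class SpectrumFingerprinter(TransformerMixin, BaseEstimator):
    """Build MS/MS fingerprints over the dataset's metabolomes.

    The sample columns must be the same, in the same order, as the BGC
    training matrix; pass the fitted :class:`BgcFingerprinter`'s
    ``feature_space_`` (or its sample columns) to ``fit`` to guarantee this.
    """

    def __init__(
        self,
        similarity_cutoff: float = 0.7,
        apply_cutoff: bool = True,
        fragment_tolerance: float = 0.1,
        min_matched_peaks: int = 1,
        intensity_power: float = 0.5,
        use_class_features: bool = False,
        use_substructure_features: bool = False,
        class_vocabulary: Sequence[str] | None = None,
        substructure_vocabulary: Sequence[str] | None = None,
    ) -> None:
        self.similarity_cutoff = similarity_cutoff
        self.apply_cutoff = apply_cutoff
        self.fragment_tolerance = fragment_tolerance
        self.min_matched_peaks = min_matched_peaks
        self.intensity_power = intensity_power
        self.use_class_features = use_class_features
        self.use_substructure_features = use_substructure_features
        self.class_vocabulary = class_vocabulary
        self.substructure_vocabulary = substructure_vocabulary

    def fit(
        self,
        X: Mapping[str, Metabolome],
        y=None,
        feature_space: FeatureSpace | None = None,
    ):
        sample_columns = (
            feature_space.sample_columns
            if feature_space is not None
            else tuple(sorted(X))
        )
        missing = [s for s in sample_columns if s not in X]
        if missing:
            raise ValueError(f"no metabolome supplied for sample column(s) {missing}")
        classes = (
            tuple(self.class_vocabulary)
            if self.class_vocabulary is not None
            else DEFAULT_CLASS_VOCABULARY
        ) if self.use_class_features else ()
        subs = (
            tuple(self.substructure_vocabulary or ())
            if self.use_substructure_features
            else ()
        )
        if feature_space is not None:
            if self.use_class_features and feature_space.class_columns:
                classes = feature_space.class_columns
            if self.use_substructure_features and feature_space.substructure_columns:
                subs = feature_space.substructure_columns
        self.metabolomes_ = dict(X)
        self.feature_space_ = FeatureSpace(tuple(sample_columns), classes, subs)
        self.cosine_params_ = CosineParams(
            fragment_tolerance=self.fragment_tolerance,
            min_matched_peaks=self.min_matched_peaks,
            intensity_power=self.intensity_power,
        )
        self.n_features_in_ = self.feature_space_.width
        return self

    def transform(
        self,
        X: Sequence[Spectrum],
        classes: Mapping[str, Iterable[str]] | None = None,
        substructures: Mapping[str, Iterable[str]] | None = None,
    ) -> pd.DataFrame:
        """Fingerprint each query spectrum; rows indexed by spectrum_id.

        ``classes``/``substructures`` map spectrum ids to externally predicted
        annotation name sets for the binary blocks (e.g. from class or
        substructure prediction tools); absent ids get all-zero blocks.
        """
        space: FeatureSpace = self.feature_space_
        rows = np.zeros((len(X), space.width))
        ids = []
        for i, q in enumerate(X):
            if q.n_peaks == 0:
                raise ValueError(f"query spectrum {q.spectrum_id!r} has no peaks")
            for j, sample in enumerate(space.sample_columns):
                val = max_cosine_to_metabolome(
                    q, self.metabolomes_[sample], self.cosine_params_
                )
                if self.apply_cutoff and val < self.similarity_cutoff:
                    val = 0.0
                rows[i, j] = val
            k = space.n_samples
            if space.class_columns:
                names = (classes or {}).get(q.spectrum_id, ())
                rows[i, k : k + len(space.class_columns)] = _feature_bits(
                    names, space.class_columns
                )
                k += len(space.class_columns)
            if space.substructure_columns:
                names = (substructures or {}).get(q.spectrum_id, ())
                rows[i, k:] = _feature_bits(names, space.substructure_columns)
            ids.append(q.spectrum_id)
        return pd.DataFrame(rows, index=pd.Index(ids, name="owner_id"), columns=space.columns)


def bgc_fingerprint(
    bgc: BgcRecord,
    bgcs: Sequence[BgcRecord],
    sims: SimilarityTable,
    cfg: FingerprintConfig | None = None,
    substructure_vocabulary: Sequence[str] | None = None,
) -> pd.Series:
    """Fingerprint one BGC against the genomes spanned by ``bgcs``."""
    cfg = cfg or FingerprintConfig()
    fp = BgcFingerprinter(
        similarity_cutoff=cfg.similarity_cutoff,
        use_class_features=cfg.use_class_features,
        use_substructure_features=cfg.use_substructure_features,
        substructure_vocabulary=substructure_vocabulary,
    ).fit(bgcs, similarities=sims)
    return fp.transform([bgc]).iloc[0]


def spectrum_fingerprint(
    q: Spectrum,
    metabolomes: Mapping[str, Metabolome],
    cosine: CosineParams | None = None,
    cfg: FingerprintConfig | None = None,
    feature_space: FeatureSpace | None = None,
    classes: Iterable[str] = (),
    substructures: Iterable[str] = (),
) -> pd.Series:
    """Fingerprint one query spectrum against the metabolomes."""
    cfg = cfg or FingerprintConfig()
    cosine = cosine or CosineParams()
    fp = SpectrumFingerprinter(
        similarity_cutoff=cfg.similarity_cutoff,
        apply_cutoff=cfg.apply_cutoff_to_spectra,
        fragment_tolerance=cosine.fragment_tolerance,
        min_matched_peaks=cosine.min_matched_peaks,
        intensity_power=cosine.intensity_power,
        use_class_features=cfg.use_class_features,
        use_substructure_features=cfg.use_substructure_features,
    ).fit(metabolomes, feature_space=feature_space)
    return fp.transform(
        [q],
        classes={q.spectrum_id: classes},
        substructures={q.spectrum_id: substructures},
    ).iloc[0]


def assemble_training_matrix(
    bgcs: Sequence[BgcRecord],
    sims: SimilarityTable,
    cfg: FingerprintConfig | None = None,
    substructure_vocabulary: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, FeatureSpace]:
    """Fingerprint every BGC into the training matrix with row-aligned labels.

    Every record must carry a ``gcf_label``; the returned matrix has one row
    per BGC over one shared feature space.
    """
    unlabeled = [b.bgc_id for b in bgcs if b.gcf_label is None]
    if unlabeled:
        raise ValueError(f"BGC(s) without gcf_label: {unlabeled[:5]}")
    cfg = cfg or FingerprintConfig()
    fp = BgcFingerprinter(
        similarity_cutoff=cfg.similarity_cutoff,
        use_class_features=cfg.use_class_features,
        use_substructure_features=cfg.use_substructure_features,
        substructure_vocabulary=substructure_vocabulary,
    ).fit(bgcs, similarities=sims)
    matrix = fp.transform(bgcs)
    labels = pd.Series(
        [b.gcf_label for b in bgcs], index=matrix.index, name="gcf_label"
    )
    return matrix, labels, fp.feature_space_


def binarize(values: np.ndarray | pd.Series, cutoff: float, n_similarity_columns: int | None = None) -> np.ndarray:
    """Presence/absence bits of a fingerprint.

    Similarity columns become 1 iff the value is >= cutoff (a value exactly at
    the cutoff counts as present); binary feature columns pass through.  With
    ``n_similarity_columns=None`` every column is treated as a similarity
    column (feature columns are 0/1, for which thresholding at any cutoff
    <= 1 is the identity anyway).
    """
    v = np.asarray(values, dtype=float)
    if n_similarity_columns is None:
        n_similarity_columns = v.shape[-1]
    out = np.empty_like(v)
    out[..., :n_similarity_columns] = (v[..., :n_similarity_columns] >= cutoff).astype(float)
    out[..., n_similarity_columns:] = v[..., n_similarity_columns:]
    return out


def read_feature_table(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """Read a long-format feature table (owner_id, feature name) into sets.

    Used for both ``classes.tsv`` (owner_id, class_name) and
    ``substructures.tsv`` (owner_id, substructure_name).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    owner_col, name_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for owner, name in zip(df[owner_col], df[name_col]):
        out.setdefault(str(owner), set()).add(str(name))
    return {k: frozenset(v) for k, v in out.items()}


def write_matrix(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a fingerprint matrix as TSV (first column ``owner_id``)."""
    matrix.to_csv(path, sep="\t", index=True, index_label="owner_id", float_format="%.6f")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a fingerprint matrix TSV written by :func:`write_matrix`."""
    return pd.read_csv(path, sep="\t", index_col="owner_id")
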