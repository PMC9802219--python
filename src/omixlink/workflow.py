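"""End-to-end pipeline: files in, ranked links and evaluation out.

Glues the reader modules, the two fingerprinters, the KNN linker and the
evaluator into one call, operating purely on the on-disk dialects (manifest +
MGF metabolomes, pairwise-distance network file, genome table, optional
feature tables and truth table).  The command-line interface and the
acceptance machinery both run through here, so every simulated dataset is
exercised through the same file round-trip a real dataset would take.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .evaluation import EvalReport, evaluate, read_truth
from .fingerprints import (
    BgcFingerprinter,
    SpectrumFingerprinter,
    read_feature_table,
)
from .linker import GCFLinkClassifier, LinkResult
from .network import (
    BgcRecord,
    NetworkParams,
    assign_gcfs,
    read_bgc_table,
    read_bigscape_network,
    read_gcf_labels,
)
from .spectra import ROLE_QUERY, merge_metabolomes, read_manifest, read_mgf

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters for one linking run.

    Paths are resolved relative to ``base_dir`` (typically the dataset
    directory).  ``network_paths`` accepts several files (one per
    biosynthetic class), which are unioned.
    """

    base_dir: Path
    manifest_path: str = "manifest.tsv"
    network_paths: tuple[str, ...] = ("network.tsv",)
    bgcs_path: str = "bgcs.tsv"
    truth_path: str | None = "truth.tsv"
    classes_path: str | None = None
    substructures_path: str | None = None
    gcf_labels_path: str | None = None
    similarity_cutoff: float = 0.7
    fragment_tolerance: float = 0.1
    min_matched_peaks: int = 1
    intensity_power: float = 0.5
    apply_cutoff_to_spectra: bool = True
    k: int = 3
    distance_metric: str = "euclidean"
    jaccard_threshold: float = 0.7
    apply_threshold: bool = True
    jaccard_scope: str = "all-features"
    top_n: int = 3
    seed: int = 0
    randomness_reps: int = 100

    def resolve(self, p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else Path(self.base_dir) / path


@dataclass
class PipelineResult:
    """Everything one run produced."""

    training_matrix: pd.DataFrame
    training_labels: pd.Series
    query_matrix: pd.DataFrame
    results: list[LinkResult]
    report: EvalReport | None
    gcf_labels: dict[str, str]
    n_similarity_columns: int


def _fingerprint_matrices(cfg: PipelineConfig):
    manifest = read_manifest(cfg.resolve(cfg.manifest_path))
    metabolomes = merge_metabolomes(manifest, base_dir=cfg.base_dir)
    query_rows = manifest[manifest["role"] == ROLE_QUERY]
    queries = []
    for p in query_rows["mgf_path"]:
        queries.extend(read_mgf(cfg.resolve(p)))

    bgcs = read_bgc_table(cfg.resolve(cfg.bgcs_path))
    sims = read_bigscape_network([cfg.resolve(p) for p in cfg.network_paths])
    external = (
        read_gcf_labels(cfg.resolve(cfg.gcf_labels_path))
        if cfg.gcf_labels_path
        else None
    )
    gcf_labels = assign_gcfs(
        bgcs,
        sims,
        NetworkParams(similarity_cutoff=cfg.similarity_cutoff),
        external_labels=external,
    )

    classes = (
        read_feature_table(cfg.resolve(cfg.classes_path)) if cfg.classes_path else {}
    )
    substructures = (
        read_feature_table(cfg.resolve(cfg.substructures_path))
        if cfg.substructures_path
        else {}
    )
    use_classes = bool(cfg.classes_path)
    use_subs = bool(cfg.substructures_path)
    sub_vocab = sorted({s for names in substructures.values() for s in names}) or None
    if use_classes or use_subs:
        bgcs = [
            BgcRecord(
                bgc_id=b.bgc_id,
                genome_id=b.genome_id,
                classes=classes.get(b.bgc_id, frozenset()),
                substructures=substructures.get(b.bgc_id, frozenset()),
                gcf_label=b.gcf_label,
            )
            for b in bgcs
        ]

    sample_columns = tuple(sorted({b.genome_id for b in bgcs} | set(metabolomes)))
    bgc_fp = BgcFingerprinter(
        similarity_cutoff=cfg.similarity_cutoff,
        use_class_features=use_classes,
        use_substructure_features=use_subs,
        substructure_vocabulary=sub_vocab,
    ).fit(bgcs, similarities=sims, sample_columns=sample_columns)
    training = bgc_fp.transform(bgcs)
    labels = pd.Series(
        [gcf_labels[b.bgc_id] for b in bgcs], index=training.index, name="gcf_label"
    )

    ms_fp = SpectrumFingerprinter(
        similarity_cutoff=cfg.similarity_cutoff,
        apply_cutoff=cfg.apply_cutoff_to_spectra,
        fragment_tolerance=cfg.fragment_tolerance,
        min_matched_peaks=cfg.min_matched_peaks,
        intensity_power=cfg.intensity_power,
        use_class_features=use_classes,
        use_substructure_features=use_subs,
        substructure_vocabulary=sub_vocab,
    ).fit(metabolomes, feature_space=bgc_fp.feature_space_)
    query_matrix = ms_fp.transform(queries, classes=classes, substructures=substructures)
    n_sim = bgc_fp.feature_space_.n_samples
    return training, labels, query_matrix, gcf_labels, n_sim


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Fingerprint, link and (when truth is available) evaluate one dataset."""
    training, labels, query_matrix, gcf_labels, n_sim = _fingerprint_matrices(cfg)
    clf = GCFLinkClassifier(
        n_neighbors=cfg.k,
        metric=cfg.distance_metric,
        jaccard_threshold=cfg.jaccard_threshold,
        apply_threshold=cfg.apply_threshold,
        jaccard_scope=cfg.jaccard_scope,
        similarity_cutoff=cfg.similarity_cutoff,
    ).fit(training, labels, n_similarity_columns=n_sim)
    ordered = query_matrix.loc[sorted(query_matrix.index, key=str)]
    results = clf.link(ordered)

    report = None
    truth_file = cfg.resolve(cfg.truth_path) if cfg.truth_path else None
    if truth_file is not None and truth_file.exists():
        truth = read_truth(truth_file)
        report = evaluate(
            results, truth, n=cfg.top_n, seed=cfg.seed, reps=cfg.randomness_reps
        )
    return PipelineResult(
        training_matrix=training,
        training_labels=labels,
        query_matrix=query_matrix,
        results=results,
        report=report,
        gcf_labels=gcf_labels,
        n_similarity_columns=n_sim,
    )
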