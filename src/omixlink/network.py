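"""BGC similarity networks and gene cluster family (GCF) assignment.

BiG-SCAPE writes pairwise BGC-BGC distances as tab-separated ``.network``
files, one per biosynthetic class; similarity is 1 minus the raw distance.
Pairs absent from the files are similarity 0 (BiG-SCAPE only writes pairs
under its distance cutoff).  A GCF is taken to be a connected component of the
similarity graph at the cutoff (single linkage, default 0.7, the calibrated
BiG-SCAPE cutoff); externally supplied family labels can override the
computed ones.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "BgcRecord",
    "SimilarityTable",
    "NetworkParams",
    "read_bigscape_network",
    "read_bgc_table",
    "read_gcf_labels",
    "assign_gcfs",
    "domain_jaccard_similarity",
]


@dataclass
class BgcRecord:
    """One biosynthetic gene cluster and its annotations.

    ``classes`` and ``substructures`` are name sets that the fingerprinting
    step turns into binary feature columns; ``gcf_label`` is filled by
    :func:`assign_gcfs` or an external label table.
    """

    bgc_id: str
    genome_id: str
    classes: frozenset[str] = frozenset()
    substructures: frozenset[str] = frozenset()
    gcf_label: str | None = None


class SimilarityTable:
    """Sparse symmetric map ``(bgc_id, bgc_id) -> similarity in [0, 1]``.

    The diagonal is implicitly 1.0 and absent pairs are 0.
    """

    def __init__(self) -> None:
        self._data: dict[tuple[str, str], float] = {}
        self._ids: set[str] = set()

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, similarity: float) -> None:
        if a == b:
            self._ids.add(a)
            return  # diagonal is implicit
        if not 0.0 <= similarity <= 1.0:
            clipped = min(max(similarity, 0.0), 1.0)
            warnings.warn(
                f"similarity({a!r}, {b!r}) = {similarity:g} outside [0, 1]; "
                f"clipped to {clipped:g}",
                stacklevel=2,
            )
            similarity = clipped
        self._data[self._key(a, b)] = float(similarity)
        self._ids.update((a, b))

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._data.get(self._key(a, b), 0.0)

    def ids(self) -> set[str]:
        """All BGC ids mentioned by any stored pair."""
        return set(self._ids)

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for (a, b), s in self._data.items():
            yield a, b, s

    def __len__(self) -> int:
        return len(self._data)


@dataclass(frozen=True)
class NetworkParams:
    """Graph construction parameters; ``similarity_cutoff`` in (0, 1]."""

    similarity_cutoff: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 < self.similarity_cutoff <= 1.0:
            raise ValueError("similarity_cutoff must be in (0, 1]")


def _normalise_column(name: str) -> str:
    return "".join(name.lower().split())


_REQUIRED = {
    "clustername1": "Clustername 1",
    "clustername2": "Clustername 2",
    "rawdistance": "Raw distance",
}


def read_bigscape_network(
    paths: str | os.PathLike | Sequence[str | os.PathLike],
    table: SimilarityTable | None = None,
) -> SimilarityTable:
    """Load one or more BiG-SCAPE ``.network`` files into a similarity table.

    Each row's similarity is stored as ``1 - raw distance`` with symmetric
    closure; BiG-SCAPE emits one file per biosynthetic class, so multiple
    paths are unioned.  Column headers are matched case- and
    space-insensitively against ``Clustername 1``, ``Clustername 2`` and
    ``Raw distance``.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    table = table if table is not None else SimilarityTable()
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str)
        colmap: dict[str, str] = {}
        for col in df.columns:
            norm = _normalise_column(col)
            if norm in _REQUIRED:
                colmap[_REQUIRED[norm]] = col
        missing = [pretty for key, pretty in _REQUIRED.items() if pretty not in colmap]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        raw = pd.to_numeric(df[colmap["Raw distance"]], errors="coerce")
        bad = raw.index[raw.isna()]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing
            raise ValueError(
                f"{path}: non-numeric raw distance at file row {int(bad[0]) + 2}"
            )
        for a, b, d in zip(df[colmap["Clustername 1"]], df[colmap["Clustername 2"]], raw):
            table.set(str(a), str(b), 1.0 - float(d))
    return table


def read_bgc_table(path: str | os.PathLike) -> list[BgcRecord]:
    """Read the genome table ``bgcs.tsv`` (columns bgc_id, genome_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("bgc_id", "genome_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["bgc_id"].duplicated().any():
        dupes = sorted(df.loc[df["bgc_id"].duplicated(), "bgc_id"])
        raise ValueError(f"{path}: duplicate bgc_id(s) {dupes}")
    return [
        BgcRecord(bgc_id=str(r.bgc_id), genome_id=str(r.genome_id))
        for r in df.itertuples()
    ]


def read_gcf_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read an external 2-column family label table (bgc_id, gcf_label)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("bgc_id", "gcf_label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return dict(zip(df["bgc_id"], df["gcf_label"]))


def assign_gcfs(
    bgcs: Sequence[BgcRecord],
    sims: SimilarityTable,
    params: NetworkParams | None = None,
    external_labels: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Assign a gene cluster family label to every BGC.

    Families are connected components of the graph whose edges are pairs with
    similarity >= cutoff.  Labels ``GCF1``, ``GCF2``, ... are numbered by the
    ascending lexicographic smallest member bgc_id, so the assignment is
    invariant to input ordering.  Singleton BGCs form singleton families.
    External labels, when supplied, override the computed ones.
    """
    params = params or NetworkParams()
    known = {b.bgc_id for b in bgcs}
    unknown = sims.ids() - known
    if unknown:
        raise ValueError(
            f"similarity table mentions bgc_id(s) absent from the BGC table: "
            f"{sorted(unknown)[:5]}"
        )
    graph = nx.Graph()
    graph.add_nodes_from(sorted(known))
    for a, b, s in sims.pairs():
        if s >= params.similarity_cutoff:
            graph.add_edge(a, b)
    components = sorted(nx.connected_components(graph), key=min)
    labels = {
        bgc_id: f"GCF{n}"
        for n, comp in enumerate(components, start=1)
        for bgc_id in comp
    }
    if external_labels:
        for bgc_id, label in external_labels.items():
            if bgc_id in labels:
                labels[bgc_id] = label
    return labels


def domain_jaccard_similarity(domains_a: Iterable[str], domains_b: Iterable[str]) -> float:
    """Jaccard similarity of two protein-domain sets; both empty -> 0.

    A stand-in pairwise BGC similarity so simulated datasets can produce
    similarity tables without an external BGC comparison run.
    """
    sa, sb = set(domains_a), set(domains_b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)
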