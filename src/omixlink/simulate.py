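"""Synthetic paired genome-metabolome datasets with known ground truth.

The generator emulates the structure the linker exploits: strains carry BGCs
grouped into families; a carried family's metabolite appears (subject to
expression dropout) in the carrier's metabolome; decoy BGCs and decoy
spectra add unlinked background; within-family BGC similarities are noisy
values in [0.7, 1.0] (the absence floor being 0, matching the cutoff
semantics of the similarity fingerprints) and cross-family pairs are omitted
from the network file, as a sparse pairwise-distance output would omit them.
Spectra are synthetic peak lists — random m/z positions with log-normal
intensities — with no attempt at chemically realistic fragmentation, because
the linker consumes only the similarity structure among spectra.

Every file is written in the dialects the reader modules define, so the
simulator doubles as a self-consistency check of the whole I/O surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fingerprints import DEFAULT_CLASS_VOCABULARY
from .network import BgcRecord, NetworkParams, SimilarityTable, assign_gcfs
from .spectra import (
    ROLE_QUERY,
    ROLE_TRAINING,
    Metabolome,
    Spectrum,
    write_mgf,
)

__all__ = ["SimConfig", "SimOutput", "simulate_paired_dataset", "make_confound"]


@dataclass(frozen=True, kw_only=True)
class SimConfig:
    """Study conditions for one simulated paired dataset.

    seed : int
        Mandatory random seed; all randomness derives from it.
    n_genomes, n_families : int
        Dataset dimensions.
    family_prevalence : float
        Probability a genome carries a family's BGC; each family is forced to
        have at least one carrier.
    expression_rate : float
        Probability a carried family's metabolite appears in that genome's
        metabolome; each family is forced to be expressed in at least one
        carrier, so every ground-truth link is recoverable in principle.
    decoy_spectra_per_sample, decoy_bgcs : int
        Unlinked background spectra per metabolome / singleton background BGCs.
    similarity_noise_sd : float
        Within-family similarity is ``1 - |N(0, sd)|`` floored at 0.7.
    mz_jitter_sd : float
        Per-peak m/z jitter (Da) applied to expressed/query spectrum copies.
    peak_dropout : float
        Probability each peak is missing from a spectrum copy.
    peaks_per_spectrum : int
        Fragment peaks per template spectrum; m/z uniform in [100, 1500] Da,
        intensities log-normal.
    use_class_features : bool
        Assign each family a biosynthetic class and emit ``classes.tsv``.
    """

    seed: int
    n_genomes: int = 20
    n_families: int = 10
    family_prevalence: float = 0.4
    expression_rate: float = 0.9
    decoy_spectra_per_sample: int = 5
    decoy_bgcs: int = 10
    similarity_noise_sd: float = 0.05
    mz_jitter_sd: float = 0.005
    peak_dropout: float = 0.1
    peaks_per_spectrum: int = 30
    use_class_features: bool = False

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.n_families < 1:
            raise ValueError("need at least one genome and one family")
        for name in ("family_prevalence", "expression_rate", "peak_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.peaks_per_spectrum < 2:
            raise ValueError("peaks_per_spectrum must be >= 2")


@dataclass
class SimOutput:
    """Handles to a written dataset: file paths plus in-memory objects."""

    outdir: Path
    manifest_path: Path
    network_path: Path
    bgcs_path: Path
    truth_path: Path
    query_mgf_path: Path
    classes_path: Path | None
    sample_mgf_paths: dict[str, Path]
    bgcs: list[BgcRecord]
    similarities: SimilarityTable
    metabolomes: dict[str, Metabolome]
    queries: list[Spectrum]
    truth: dict[str, str]
    gcf_labels: dict[str, str]


def _template_spectrum(rng: np.random.Generator, sid: str, n_peaks: int) -> Spectrum:
    mz = np.sort(rng.uniform(100.0, 1500.0, size=n_peaks))
    intensity = rng.lognormal(mean=0.0, sigma=1.0, size=n_peaks)
    precursor = float(rng.uniform(200.0, 1500.0))
    return Spectrum(sid, precursor, np.column_stack([mz, intensity]))


def _noisy_copy(rng: np.random.Generator, template: Spectrum, sid: str, cfg: SimConfig) -> Spectrum:
    keep = rng.random(template.n_peaks) >= cfg.peak_dropout
    if not keep.any():
        keep[int(np.argmax(template.intensity))] = True
    mz = template.mz[keep] + rng.normal(0.0, cfg.mz_jitter_sd, size=int(keep.sum()))
    intensity = template.intensity[keep] * np.exp(rng.normal(0.0, 0.1, size=int(keep.sum())))
    precursor = template.precursor_mz + float(rng.normal(0.0, cfg.mz_jitter_sd))
    return Spectrum(sid, precursor, np.column_stack([mz, intensity]))


def _exact_copy(template: Spectrum, sid: str) -> Spectrum:
    return template.with_id(sid)


def simulate_paired_dataset(
    cfg: SimConfig,
    outdir: str | Path,
    _presence_override=None,
) -> SimOutput:
    """Generate and write one paired dataset; deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    (outdir / "mgf").mkdir(parents=True, exist_ok=True)

    genomes = [f"G{i:03d}" for i in range(1, cfg.n_genomes + 1)]
    families = [f"F{j:03d}" for j in range(1, cfg.n_families + 1)]

    # presence[j, i]: genome i carries family j; every family gets >= 1 carrier
    presence = rng.random((cfg.n_families, cfg.n_genomes)) < cfg.family_prevalence
    forced_carrier = rng.integers(0, cfg.n_genomes, size=cfg.n_families)
    for j, i in enumerate(forced_carrier):
        presence[j, int(i)] = True
    if _presence_override is not None:
        _presence_override(presence)

    bgcs: list[BgcRecord] = []
    sims = SimilarityTable()
    family_members: dict[str, list[str]] = {}
    family_class: dict[str, str] = {}
    for j, fam in enumerate(families):
        members = [f"{genomes[i]}_{fam}" for i in range(cfg.n_genomes) if presence[j, i]]
        family_members[fam] = members
        if cfg.use_class_features:
            family_class[fam] = str(rng.choice(DEFAULT_CLASS_VOCABULARY))
        for i in range(cfg.n_genomes):
            if presence[j, i]:
                bgcs.append(
                    BgcRecord(
                        bgc_id=f"{genomes[i]}_{fam}",
                        genome_id=genomes[i],
                        classes=frozenset([family_class[fam]]) if cfg.use_class_features else frozenset(),
                    )
                )
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                s = 1.0 - abs(rng.normal(0.0, cfg.similarity_noise_sd))
                sims.set(members[a_idx], members[b_idx], max(s, 0.7))

    for d in range(cfg.decoy_bgcs):
        g = genomes[int(rng.integers(0, cfg.n_genomes))]
        bgcs.append(
            BgcRecord(
                bgc_id=f"{g}_DEC{d:03d}",
                genome_id=g,
                classes=frozenset([str(rng.choice(DEFAULT_CLASS_VOCABULARY))])
                if cfg.use_class_features
                else frozenset(),
            )
        )

    gcf_labels = assign_gcfs(bgcs, sims, NetworkParams(similarity_cutoff=0.7))
    family_gcf = {fam: gcf_labels[members[0]] for fam, members in family_members.items()}
    bgcs = [replace(b, gcf_label=gcf_labels[b.bgc_id]) for b in bgcs]

    noiseless = cfg.mz_jitter_sd == 0.0 and cfg.peak_dropout == 0.0
    templates = {
        fam: _template_spectrum(rng, f"{fam}_template", cfg.peaks_per_spectrum)
        for fam in families
    }

    # expression: which carriers' metabolomes contain the family's metabolite;
    # at least one expressing carrier per family keeps every link recoverable
    metabolomes: dict[str, Metabolome] = {}
    spectra_by_genome: dict[str, list[Spectrum]] = {g: [] for g in genomes}
    for j, fam in enumerate(families):
        carriers = [i for i in range(cfg.n_genomes) if presence[j, i]]
        expressed = [i for i in carriers if rng.random() < cfg.expression_rate]
        if not expressed:
            expressed = [carriers[int(rng.integers(0, len(carriers)))]]
        for i in expressed:
            sid = f"{genomes[i]}_{fam}_ms"
            copy = (
                _exact_copy(templates[fam], sid)
                if noiseless
                else _noisy_copy(rng, templates[fam], sid, cfg)
            )
            spectra_by_genome[genomes[i]].append(copy)
    for g in genomes:
        for d in range(cfg.decoy_spectra_per_sample):
            spectra_by_genome[g].append(
                _template_spectrum(rng, f"{g}_dec{d:03d}", cfg.peaks_per_spectrum)
            )
        metabolomes[g] = Metabolome(sample_id=g, spectra=spectra_by_genome[g])

    queries: list[Spectrum] = []
    truth: dict[str, str] = {}
    for fam in families:
        sid = f"query_{fam}"
        q = (
            _exact_copy(templates[fam], sid)
            if noiseless
            else _noisy_copy(rng, templates[fam], sid, cfg)
        )
        queries.append(q)
        truth[sid] = family_gcf[fam]

    # --- write everything in the reader dialects ---
    bgcs_path = outdir / "bgcs.tsv"
    pd.DataFrame(
        [(b.bgc_id, b.genome_id) for b in bgcs], columns=["bgc_id", "genome_id"]
    ).to_csv(bgcs_path, sep="\t", index=False)

    network_path = outdir / "network.tsv"
    pd.DataFrame(
        [(a, b, 1.0 - s) for a, b, s in sorted(sims.pairs())],
        columns=["Clustername 1", "Clustername 2", "Raw distance"],
    ).to_csv(network_path, sep="\t", index=False, float_format="%.6f")

    sample_mgf_paths: dict[str, Path] = {}
    manifest_rows = []
    for g in genomes:
        p = outdir / "mgf" / f"{g}.mgf"
        write_mgf(metabolomes[g].spectra, p)
        sample_mgf_paths[g] = p
        manifest_rows.append((g, str(p.relative_to(outdir)), ROLE_TRAINING))
    query_mgf_path = outdir / "queries.mgf"
    write_mgf(queries, query_mgf_path)
    manifest_rows.append(("queries", str(query_mgf_path.relative_to(outdir)), ROLE_QUERY))
    manifest_path = outdir / "manifest.tsv"
    pd.DataFrame(manifest_rows, columns=["sample_id", "mgf_path", "role"]).to_csv(
        manifest_path, sep="\t", index=False
    )

    truth_path = outdir / "truth.tsv"
    pd.DataFrame(sorted(truth.items()), columns=["spectrum_id", "true_gcf_label"]).to_csv(
        truth_path, sep="\t", index=False
    )

    classes_path: Path | None = None
    if cfg.use_class_features:
        classes_path = outdir / "classes.tsv"
        rows = [(b.bgc_id, c) for b in bgcs for c in sorted(b.classes)]
        rows += [
            (f"query_{fam}", family_class[fam]) for fam in families
        ]
        pd.DataFrame(rows, columns=["owner_id", "class_name"]).to_csv(
            classes_path, sep="\t", index=False
        )

    return SimOutput(
        outdir=outdir,
        manifest_path=manifest_path,
        network_path=network_path,
        bgcs_path=bgcs_path,
        truth_path=truth_path,
        query_mgf_path=query_mgf_path,
        classes_path=classes_path,
        sample_mgf_paths=sample_mgf_paths,
        bgcs=bgcs,
        similarities=sims,
        metabolomes=metabolomes,
        queries=queries,
        truth=truth,
        gcf_labels=gcf_labels,
    )


def make_confound(cfg: SimConfig, mode: str, outdir: str | Path) -> SimOutput:
    """Stress-case datasets.

    ``co-resident-families`` forces the first two families onto identical
    genome presence patterns, so their fingerprints collide and their queries
    become mutually confusable (the classic false-positive mode when two
    clusters always travel together).  ``dropout-heavy`` sets the expression
    rate to 0.2, thinning the co-occurrence evidence.
    """
    if mode == "co-resident-families":
        if cfg.n_families < 2:
            raise ValueError("co-resident mode needs at least two families")

        def override(presence):
            presence[1, :] = presence[0, :]

        return simulate_paired_dataset(cfg, outdir, _presence_override=override)
    if mode == "dropout-heavy":
        return simulate_paired_dataset(replace(cfg, expression_rate=0.2), outdir)
    raise ValueError(f"unknown confound mode {mode!r}")
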