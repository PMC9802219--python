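"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from omixlink import CosineParams, SimConfig, Spectrum, simulate_paired_dataset
from omixlink.workflow import PipelineConfig, run_pipeline


def random_spectrum(
    rng: np.random.Generator,
    spectrum_id: str = "s",
    n_peaks: int | None = None,
    mz_range: tuple[float, float] = (100.0, 110.0),
) -> Spectrum:
    """Random test spectrum.

    The default m/z window is narrow so that random pairs actually share
    candidate peak matches under a 0.1 Da tolerance.
    """
    n = n_peaks if n_peaks is not None else int(rng.integers(2, 9))
    mz = rng.uniform(*mz_range, size=n)
    intensity = rng.lognormal(0.0, 1.0, size=n)
    precursor = float(rng.uniform(*mz_range)) + 50.0
    return Spectrum(spectrum_id, precursor, np.column_stack([mz, intensity]))


def exhaustive_modified_cosine(a: Spectrum, b: Spectrum, params: CosineParams) -> float:
    """Optimal modified cosine by branch-and-bound over all one-to-one matchings.

    Independent of the greedy implementation: enumerates every valid
    one-to-one assignment of candidate peak pairs and returns the maximum
    achievable sum of weight products.  Only feasible for small spectra.
    """
    wa = a.intensity**params.intensity_power
    wa = wa / np.linalg.norm(wa)
    wb = b.intensity**params.intensity_power
    wb = wb / np.linalg.norm(wb)
    shift = a.precursor_mz - b.precursor_mz
    tol = params.fragment_tolerance
    cands = []
    for i in range(a.n_peaks):
        for j in range(b.n_peaks):
            d = a.mz[i] - b.mz[j]
            if abs(d) <= tol or abs(d - shift) <= tol:
                cands.append((i, j, float(wa[i] * wb[j])))
    cands.sort(key=lambda t: -t[2])
    suffix = np.concatenate([np.cumsum([c[2] for c in cands][::-1])[::-1], [0.0]])
    best = 0.0

    def rec(pos: int, used_a: int, used_b: int, total: float, count: int) -> None:
        nonlocal best
        if total > best and count >= params.min_matched_peaks:
            best = total
        if pos >= len(cands) or total + suffix[pos] <= best:
            return
        i, j, p = cands[pos]
        if not (used_a >> i) & 1 and not (used_b >> j) & 1:
            rec(pos + 1, used_a | (1 << i), used_b | (1 << j), total + p, count + 1)
        rec(pos + 1, used_a, used_b, total, count)

    rec(0, 0, 0, 0.0, 0)
    return min(best, 1.0)


class UnionFind:
    """Textbook union-find, used as an oracle for family assignment."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """A default-condition simulated dataset plus its pipeline run."""
    outdir = tmp_path_factory.mktemp("sim_default")
    out = simulate_paired_dataset(SimConfig(seed=7), outdir)
    result = run_pipeline(PipelineConfig(base_dir=outdir, seed=7))
    return out, result


@pytest.fixture(scope="session")
def noiseless_sim(tmp_path_factory):
    """Zero-noise, full-expression, decoy-free dataset (links fully recoverable)."""
    outdir = tmp_path_factory.mktemp("sim_noiseless")
    cfg = SimConfig(
        seed=11,
        n_genomes=15,
        n_families=8,
        expression_rate=1.0,
        decoy_spectra_per_sample=0,
        decoy_bgcs=0,
        similarity_noise_sd=0.0,
        mz_jitter_sd=0.0,
        peak_dropout=0.0,
    )
    out = simulate_paired_dataset(cfg, outdir)
    result = run_pipeline(PipelineConfig(base_dir=outdir, seed=11))
    return out, result
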