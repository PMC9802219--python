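"""Modified cosine similarity between MS/MS spectra.

The modified cosine score (the GNPS molecular-networking score) treats two
fragment peaks as matchable either directly, when their m/z values agree
within a fragment tolerance, or *shifted*, when they agree after adding the
precursor-mass difference of the two spectra.  Peak intensities are raised to
a power (default square root), each spectrum's weight vector is normalised to
unit Euclidean norm, and the score is the sum of weight products over a
one-to-one peak matching chosen greedily by descending product.  A greedy
matching is the de-facto behaviour of molecular-networking implementations;
an exhaustive optimal matcher is kept in the test suite as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Metabolome, Spectrum

__all__ = ["CosineParams", "PeakMatch", "modified_cosine", "max_cosine_to_metabolome"]


@dataclass(frozen=True)
class CosineParams:
    """Scoring parameters.

    fragment_tolerance : Da window within which two fragment m/z values (or
        their precursor-shifted difference) count as matching.  Default 0.1.
    min_matched_peaks : minimum number of matched peak pairs for a nonzero
        score.  Default 1.
    intensity_power : exponent applied to intensities before normalisation.
        Default 0.5 (square-root weighting).
    """

    fragment_tolerance: float = 0.1
    min_matched_peaks: int = 1
    intensity_power: float = 0.5

    def __post_init__(self) -> None:
        if not self.fragment_tolerance > 0:
            raise ValueError("fragment_tolerance must be positive")
        if self.min_matched_peaks < 1:
            raise ValueError("min_matched_peaks must be >= 1")
        if not self.intensity_power > 0:
            raise ValueError("intensity_power must be positive")


@dataclass(frozen=True)
class PeakMatch:
    """One matched peak pair and its contribution to the score."""

    index_a: int
    index_b: int
    shifted: bool
    product: float


def _unit_weights(spectrum: Spectrum, power: float) -> np.ndarray:
    w = spectrum.intensity**power
    norm = np.linalg.norm(w)
    return w / norm


def modified_cosine(
    a: Spectrum, b: Spectrum, params: CosineParams | None = None
) -> tuple[float, list[PeakMatch]]:
    """Modified cosine score between two spectra.

    Returns ``(score, matches)`` with the score in [0, 1].  Candidate peak
    pairs satisfy ``|mz_a - mz_b| <= tol`` (direct) or
    ``|mz_a - mz_b - (precursor_a - precursor_b)| <= tol`` (shifted, sign of
    the precursor difference preserved).  A pair qualifying both ways counts
    once, as direct.  Each peak is used at most once; pairs are accepted
    greedily by descending weight product.  If fewer than
    ``min_matched_peaks`` pairs match, the score is 0.

    Raises
    ------
    ValueError
        If either spectrum has an empty peak list.
    """
    params = params or CosineParams()
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("modified_cosine requires non-empty peak lists")
    wa = _unit_weights(a, params.intensity_power)
    wb = _unit_weights(b, params.intensity_power)
    diff = a.mz[:, None] - b.mz[None, :]
    tol = params.fragment_tolerance
    direct = np.abs(diff) <= tol
    shift = a.precursor_mz - b.precursor_mz
    shifted = np.abs(diff - shift) <= tol
    candidate = direct | shifted
    ia, ib = np.nonzero(candidate)
    if ia.size == 0:
        return 0.0, []
    products = wa[ia] * wb[ib]
    # descending product; ties broken by ascending (index_a, index_b) so that
    # identical spectra deterministically match along the diagonal
    order = np.lexsort((ib, ia, -products))
    used_a = np.zeros(a.n_peaks, dtype=bool)
    used_b = np.zeros(b.n_peaks, dtype=bool)
    matches: list[PeakMatch] = []
    total = 0.0
    for idx in order:
        i, j = int(ia[idx]), int(ib[idx])
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = True
        used_b[j] = True
        p = float(products[idx])
        matches.append(PeakMatch(i, j, shifted=not direct[i, j], product=p))
        total += p
    if len(matches) < params.min_matched_peaks:
        return 0.0, matches
    return float(min(max(total, 0.0), 1.0)), matches


def max_cosine_to_metabolome(
    q: Spectrum, m: Metabolome, params: CosineParams | None = None
) -> float:
    """Maximum modified cosine between ``q`` and any spectrum of a metabolome.

    An empty metabolome scores 0.  This per-sample maximum is the entry the
    MS/MS fingerprint stores for the corresponding sample column.
    """
    params = params or CosineParams()
    best = 0.0
    for s in m:
        score, _ = modified_cosine(q, s, params)
        if score > best:
            best = score
            if best >= 1.0:
                break
    return best
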