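"""Species-level divergence aggregation and effective population size.

Watterson's estimator on four-fold degenerate sites gives absolute Ne where
a mutation rate is known (theta = 2 Ne mu); elsewhere Ne is obtained by
inverting the nearly-neutral relationship dN/dS = x / (1 - exp(-x)) with
x = Ne*s, after calibrating a common selection coefficient s on the species
with absolute estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .codon import PairwiseDivergence

DS_WINDOW = (0.1, 0.3)


@dataclass
class NeEstimate:
    species_id: str
    mean_dnds: Optional[float] = None
    mean_dsdn: Optional[float] = None
    n_pairs_in_window: int = 0
    ne_relative: Optional[float] = None
    ne_absolute: Optional[float] = None
    theta_per_site: Optional[float] = None
    s_used: Optional[float] = None
    excluded: bool = False


def species_dsdn(
    pairs: Iterable[PairwiseDivergence],
    window: tuple[float, float] = DS_WINDOW,
) -> tuple[Optional[float], Optional[float], int]:
    """Mean dN/dS (and reciprocal) over pairs inside the dS window.

    Bounds are inclusive.  Pairs with undefined dN/dS (ds = 0 or saturated)
    never qualify.  Returns ``(None, None, 0)`` when no pair qualifies —
    the species is excluded from the divergence-based analysis.
    """
    lo, hi = window
    vals = [
        p.dnds
        for p in pairs
        if p.dnds is not None and not p.saturated and lo <= p.ds <= hi
    ]
    if not vals:
        return None, None, 0
    mean_dnds = float(np.mean(vals))
    mean_dsdn = 1.0 / mean_dnds if mean_dnds > 0 else None
    return mean_dnds, mean_dsdn, len(vals)


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (the Watterson / pan-genome normalizer)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(sum(1.0 / i for i in range(1, n)))


def watterson_theta(columns: np.ndarray, n_sequences: Optional[int] = None) -> Optional[float]:
    """Watterson's theta per site from a matrix of neutral site columns.

    ``columns`` is an (n_sequences x L) array of single-character states
    (or integer codes).  theta = S / (a_n * L) with S the number of
    segregating columns.  Returns ``None`` when L = 0.
    """
    columns = np.asarray(columns)
    if columns.ndim != 2:
        raise ValueError("expected a 2-D (sequences x sites) matrix")
    n = n_sequences if n_sequences is not None else columns.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    L = columns.shape[1]
    if L == 0:
        return None
    segregating = int(((columns != columns[0]).any(axis=0)).sum())
    return segregating / (harmonic_number(n) * L)


def ne_from_theta(theta_per_site: float, mu: float) -> float:
    """Ne = theta / (2 mu) for a haploid population."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if theta_per_site < 0:
        raise ValueError("theta must be nonnegative")
    return theta_per_site / (2.0 * mu)


def nearly_neutral_map(x: float) -> float:
    """f(x) = x / (1 - exp(-x)), the fixation-rate ratio at scaled selection x.

    Evaluated with a Taylor expansion near 0 for stability; f(0) = 1 is the
    neutral limit.  Strictly increasing and bounded by (0, 1] for x <= 0.
    """
    if not math.isfinite(x):
        raise ValueError("x must be finite")
    if abs(x) < 1e-8:
        # x/(1-e^-x) = 1 + x/2 + x^2/12 + O(x^4)
        return 1.0 + x / 2.0 + x * x / 12.0
    if x < 0:
        # overflow-safe form: multiply through by e^x
        return x * math.exp(x) / math.expm1(x)
    return x / -math.expm1(-x)


S_BRACKET = (-1.0, -1e-15)
NE_BRACKET = (1.0, 1e15)


def calibrate_s(calibration: Sequence[tuple[float, float]]) -> float:
    """Mean selection coefficient from (mean_dnds, absolute Ne) pairs.

    For each calibration species solve f(Ne*s) = dnds for s < 0 by bracketed
    root-finding.  Species with dnds >= 1 are skipped (f < 1 for s < 0).
    """
    estimates = []
    for dnds, ne in calibration:
        if not (0 < dnds < 1):
            continue
        if ne <= 0:
            raise ValueError("calibration Ne must be positive")

        def g(s: float, _ne=ne, _d=dnds) -> float:
            return nearly_neutral_map(_ne * s) - _d

        lo, hi = S_BRACKET
        # widen the lower bracket if f(ne*lo) has not yet dropped below dnds
        while g(lo) > 0 and lo > -1e6:
            lo *= 10
        estimates.append(brentq(g, lo, hi, xtol=1e-300, rtol=8.9e-16))
    if not estimates:
        raise ValueError("no usable calibration species (all dnds >= 1)")
    return float(np.mean(estimates))


def ne_from_dnds(mean_dnds: float, s_mean: float) -> Optional[float]:
    """Invert f(Ne*s) = mean_dnds for Ne, given a calibrated s < 0.

    Returns ``None`` when mean_dnds >= 1 (outside the image of f on s < 0).
    """
    if s_mean >= 0:
        raise ValueError("s_mean must be negative")
    if mean_dnds <= 0:
        raise ValueError("mean_dnds must be positive")
    if mean_dnds >= 1:
        return None

    def g(ne: float) -> float:
        return nearly_neutral_map(ne * s_mean) - mean_dnds

    lo, hi = NE_BRACKET
    while g(lo) < 0 and lo > 1e-12:
        lo /= 10  # dnds very close to 1: solution below 1 individual
    while g(hi) > 0 and hi < 1e30:
        hi *= 10
    return float(brentq(g, lo, hi, xtol=1e-300, rtol=8.9e-16))


def all_pairwise_divergences(
    sequences: dict[str, str],
    pairwise_dnds_fn=None,
) -> list[PairwiseDivergence]:
    """NG86 divergence for every unordered strain pair of an alignment."""
    from .codon import pairwise_dnds as _default

    fn = pairwise_dnds_fn or _default
    ids = sorted(sequences)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            out.append(fn(sequences[a], sequences[b], a, b))
    return out
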