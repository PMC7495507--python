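"""Coarse-graining, sample entropy, and multiscale-entropy profiles.

Sample entropy SampEn(m, r, N) = -ln(A/B), where B is the probability
that two length-m template vectors drawn from the series lie within r in
Chebyshev distance, and A the same for length-(m+1) vectors; self-matches
are excluded.  Multiscale entropy evaluates SampEn on coarse-grained
(non-overlapping window-averaged) versions of the series over a schedule
of scale factors.  Because each frequency band lives on its own time
scale, the schedules are band-specific: gamma 1..20, beta 2..40 step 2,
alpha 4..80 step 4, theta 8..160 step 8 (20 scale factors each).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial.distance import cdist

from neuromse.hilbert import BandComponents

__all__ = [
    "SampEnParams",
    "ScaleFactorSet",
    "MSEProfile",
    "COMPONENTS",
    "band_scale_factors",
    "coarse_grain",
    "sample_entropy",
    "mse_profile",
    "count_peaks",
]

COMPONENTS = ("spectral", "amplitude", "phase")

#: coarse-grained series shorter than this are flagged low-confidence
LOW_CONFIDENCE_LENGTH = 25

_BAND_STEPS = {"gamma": 1, "beta": 2, "alpha": 4, "theta": 8}


@dataclass
class SampEnParams:
    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")


@dataclass
class ScaleFactorSet:
    band: str
    factors: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.factors) != 20:
            raise ValueError("exactly 20 scale factors expected")
        if any(b <= a for a, b in zip(self.factors, self.factors[1:])):
            raise ValueError("scale factors must be strictly increasing")


def band_scale_factors(band: str) -> ScaleFactorSet:
    """The 20-scale-factor schedule for a band (step 1/2/4/8 by band)."""
    try:
        step = _BAND_STEPS[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; expected one of "
                         f"{sorted(_BAND_STEPS)}") from None
    return ScaleFactorSet(band=band,
                          factors=tuple(step * k for k in range(1, 21)))


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping window means of length tau; trailing remainder dropped."""
    x = np.asarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau > x.size:
        raise ValueError(f"tau={tau} exceeds series length {x.size}")
    n = x.size // tau
    return x[:n * tau].reshape(n, tau).mean(axis=1)


def sample_entropy(series: np.ndarray, m: int = 2,
                   r_abs: float = 0.2) -> float:
    """SampEn with an absolute Chebyshev tolerance (strict inequality).

    Both the length-m and length-(m+1) template counts run over the same
    index range i = 1..N-m, with ordered pairs i != j.  Returns NaN (the
    undefined marker) when either count is zero.
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    if r_abs <= 0:
        raise ValueError("r_abs must be > 0")
    n = x.size
    if n < m + 2:
        return float("nan")

    windows = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # (n-m, m+1)
    xm = windows[:, :m]
    last = windows[:, m]
    n_templates = windows.shape[0]

    count_b = 0
    count_a = 0
    chunk = max(1, int(2**22 // max(n_templates, 1)))
    for start in range(0, n_templates, chunk):
        stop = min(start + chunk, n_templates)
        if m == 1:
            db = np.abs(xm[start:stop] - xm.T)  # (chunk, n_templates)
        else:
            db = cdist(xm[start:stop], xm, metric="chebyshev")
        within_b = db < r_abs
        da = np.maximum(db, np.abs(last[start:stop, None] - last[None, :]))
        count_b += int(within_b.sum()) - (stop - start)  # drop self-matches
        count_a += int((da < r_abs).sum()) - (stop - start)
    if count_a == 0 or count_b == 0:
        return float("nan")
    return float(-np.log(count_a / count_b))


def count_peaks(profile: np.ndarray, min_prominence_frac: float = 0.1) -> int:
    """Number of maxima of an entropy profile, after adjacent-pair smoothing.

    Narrow-band components produce a low-amplitude ripple across scale
    factors (coarse-graining windows commensurate with the oscillation
    period), so maxima are counted with a prominence of at least
    ``min_prominence_frac`` times the smoothed profile's range; boundary
    maxima count.  Adaptive decompositions typically give one peak where
    band-pass-filtered components give several.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 3 or not np.all(np.isfinite(p)):
        raise ValueError("profile must be finite with length >= 3")
    sm = 0.5 * (p[:-1] + p[1:])
    prom = min_prominence_frac * (sm.max() - sm.min())
    padded = np.concatenate([[sm.min() - 1.0], sm, [sm.min() - 1.0]])
    peaks, _ = find_peaks(padded, prominence=max(prom, 0.0))
    return int(len(peaks))


@dataclass
class MSEProfile:
    """SampEn values over (component x scale factor) for one region/band.

    ``values`` is a (3, 20) array ordered (spectral, amplitude, phase) x
    scale factors; undefined cells are NaN.  ``n_segments`` counts the
    segments contributing to each cell, ``low_confidence`` flags cells
    whose coarse-grained series were shorter than ``LOW_CONFIDENCE_LENGTH``.
    """

    subject_id: str
    region_id: int
    band: str
    scale_factors: tuple[int, ...]
    values: np.ndarray
    n_segments: np.ndarray
    low_confidence: np.ndarray
    components: tuple[str, ...] = COMPONENTS

    def vector(self) -> np.ndarray:
        """The flat 60-dim feature (3 components x 20 SFs)."""
        return self.values.reshape(-1)

    def component(self, name: str) -> np.ndarray:
        return self.values[self.components.index(name)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, comp in enumerate(self.components):
            for si, sf in enumerate(self.scale_factors):
                rows.append({
                    "subject": self.subject_id, "region": self.region_id,
                    "band": self.band, "component": comp, "scale_factor": sf,
                    "sampen": self.values[ci, si],
                    "n_segments_defined": int(self.n_segments[ci, si]),
                    "low_confidence": bool(self.low_confidence[ci, si]),
                })
        return pd.DataFrame(rows)


def mse_profile(segments: list[BandComponents],
                params: SampEnParams | None = None,
                sfs: ScaleFactorSet | None = None,
                subject_id: str = "", region_id: int = 0) -> MSEProfile:
    """Multiscale entropy of a band's components, averaged across segments.

    Per segment and component, the tolerance is ``r`` times the SD of the
    *un-coarse-grained* component series of that segment (the canonical
    multiscale-entropy convention); SampEn is computed on each
    coarse-grained series and then averaged over segments with defined
    values.  Cells with no defined segment stay NaN.
    """
    if not segments:
        raise ValueError("at least one segment required")
    if params is None:
        params = SampEnParams()
    if sfs is None:
        sfs = band_scale_factors(segments[0].band)

    n_sf = len(sfs.factors)
    sums = np.zeros((len(COMPONENTS), n_sf))
    counts = np.zeros((len(COMPONENTS), n_sf), dtype=int)
    lowconf = np.zeros((len(COMPONENTS), n_sf), dtype=bool)

    for seg in segments:
        comps = seg.components()
        for ci, comp in enumerate(COMPONENTS):
            series = comps[comp]
            sd = float(np.std(series))
            if sd == 0.0:
                continue  # degenerate: undefined for every scale
            r_abs = params.r * sd
            for si, tau in enumerate(sfs.factors):
                if tau > series.size:
                    continue
                cg = coarse_grain(series, tau)
                if cg.size < LOW_CONFIDENCE_LENGTH:
                    lowconf[ci, si] = True
                val = sample_entropy(cg, params.m, r_abs)
                if np.isfinite(val):
                    sums[ci, si] += val
                    counts[ci, si] += 1

    values = np.full((len(COMPONENTS), n_sf), np.nan)
    defined = counts > 0
    values[defined] = sums[defined] / counts[defined]
    return MSEProfile(subject_id=subject_id, region_id=region_id,
                      band=sfs.band, scale_factors=sfs.factors,
                      values=values, n_segments=counts,
                      low_confidence=lowconf)
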