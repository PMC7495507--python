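"""Synthetic MEG-like cohort generation.

Real resting-state source time series are private in essentially every
clinical M/EEG study, so the pipeline is exercised on generated cohorts
that reproduce the statistical structure the analysis assumes: a 1/f
background, a narrow-band alpha oscillation whose envelope irregularity
("amplitude complexity") and phase random-walk ("phase complexity") are
controllable per group, group effects injected only into designated
temporal regions, and a subject manifest with demographics and cognitive
scores whose association with disease severity supports the
entropy-cognition correlation analyses.

The patient group's defaults encode the clinical direction of effect:
lower amplitude complexity and higher phase diffusion than controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from neuromse.decomposition import bandpass

__all__ = [
    "SimulationConfig",
    "SubjectManifest",
    "Recording",
    "generate_pink_noise",
    "generate_oscillation",
    "generate_cohort",
]

#: WMS-R subscore (mean, SD) per group, used only as manifest dressing.
_WMSR_NORMS = {
    "general": {"HC": (102, 11), "AD": (65, 13)},
    "concentration": {"HC": (105, 12), "AD": (87, 17)},
    "verbal": {"HC": (101, 11), "AD": (69, 12)},
    "visual": {"HC": (102, 12), "AD": (67, 15)},
    "delayed_recall": {"HC": (99, 12), "AD": (60, 12)},
}


@dataclass
class SimulationConfig:
    """Cohort-level generator parameters.

    ``amp_complexity_*`` weight the stochastic part of the oscillation
    envelope (0 = fully deterministic slow envelope, 1 = fully
    stochastic); ``phase_diffusion_*`` is the per-sample innovation SD
    (rad) of the mean-reverting phase random walk.  AD values apply only
    in the first ``n_temporal_regions`` regions; all other regions use
    the HC values for every subject.
    """

    n_per_group: int = 20
    n_regions: int = 8
    n_temporal_regions: int = 2
    fs: float = 400.0
    segment_seconds: float = 10.0
    n_segments: int = 12
    alpha_freq: float = 10.0
    pink_beta: float = 1.0
    amp_complexity_hc: float = 0.9
    amp_complexity_ad: float = 0.2
    phase_diffusion_hc: float = 0.02
    phase_diffusion_ad: float = 0.05
    snr: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_regions", "n_temporal_regions",
                     "n_segments"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_temporal_regions > self.n_regions:
            raise ValueError("n_temporal_regions cannot exceed n_regions")
        if self.fs <= 2 * self.alpha_freq:
            raise ValueError("fs must exceed twice the oscillation frequency")
        for name in ("amp_complexity_hc", "amp_complexity_ad"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("phase_diffusion_hc", "phase_diffusion_ad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.segment_seconds))

    @property
    def temporal_regions(self) -> tuple[int, ...]:
        return tuple(range(self.n_temporal_regions))


@dataclass
class SubjectManifest:
    subject_id: str
    group: str
    age: float
    sex: str
    dz_use: bool
    mmse: float
    wmsr_subscores: dict[str, float] = field(default_factory=dict)
    # generator-side ground truth, kept for parameter-recovery analyses
    severity: float = 0.0
    amp_complexity: float = 0.0
    phase_diffusion: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in ("HC", "AD"):
            raise ValueError("group must be 'HC' or 'AD'")
        if not 0 <= self.mmse <= 30:
            raise ValueError("mmse must lie in [0, 30]")


@dataclass
class Recording:
    """One subject's segmented region time series: (segments, regions, samples)."""

    subject_id: str
    fs: float
    data: np.ndarray

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def generate_pink_noise(n: int, beta: float = 1.0,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Zero-mean noise with expected power spectrum proportional to 1/f^beta.

    Shaped in the frequency domain: a white Gaussian spectrum is scaled
    by f^(-beta/2) (DC zeroed) and inverse-transformed, then normalized
    to unit standard deviation.  beta=0 gives white noise.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-beta / 2.0)
    spec = (rng.standard_normal(freqs.size)
            + 1j * rng.standard_normal(freqs.size)) * scale
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_oscillation(duration_s: float, fs: float, f0: float,
                         amp_complexity: float, phase_diffusion: float,
                         seed: int | np.random.Generator = 0,
                         relaxation_s: float = 2.0,
                         return_components: bool = False):
    """Narrow-band oscillation a(t) * cos(2*pi*f0*t + phi(t)).

    The envelope mixes a deterministic raised cosine at 0.2 Hz (weight
    1 - amp_complexity) with the absolute value of 0.5-4 Hz band-limited
    Gaussian noise (weight amp_complexity), both normalized to unit mean
    so a(t) >= 0 with unit mean for every mixing weight.  phi(t) is a
    mean-reverting (Ornstein-Uhlenbeck-like) Gaussian random walk with
    per-sample innovation SD ``phase_diffusion`` and relaxation time
    ``relaxation_s``, keeping f0 the spectral peak.
    """
    if not 0 <= amp_complexity <= 1:
        raise ValueError("amp_complexity must lie in [0, 1]")
    if phase_diffusion < 0:
        raise ValueError("phase_diffusion must be >= 0")
    if fs <= 2 * f0:
        raise ValueError("fs must exceed 2*f0")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    slow = 1.0 + 0.5 * np.cos(2 * np.pi * 0.2 * t
                              + rng.uniform(0, 2 * np.pi))
    slow /= slow.mean()
    stoch = np.abs(bandpass(rng.standard_normal(n), fs, 0.5, 4.0))
    mean = stoch.mean()
    if mean > 0:
        stoch /= mean
    envelope = (1 - amp_complexity) * slow + amp_complexity * stoch

    decay = 1.0 - 1.0 / (relaxation_s * fs)
    innov = rng.standard_normal(n) * phase_diffusion
    # AR(1) recursion phi[i] = decay * phi[i-1] + innov[i]
    phi = lfilter([1.0], [1.0, -decay], innov)

    signal = envelope * np.cos(2 * np.pi * f0 * t + phi)
    if return_components:
        return signal, envelope, phi
    return signal


def _subject_severity(group: str, rng: np.random.Generator) -> float:
    """Latent disease severity in [0, 1]; controls sit near zero."""
    if group == "HC":
        return float(rng.uniform(0.0, 0.2))
    return float(rng.uniform(0.6, 1.0))


def generate_cohort(config: SimulationConfig
                    ) -> tuple[list[Recording], list[SubjectManifest]]:
    """Generate a two-group cohort of segmented region time series.

    Each region series is ``snr * oscillation + pink background`` (both
    unit-RMS before scaling).  A per-subject latent severity interpolates
    the HC -> AD envelope/phase parameters, applied only in the temporal
    regions; severity also drives the MMSE score (29 - 4*severity plus
    N(0, 3.0) noise, clipped to [0, 30]), so that higher phase diffusion
    associates with lower MMSE at a rank correlation near -0.4.
    Fully reproducible from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    subject_seeds = ss.spawn(2 * config.n_per_group)
    recordings: list[Recording] = []
    manifests: list[SubjectManifest] = []
    groups = ["HC"] * config.n_per_group + ["AD"] * config.n_per_group

    for idx, (group, sseed) in enumerate(zip(groups, subject_seeds)):
        rng = np.random.default_rng(sseed)
        sev = _subject_severity(group, rng)
        amp = (config.amp_complexity_hc
               + sev * (config.amp_complexity_ad - config.amp_complexity_hc))
        pdiff = (config.phase_diffusion_hc
                 + sev * (config.phase_diffusion_ad - config.phase_diffusion_hc))

        age_mu, age_sd = (68.1, 7.3) if group == "HC" else (71.7, 6.5)
        age = float(np.clip(rng.normal(age_mu, age_sd), 50, 90))
        sex = "M" if rng.uniform() < (0.619 if group == "HC" else 0.588) else "F"
        dz = bool(group == "AD" and rng.uniform() < 10 / 17)
        mmse = float(np.clip(29.0 - 4.0 * sev + rng.normal(0, 3.0), 0, 30))
        wmsr = {name: float(rng.normal(*norms[group]))
                for name, norms in _WMSR_NORMS.items()}

        data = np.empty((config.n_segments, config.n_regions, config.n_samples))
        for seg in range(config.n_segments):
            for region in range(config.n_regions):
                temporal = region < config.n_temporal_regions
                a = amp if temporal else config.amp_complexity_hc
                p = pdiff if temporal else config.phase_diffusion_hc
                osc = generate_oscillation(config.segment_seconds, config.fs,
                                           config.alpha_freq, a, p, seed=rng)
                rms = np.sqrt(np.mean(osc ** 2))
                if rms > 0:
                    osc = osc / rms
                background = generate_pink_noise(config.n_samples,
                                                 config.pink_beta, seed=rng)
                data[seg, region] = config.snr * osc + background

        sid = f"sub-{idx:03d}"
        recordings.append(Recording(subject_id=sid, fs=config.fs, data=data))
        manifests.append(SubjectManifest(
            subject_id=sid, group=group, age=age, sex=sex, dz_use=dz,
            mmse=mmse, wmsr_subscores=wmsr, severity=sev,
            amp_complexity=amp, phase_diffusion=pdiff))
    return recordings, manifests
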