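"""Synthetic RR-interval series, planted-atom signals and study cohorts.

The generator emulates the two populations the screening pipeline is built
to separate:

* **NSR-like** (healthy, normal sinus rhythm): slower heart rate, high
  overall variability, a dominant respiratory (HF) oscillation and a
  substantial broadband (white + 1/f) component — noise-like structure
  that matching pursuit decomposes slowly.
* **CHF-like** (congestive heart failure): faster rate, low variability,
  energy shifted into a coherent very-low/low-frequency oscillation with
  the high-frequency component almost absent — coherent structure that MP
  exhausts in a few atoms.

Each interval is the mean RR plus sinusoidal modulations at fixed VLF, LF
and HF frequencies evaluated at the cumulative beat time, plus white and
1/f-coloured noise.  Fixed modulation frequencies keep the band-power
ground truth analytically known.  When ``sdnn > 0`` the composed
fluctuation is rescaled to that target standard deviation, which pins the
between-class variability contrast without changing the within-series band
mix.  Intervals are clipped to a physiological [200, 2500] ms.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gabor_mp import GaborAtom
from .preprocessing import RRSeries

__all__ = [
    "RRGenParams",
    "PlantedSignal",
    "generate_rr",
    "nsr_preset",
    "chf_preset",
    "generate_planted_signal",
    "generate_study_cohort",
    "write_rr_text",
    "write_cohort",
]

#: Physiological clipping bounds for generated intervals, ms.
CLIP_MS = (200.0, 2500.0)

#: Default modulation frequencies, Hz.  The VLF tone sits near the top of
#: the VLF band so that a useful fraction survives the smoothness-priors
#: detrender (whose default cutoff is ~0.035 Hz); LF and HF sit at the
#: conventional Mayer-wave and respiratory frequencies.
VLF_FREQ = 0.033
LF_FREQ = 0.1
HF_FREQ = 0.25


@dataclass(frozen=True)
class RRGenParams:
    """Parameters of one synthetic RR series (amplitudes/SDs in ms)."""

    mean_rr: float = 900.0
    sdnn: float = 0.0  # target overall SD; 0 disables rescaling
    vlf_amp: float = 0.0
    lf_amp: float = 0.0
    hf_amp: float = 0.0
    noise_sd: float = 0.0
    one_over_f_sd: float = 0.0
    n_beats: int = 256
    seed: int = 0
    vlf_freq: float = VLF_FREQ
    lf_freq: float = LF_FREQ
    hf_freq: float = HF_FREQ

    def __post_init__(self):
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.n_beats < 256:
            raise ValueError("n_beats must be at least 256")
        for name in ("sdnn", "vlf_amp", "lf_amp", "hf_amp",
                     "noise_sd", "one_over_f_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("vlf_freq", "lf_freq", "hf_freq"):
            if not (0 < getattr(self, name) < 0.5):
                raise ValueError(f"{name} must lie in (0, 0.5) Hz")


@dataclass(frozen=True)
class PlantedSignal:
    """Specification of a noiseless-or-noisy exact atom combination."""

    atoms: tuple
    coefficients: tuple
    noise_sd: float = 0.0
    length: int = 1024

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        if len(self.atoms) != len(self.coefficients):
            raise ValueError("atoms and coefficients must align")
        for a in self.atoms:
            if a.waveform.size != self.length:
                raise ValueError("atom length does not match signal length")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-SD 1/f-coloured Gaussian noise via spectral shaping."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = np.inf  # kill DC
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_rr(params: RRGenParams) -> RRSeries:
    """Generate one RR series per the modulation-plus-noise model.

    Interval ``k`` is ``mean_rr`` plus sinusoids at the three band
    frequencies evaluated at the cumulative beat time (seconds, advanced
    by each interval as it is generated), plus white and 1/f noise.  With
    ``sdnn > 0`` the fluctuation is rescaled post hoc to that SD, then the
    mean is re-added and the result clipped to [200, 2500] ms.
    """
    rng = np.random.default_rng(params.seed)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    white = rng.normal(size=params.n_beats)
    pink = _pink_noise(rng, params.n_beats)

    freqs = np.array([params.vlf_freq, params.lf_freq, params.hf_freq])
    amps = np.array([params.vlf_amp, params.lf_amp, params.hf_amp])

    dev = np.empty(params.n_beats)
    t = 0.0
    for k in range(params.n_beats):
        mod = float(np.sum(amps * np.sin(2 * np.pi * freqs * t + phases)))
        dev[k] = (mod + params.noise_sd * white[k]
                  + params.one_over_f_sd * pink[k])
        t += (params.mean_rr + dev[k]) / 1000.0

    if params.sdnn > 0 and dev.std() > 0:
        dev = dev * (params.sdnn / dev.std())
    rr = np.clip(params.mean_rr + dev, *CLIP_MS)
    return RRSeries(intervals=rr, subject_id=f"synthetic-{params.seed}")


def nsr_preset() -> RRGenParams:
    """Healthy (normal-sinus-rhythm-like) parameter set.

    Resting healthy adults: mean RR ~900 ms, short-term SDNN ~50 ms,
    respiratory sinus arrhythmia dominant (HF at 0.25 Hz), a clear Mayer
    wave (LF at 0.1 Hz), and a strong broadband component that gives the
    series its noise-like, slowly decaying MP structure.
    """
    return RRGenParams(
        mean_rr=900.0, sdnn=50.0,
        vlf_amp=10.0, lf_amp=30.0, hf_amp=30.0,
        noise_sd=15.0, one_over_f_sd=18.0,
        n_beats=300,
    )


def chf_preset() -> RRGenParams:
    """Congestive-heart-failure-like parameter set.

    Faster rate (mean RR ~700 ms), strongly reduced overall variability
    (SDNN ~18 ms), respiratory modulation almost abolished, and the
    remaining energy concentrated in a coherent very-low-frequency
    oscillation — a few Gabor atoms capture most of the signal, so the MP
    residual decays fast.
    """
    return RRGenParams(
        mean_rr=700.0, sdnn=18.0,
        vlf_amp=25.0, lf_amp=4.0, hf_amp=1.5,
        noise_sd=1.0, one_over_f_sd=2.0,
        n_beats=300,
    )


def generate_planted_signal(spec: PlantedSignal, seed: int = 0) -> np.ndarray:
    """Exact linear combination of atoms plus optional Gaussian noise."""
    x = np.zeros(spec.length)
    for c, atom in zip(spec.coefficients, spec.atoms):
        x += c * atom.waveform
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, spec.noise_sd, size=spec.length)
    return x


#: Per-subject jitter fraction applied to the preset amplitudes, noise
#: levels, SDNN target and mean RR (uniform in +-10%).
JITTER_FRACTION = 0.10

_JITTERED_FIELDS = ("mean_rr", "sdnn", "vlf_amp", "lf_amp", "hf_amp",
                    "noise_sd", "one_over_f_sd")


def _jittered(params: RRGenParams, rng: np.random.Generator,
              seed: int) -> RRGenParams:
    updates = {"seed": seed}
    for name in _JITTERED_FIELDS:
        v = getattr(params, name)
        updates[name] = v * (1 + JITTER_FRACTION * rng.uniform(-1, 1))
    return replace(params, **updates)


def generate_study_cohort(
    n_nsr: int = 40, n_chf: int = 29, seed: int = 0
) -> list[RRSeries]:
    """Labelled cohort of jittered NSR- and CHF-preset series.

    The default (40, 29) mirrors the study layout: 40 healthy volunteers
    and 29 heart-failure subjects, one 256-beat-capable segment each.
    """
    if n_nsr < 1 or n_chf < 1:
        raise ValueError("need at least one subject per class")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_nsr):
        p = _jittered(nsr_preset(), rng, seed=int(rng.integers(2**31)))
        rr = generate_rr(p)
        rr.label = "NSR"
        rr.subject_id = f"nsr{i:03d}"
        cohort.append(rr)
    for i in range(n_chf):
        p = _jittered(chf_preset(), rng, seed=int(rng.integers(2**31)))
        rr = generate_rr(p)
        rr.label = "CHF"
        rr.subject_id = f"chf{i:03d}"
        cohort.append(rr)
    return cohort


def write_rr_text(rr: RRSeries, path) -> None:
    """Write an RR series as plain text, one interval (ms) per line."""
    np.savetxt(path, rr.intervals, fmt="%.6f")


def write_cohort(cohort: list[RRSeries], out_dir, params=None) -> Path:
    """Write RR text files plus a manifest CSV; returns the manifest path.

    The manifest has columns ``filename``, ``subject_id``, ``label`` and
    (when per-subject parameters are supplied) ``params`` as a JSON string.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rr in enumerate(cohort):
        fname = f"{rr.subject_id or f'subject{i:03d}'}.rr.txt"
        write_rr_text(rr, out_dir / fname)
        row = {"filename": fname, "subject_id": rr.subject_id,
               "label": rr.label}
        if params is not None:
            row["params"] = json.dumps(asdict(params[i]))
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
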