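"""The 16 matching-pursuit-derived HRV features.

Four families, computed from one MP decomposition (nominally 30 atoms) of a
preprocessed 1024-sample HRV segment:

* residual-energy decay  ``E(VLF), E(LF), E(HF), E`` — mean over the M
  iterations of the (band-restricted) residual energy, normalised by the
  signal energy.  Coherent signals (few dominant oscillations, typical of
  heart failure) decay fast and score low; noise-like healthy variability
  decays slowly and scores high.
* PSD band powers  ``VLF, LF, HF, HF/VLF, HF+LF`` — Welch periodogram of
  the per-band subsignal (atoms whose centre frequency falls in the band),
  summed over the band's bins.  Absolute powers are stored per unit signal
  variance so that all features are invariant to rescaling the input.
* MP entropies  ``Hw(LF), Hw(HF)`` — Shannon entropy (bits) of the global
  per-atom energy distribution p_n = c_n^2 / sum(c^2), summed over the
  atoms in the band.
* frequency distribution  ``D(LF), D(HF), D(HF)/D(VLF), D(VLF)/D(LF),
  D(LF)/D(HF)`` — fraction of the M atoms whose centre frequency lies in
  each band, plus ratios.

Ratios with a vanishing denominator are defined as numerator / 1e-12,
capped at 1e6: features stay finite and the downstream MinMax scaling
compresses the caps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .gabor_mp import MPResult, atom_band, build_dictionary, mp_decompose, reconstruct
from .preprocessing import UniformHRV

__all__ = [
    "FEATURE_NAMES",
    "WelchSpec",
    "mean_energy_decay",
    "band_subsignal",
    "welch_psd",
    "psd_features",
    "mp_entropy",
    "freq_distribution",
    "extract_features",
    "extract_feature_table",
]

#: Fixed order of the 16 features; the column contract of the feature table.
FEATURE_NAMES: list[str] = [
    "E_VLF", "E_LF", "E_HF", "E",
    "VLF", "LF", "HF", "HF_over_VLF", "HF_plus_LF",
    "Hw_LF", "Hw_HF",
    "D_LF", "D_HF", "D_HF_over_D_VLF", "D_VLF_over_D_LF", "D_LF_over_D_HF",
]

_EPS = 1e-12
_RATIO_CAP = 1e6


def _safe_ratio(num: float, den: float) -> float:
    if den < _EPS:
        return min(num / _EPS, _RATIO_CAP)
    return num / den


def _atom_bands(mp: MPResult) -> list[str]:
    return [atom_band(a, mp.fs) for a in mp.atoms]


@dataclass
class WelchSpec:
    """One-sided Welch power spectral density estimate."""

    frequencies: np.ndarray  # Hz
    power: np.ndarray  # density, units^2 / Hz
    seg_len: int
    overlap: float
    window: str


def mean_energy_decay(mp: MPResult, band: str = "total") -> float:
    """Mean residual-energy decay rate, normalised by signal energy.

    ``band='total'`` averages the recorded residual energies over the M
    iterations.  For a named band, the residual is restricted to the
    energy carried by atoms of that band: the band total is
    ``B = sum(c_n^2, atom_n in band)`` and after m iterations the band
    residual is B minus the band energy already extracted.
    """
    if mp.M < 1:
        raise ValueError("decomposition has no iterations")
    if mp.signal_energy == 0:
        raise ValueError("signal energy is zero")
    if band == "total":
        return float(np.mean(mp.residual_energy[1:]) / mp.signal_energy)
    bands = _atom_bands(mp)
    in_band = np.array([b == band for b in bands])
    e = mp.coefficients**2
    band_total = float(e[in_band].sum())
    extracted = np.cumsum(np.where(in_band, e, 0.0))
    band_residual = band_total - extracted
    return float(np.mean(band_residual) / mp.signal_energy)


def band_subsignal(mp: MPResult, band: str) -> np.ndarray:
    """Reconstruction restricted to atoms whose centre frequency is in ``band``."""
    idx = [i for i, b in enumerate(_atom_bands(mp)) if b == band]
    if not idx:
        n = mp.atoms[0].waveform.size if mp.atoms else 0
        return np.zeros(n)
    return reconstruct(mp, idx)


def welch_psd(
    x: np.ndarray,
    fs: float,
    seg_len: int = 256,
    overlap: float = 0.5,
    window: str = "boxcar",
) -> WelchSpec:
    """Welch-averaged one-sided periodogram (density scaling, no detrend)."""
    x = np.asarray(x, dtype=float)
    if seg_len > x.size:
        raise ValueError("seg_len exceeds signal length")
    f, pxx = welch(
        x, fs=fs, window=window, nperseg=seg_len,
        noverlap=int(round(overlap * seg_len)), detrend=False,
        scaling="density",
    )
    return WelchSpec(frequencies=f, power=pxx, seg_len=seg_len,
                     overlap=overlap, window=window)


def _band_power(spec: WelchSpec, band: str) -> float:
    from .gabor_mp import BAND_EDGES_HZ

    lo, hi = BAND_EDGES_HZ[band]
    sel = (spec.frequencies >= lo) & (
        (spec.frequencies < hi) | ((band == "HF") & (spec.frequencies == hi))
    )
    if not np.any(sel):
        return 0.0
    df = spec.frequencies[1] - spec.frequencies[0]
    return float(spec.power[sel].sum() * df)


def psd_features(
    mp: MPResult, seg_len: int = 256, overlap: float = 0.5, window: str = "boxcar"
) -> tuple[float, float, float, float, float]:
    """(VLF, LF, HF, HF/VLF, HF+LF) band powers from per-band subsignals.

    Powers are integrated over the band's bins of the Welch spectrum of the
    corresponding subsignal and divided by the segment variance
    (signal energy / n), making them scale-free; the ratio is formed from
    the normalised powers (identical to the raw ratio when VLF > 0).
    """
    n = mp.atoms[0].waveform.size if mp.atoms else 0
    variance = mp.signal_energy / n
    powers = {}
    for band in ("VLF", "LF", "HF"):
        sub = band_subsignal(mp, band)
        if not np.any(sub):
            powers[band] = 0.0
            continue
        spec = welch_psd(sub, fs=mp.fs, seg_len=seg_len,
                         overlap=overlap, window=window)
        powers[band] = _band_power(spec, band) / variance
    hf_over_vlf = _safe_ratio(powers["HF"], powers["VLF"])
    return (
        powers["VLF"], powers["LF"], powers["HF"],
        hf_over_vlf, powers["HF"] + powers["LF"],
    )


def mp_entropy(mp: MPResult, band: str) -> float:
    """Entropy (bits) of the per-atom energy distribution, restricted to ``band``.

    Probabilities are normalised globally over all M atoms
    (p_n = c_n^2 / sum c^2); the band restricts only the summation, so a
    band holding all the energy in one atom scores 0 and a band holding
    the whole signal spread over m equal atoms scores log2(m).
    """
    if mp.M < 1:
        raise ValueError("decomposition has no atoms")
    e = mp.coefficients**2
    total = e.sum()
    if total == 0:
        raise ValueError("total extracted energy is zero")
    p = e / total
    in_band = np.array([b == band for b in _atom_bands(mp)])
    p_band = p[in_band & (p > 0)]
    if p_band.size == 0:
        return 0.0
    return float(-(p_band * np.log2(p_band)).sum())


def freq_distribution(mp: MPResult, band: str) -> float:
    """Fraction of atoms whose centre frequency lies in ``band``."""
    if mp.M < 1:
        raise ValueError("decomposition has no atoms")
    bands = _atom_bands(mp)
    return sum(b == band for b in bands) / mp.M


def extract_features(
    x: UniformHRV,
    dictionary=None,
    M: int = 30,
    seg_len: int = 256,
    overlap: float = 0.5,
    window: str = "boxcar",
) -> pd.Series:
    """Decompose a segment and compute the 16 features in fixed order.

    Returns a pandas Series indexed by :data:`FEATURE_NAMES`, named after
    the segment's subject id, with the class label in ``attrs['label']``.
    """
    if dictionary is None:
        dictionary = build_dictionary(x.n)
    mp = mp_decompose(x.values, dictionary, M=M, fs=x.fs)
    return features_from_mp(
        mp, seg_len=seg_len, overlap=overlap, window=window,
        segment_id=x.subject_id, label=x.label,
    )


def features_from_mp(
    mp: MPResult,
    seg_len: int = 256,
    overlap: float = 0.5,
    window: str = "boxcar",
    segment_id: str = "",
    label: str = "unknown",
) -> pd.Series:
    """The 16-feature vector of an existing decomposition."""
    e_vlf = mean_energy_decay(mp, "VLF")
    e_lf = mean_energy_decay(mp, "LF")
    e_hf = mean_energy_decay(mp, "HF")
    e_tot = mean_energy_decay(mp, "total")
    vlf, lf, hf, hf_over_vlf, hf_plus_lf = psd_features(
        mp, seg_len=seg_len, overlap=overlap, window=window
    )
    hw_lf = mp_entropy(mp, "LF")
    hw_hf = mp_entropy(mp, "HF")
    d_vlf = freq_distribution(mp, "VLF")
    d_lf = freq_distribution(mp, "LF")
    d_hf = freq_distribution(mp, "HF")
    values = [
        e_vlf, e_lf, e_hf, e_tot,
        vlf, lf, hf, hf_over_vlf, hf_plus_lf,
        hw_lf, hw_hf,
        d_lf, d_hf,
        _safe_ratio(d_hf, d_vlf), _safe_ratio(d_vlf, d_lf), _safe_ratio(d_lf, d_hf),
    ]
    out = pd.Series(values, index=FEATURE_NAMES, name=segment_id or None)
    out.attrs["label"] = label
    return out


def extract_feature_table(
    series_list,
    start_index: int = 0,
    length: int = 256,
    n_out: int = 1024,
    lam: float = 500.0,
    M: int = 30,
    dictionary=None,
    return_mp: bool = False,
):
    """Preprocess and featurise a list of RR series into one table.

    Returns a DataFrame with columns ``segment_id``, ``label`` and the 16
    features; with ``return_mp=True`` also the list of MPResult objects.
    """
    from .preprocessing import preprocess

    if dictionary is None:
        dictionary = build_dictionary(n_out)
    rows, mps = [], []
    for rr in series_list:
        seg = preprocess(rr, start_index=start_index, length=length,
                         n_out=n_out, lam=lam)
        mp = mp_decompose(seg.values, dictionary, M=M, fs=seg.fs)
        vec = features_from_mp(mp, segment_id=seg.subject_id, label=seg.label)
        row = {"segment_id": seg.subject_id, "label": seg.label}
        row.update(vec.to_dict())
        rows.append(row)
        mps.append(mp)
    table = pd.DataFrame(rows, columns=["segment_id", "label"] + FEATURE_NAMES)
    if return_mp:
        return table, mps
    return table
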