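"""Gabor dictionary and matching-pursuit decomposition.

A real Gabor atom is a Gaussian-windowed sinusoid

    phi(t) = A * exp(-pi * ((t - u) / s)**2) * cos(w * (t - u) + phi0)

with scale ``s`` (samples), translation ``u`` (samples), frequency ``w``
(radians per sample) and phase ``phi0``, normalised so ``||phi||_2 = 1``.
Matching pursuit (MP) greedily expands a signal over an overcomplete family
of such atoms: at each iteration the atom with the largest absolute inner
product with the current residual is selected and subtracted, and the
residual energy after every iteration is recorded.  Signals dominated by a
few oscillatory components ("coherent" structure) lose their energy in a
handful of iterations; noise-like signals decay slowly — the contrast that
the downstream heart-rate-variability features exploit.

The dictionary follows the canonical dyadic discretisation: scales
``s = 2**j`` for ``j = 1..log2(n)``, translations on a grid of spacing
``s / 2`` and frequencies ``w = k * pi / s`` for ``k = 0..s``.  Instead of
gridding the phase, each (s, u, w) triple is handled through its quadrature
pair (cosine and sine atoms): the optimal phase is obtained analytically by
projecting the residual onto the 2-D span of the pair, which is exact and
equivalent to a dense phase grid.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BAND_EDGES_HZ",
    "GaborAtom",
    "Dictionary",
    "MPResult",
    "gabor_waveform",
    "build_dictionary",
    "mp_decompose",
    "reconstruct",
    "atom_band",
    "export_decomposition",
]

#: Standard short-term HRV frequency bands in Hz (half-open on the right,
#: except HF which includes its upper edge).
BAND_EDGES_HZ: dict[str, tuple[float, float]] = {
    "VLF": (0.003, 0.04),
    "LF": (0.04, 0.15),
    "HF": (0.15, 0.4),
}

# Residual energy (relative to the signal energy) below which the greedy
# loop stops early: the signal is numerically exhausted.
_RESIDUAL_FLOOR = 1e-13

# Threshold on the norm of the sine atom component orthogonal to the cosine
# atom, below which the quadrature pair degenerates to a single direction
# (w = 0 or w = pi on an integer grid).
_DEGENERATE_TOL = 1e-10


@dataclass(frozen=True)
class GaborAtom:
    """A selected Gabor atom: parameters plus its unit-norm waveform."""

    s: float  # scale, samples
    u: float  # translation, samples
    w: float  # frequency, radians per sample, in [0, pi]
    phi: float  # phase, radians
    waveform: np.ndarray = field(repr=False, compare=False)

    def freq_hz(self, fs: float) -> float:
        """Centre frequency in Hz for a signal sampled at ``fs`` Hz."""
        return self.w * fs / (2.0 * np.pi)


@dataclass(frozen=True)
class Dictionary:
    """Dyadic Gabor family for signals of length ``n``.

    ``s``, ``u``, ``w`` are parallel arrays of the (scale, translation,
    frequency) triples; ``quadrature`` holds, for triple ``i``, the
    orthonormalised cosine/sine pair in rows ``2 i`` and ``2 i + 1`` (the
    second row is zero when the pair is degenerate).  ``meta`` records the
    atom count per scale.
    """

    n: int
    s: np.ndarray
    u: np.ndarray
    w: np.ndarray
    quadrature: np.ndarray = field(repr=False)
    meta: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.s.size


@dataclass
class MPResult:
    """Outcome of a matching-pursuit run.

    ``residual_energy`` has length ``M + 1`` where ``M`` is the number of
    iterations actually performed; element ``m`` is the residual energy
    after ``m`` iterations (element 0 is the signal energy).
    """

    coefficients: np.ndarray
    atoms: list[GaborAtom]
    residual_energy: np.ndarray
    signal_energy: float
    fs: float

    @property
    def M(self) -> int:
        return len(self.atoms)


def gabor_waveform(
    s: float, u: float, w: float, phi: float, n: int
) -> np.ndarray:
    """Sample a unit-norm Gabor atom on ``t = 0 .. n - 1``.

    Raises ``ValueError`` for non-positive scale, out-of-range translation
    or a parameter combination whose sampled waveform is identically zero.
    """
    if s <= 0:
        raise ValueError(f"scale must be positive, got {s}")
    if not (0 <= u < n):
        raise ValueError(f"translation must lie in [0, n), got {u}")
    t = np.arange(n, dtype=float)
    tau = t - u
    g = np.exp(-np.pi * (tau / s) ** 2) * np.cos(w * tau + phi)
    norm = np.linalg.norm(g)
    if norm == 0.0:
        raise ValueError("parameters yield an identically zero waveform")
    return g / norm


def _scale_grid(n: int) -> list[int]:
    return [2**j for j in range(1, int(np.log2(n)) + 1)]


@functools.lru_cache(maxsize=4)
def build_dictionary(n: int = 1024) -> Dictionary:
    """Build the dyadic Gabor dictionary for signal length ``n``.

    ``n`` must be a power of two, at least 8.  The dictionary is
    overcomplete: roughly ``2 n log2(n)`` (scale, translation, frequency)
    triples, each carrying an analytically phase-optimised quadrature pair.
    Results are cached per ``n`` (the matrices are large and immutable).
    """
    if n < 8:
        raise ValueError("dictionary requires n >= 8")
    if n & (n - 1):
        raise ValueError("dictionary requires n to be a power of two")

    t = np.arange(n, dtype=float)
    scales: list[np.ndarray] = []
    trans: list[np.ndarray] = []
    freqs: list[np.ndarray] = []
    blocks: list[np.ndarray] = []
    meta: dict = {"scales": {}}

    for s in _scale_grid(n):
        us = np.arange(0, n, s // 2, dtype=float)
        ws = np.pi * np.arange(s + 1, dtype=float) / s
        n_u, n_w = us.size, ws.size

        tau = t[None, :] - us[:, None]  # (n_u, n)
        env = np.exp(-np.pi * (tau / s) ** 2)
        phase = ws[None, :, None] * tau[:, None, :]  # (n_u, n_w, n)
        gc = (env[:, None, :] * np.cos(phase)).reshape(n_u * n_w, n)
        gs = (env[:, None, :] * np.sin(phase)).reshape(n_u * n_w, n)

        # Orthonormalise each cosine/sine pair (Gram-Schmidt).
        n1 = np.linalg.norm(gc, axis=1)
        q1 = gc / n1[:, None]
        p = np.einsum("ij,ij->i", q1, gs)
        gs_perp = gs - p[:, None] * q1
        r = np.linalg.norm(gs_perp, axis=1)
        q2 = np.zeros_like(gs)
        ok = r > _DEGENERATE_TOL
        q2[ok] = gs_perp[ok] / r[ok, None]

        block = np.empty((2 * n_u * n_w, n))
        block[0::2] = q1
        block[1::2] = q2
        blocks.append(block)

        ss, uu = np.broadcast_arrays(
            np.full((n_u, n_w), float(s)), us[:, None] + 0.0 * ws[None, :]
        )
        ww = np.broadcast_to(ws[None, :], (n_u, n_w))
        scales.append(ss.ravel())
        trans.append(uu.ravel())
        freqs.append(np.ascontiguousarray(ww).ravel())
        meta["scales"][s] = n_u * n_w

    quadrature = np.vstack(blocks)
    d = Dictionary(
        n=n,
        s=np.concatenate(scales),
        u=np.concatenate(trans),
        w=np.concatenate(freqs),
        quadrature=quadrature,
        meta=meta,
    )
    assert d.n_atoms > n, "dictionary must be overcomplete"
    return d


def _best_phase_atom(
    residual: np.ndarray, s: float, u: float, w: float, n: int
) -> GaborAtom:
    """Atom of the (s, u, w) triple whose phase maximises |<R, atom>|."""
    t = np.arange(n, dtype=float)
    tau = t - u
    env = np.exp(-np.pi * (tau / s) ** 2)
    gc = env * np.cos(w * tau)
    gs = env * np.sin(w * tau)

    gcc = gc @ gc
    gss = gs @ gs
    gcs = gc @ gs
    bc = gc @ residual
    bs = gs @ residual

    det = gcc * gss - gcs * gcs
    if gss < _DEGENERATE_TOL**2 or det < _DEGENERATE_TOL * gcc * max(gss, 1e-300):
        alpha, beta = bc / gcc, 0.0
    else:
        alpha = (gss * bc - gcs * bs) / det
        beta = (gcc * bs - gcs * bc) / det
    phi = float(-np.arctan2(beta, alpha))
    return GaborAtom(
        s=float(s), u=float(u), w=float(w), phi=phi,
        waveform=gabor_waveform(s, u, w, phi, n),
    )


def mp_decompose(
    x: np.ndarray, dictionary: Dictionary, M: int = 30, fs: float = 4.0
) -> MPResult:
    """Greedy matching pursuit of ``x`` over ``dictionary``.

    At each of up to ``M`` iterations the (s, u, w) triple maximising the
    phase-optimised projection of the residual is selected (ties broken by
    lowest atom index), its coefficient ``c = <R, atom>`` recorded, and
    ``c * atom`` subtracted from the residual.  Stops early once the
    residual energy falls below ``1e-13`` of the signal energy.

    ``fs`` is carried through to the result so downstream band logic can
    convert atom frequencies to Hz.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != dictionary.n:
        raise ValueError(
            f"signal length {x.size} does not match dictionary n={dictionary.n}"
        )
    signal_energy = float(x @ x)
    if signal_energy == 0.0:
        raise ValueError("cannot decompose an identically zero signal")

    residual = x.copy()
    res_energy = [signal_energy]
    coeffs: list[float] = []
    atoms: list[GaborAtom] = []

    for _ in range(M):
        if res_energy[-1] <= _RESIDUAL_FLOOR * signal_energy:
            break
        proj = dictionary.quadrature @ residual
        power = proj[0::2] ** 2 + proj[1::2] ** 2
        idx = int(np.argmax(power))  # first maximum -> lowest index on ties
        atom = _best_phase_atom(
            residual, dictionary.s[idx], dictionary.u[idx], dictionary.w[idx],
            dictionary.n,
        )
        c = float(residual @ atom.waveform)
        if c == 0.0:
            break
        residual -= c * atom.waveform
        coeffs.append(c)
        atoms.append(atom)
        res_energy.append(float(residual @ residual))

    return MPResult(
        coefficients=np.array(coeffs),
        atoms=atoms,
        residual_energy=np.array(res_energy),
        signal_energy=signal_energy,
        fs=float(fs),
    )


def reconstruct(mp: MPResult, which="all") -> np.ndarray:
    """Sum ``c_i * atom_i`` over ``which`` (index iterable or ``"all"``)."""
    n = mp.atoms[0].waveform.size if mp.atoms else 0
    if isinstance(which, str):
        if which != "all":
            raise ValueError(f"unknown subset spec {which!r}")
        idx = range(len(mp.atoms))
    else:
        idx = list(which)
        if any(i < 0 or i >= len(mp.atoms) for i in idx):
            raise IndexError("atom index out of range")
    out = np.zeros(n)
    for i in idx:
        out += mp.coefficients[i] * mp.atoms[i].waveform
    return out


def atom_band(atom: GaborAtom, fs: float) -> str:
    """Band tag ('VLF' | 'LF' | 'HF' | 'none') of the atom's centre frequency."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    f = atom.freq_hz(fs)
    for band, (lo, hi) in BAND_EDGES_HZ.items():
        if (lo <= f < hi) or (band == "HF" and f == hi):
            return band
    return "none"


def export_decomposition(mp: MPResult, path) -> None:
    """Write a decomposition as CSV (one row per iteration) for inspection."""
    import pandas as pd

    rows = []
    for i, (c, a) in enumerate(zip(mp.coefficients, mp.atoms), start=1):
        rows.append(
            {
                "iteration": i,
                "coefficient": c,
                "s": a.s,
                "u": a.u,
                "w_hz": a.freq_hz(mp.fs),
                "phi": a.phi,
                "band": atom_band(a, mp.fs),
                "residual_energy": mp.residual_energy[i],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
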