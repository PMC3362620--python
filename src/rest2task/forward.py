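"""Analytic single-sphere dipole forward model.

Surface potential of a current dipole inside a homogeneous conducting
sphere (insulating exterior), evaluated by its spherical-harmonic series

    V(r_e) = 1/(4 pi sigma a^2) * sum_{n>=1} (2n+1)/n * (b/a)^(n-1)
             * [ n * m_r * P_n(cos g) + m_t * P_n^1(cos g) ]

where ``b`` is the dipole eccentricity, ``g`` the angle between dipole
position and electrode, ``m_r``/``m_t`` the radial/tangential moment
components in the plane spanned by the two, and ``P_n^1`` the associated
Legendre function without the Condon-Shortley phase.  The series converges
geometrically for b < a; truncation at n = 60 leaves a relative tail below
1e-4 for b <= 0.9.  For a central dipole it reduces to the closed form
V = 3 (m . r_hat) / (4 pi sigma a^2), which serves as a sanity anchor.

All quantities are in head-frame units: sphere radius a = 1, conductivity
sigma = 1, electrode positions on the unit sphere.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import eval_legendre, lpmv

_N_TERMS = 60
_K = 1.0 / (4.0 * np.pi)  # 1/(4 pi sigma a^2) with sigma = a = 1


def _series_coeffs(b: float) -> np.ndarray:
    n = np.arange(1, _N_TERMS + 1)
    return b ** (n - 1.0)


def gain_matrix(location: np.ndarray, montage: np.ndarray) -> np.ndarray:
    """Lead field of a dipole at ``location``: (n_electrodes, 3) matrix ``G``
    with ``V = G @ moment`` for any Cartesian moment vector.

    ``montage`` rows must lie on the unit sphere; ``|location|`` must be < 1.
    """
    loc = np.asarray(location, dtype=float)
    el = np.asarray(montage, dtype=float)
    b = float(np.linalg.norm(loc))
    if b >= 1.0:
        raise ValueError(f"dipole at radius {b:.3f} is not inside the unit sphere")
    if b < 1e-12:
        # central dipole: V = 3 (m . r_hat) / (4 pi)
        return 3.0 * _K * el

    rhat = loc / b
    cosg = np.clip(el @ rhat, -1.0, 1.0)
    sing = np.sqrt(np.maximum(0.0, 1.0 - cosg**2))
    # tangential unit vector at each electrode, in the (dipole, electrode) plane
    t = el - cosg[:, None] * rhat[None, :]
    tn = np.linalg.norm(t, axis=1)
    ok = tn > 1e-12
    t[ok] /= tn[ok, None]
    t[~ok] = 0.0  # P_n^1 -> 0 there, contribution vanishes

    n = np.arange(1, _N_TERMS + 1)
    coeff = _series_coeffs(b)                       # b^(n-1)
    pn = eval_legendre(n[:, None], cosg[None, :])   # (N, n_el)
    # lpmv carries the Condon-Shortley phase; the physics convention does not
    pn1 = -lpmv(1, n[:, None], cosg[None, :])
    f_r = _K * ((2 * n + 1) * coeff) @ pn           # radial-moment kernel
    f_t = _K * ((2 * n + 1) / n * coeff) @ pn1      # tangential-moment kernel
    return f_r[:, None] * rhat[None, :] + f_t[:, None] * t


def forward_gain(
    location: np.ndarray, orientation: np.ndarray, montage: np.ndarray
) -> np.ndarray:
    """Per-electrode potential of a unit-magnitude dipole (deterministic).

    ``orientation`` is normalized internally; scale the result to set the
    dipole moment.
    """
    ori = np.asarray(orientation, dtype=float)
    norm = np.linalg.norm(ori)
    if norm == 0:
        raise ValueError("orientation must be non-zero")
    return gain_matrix(location, montage) @ (ori / norm)


def default_montage() -> tuple[list[str], np.ndarray]:
    """32-channel 10-20 layout (BioSemi cap), positions on the unit sphere."""
    labels, pos = _cached_montage()
    return list(labels), pos.copy()


@lru_cache(maxsize=1)
def _cached_montage() -> tuple[tuple[str, ...], np.ndarray]:
    import mne

    m = mne.channels.make_standard_montage("biosemi32")
    ch_pos = m.get_positions()["ch_pos"]
    labels = tuple(ch_pos)
    pos = np.array([ch_pos[c] for c in labels])
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return labels, pos
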