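"""Closed-form map calculations: MTsat, R2*-corrected MTV, dry-wet MTV.

All three operate elementwise and broadcast over full volumes; NaN inputs
propagate to NaN outputs (invalid voxels stay invalid).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["compute_mtsat", "correct_mtv_r2star", "mtv_from_dry_wet"]


def compute_mtsat(s_mt, m0, b1, alpha, tr, r1):
    """Magnetization-transfer saturation from SPGR quantities.

        MTsat = M0 * B1 * alpha * (R1 * TR) / S_MT - (B1 * alpha)^2 / 2 - R1 * TR

    Parameters
    ----------
    s_mt : array_like
        Signal of the SPGR scan with the additional MT pulse (arbitrary
        units, same scale as ``m0``).
    m0 : array_like
        Equilibrium magnetization (same arbitrary units).
    b1 : array_like
        Transmit-field scale (dimensionless, nominal 1).
    alpha : float
        Nominal excitation flip angle in **radians** (CLI accepts degrees).
    tr : float
        Repetition time in seconds.
    r1 : array_like
        Longitudinal relaxation rate in s^-1.

    Notes
    -----
    Jointly scaling ``m0`` and ``s_mt`` leaves the result unchanged (degree-0
    homogeneity).  Values below the physical floor -R1*TR are returned
    as-is but flagged with a warning; nothing is clamped.
    """
    s_mt = np.asarray(s_mt, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    if np.any(s_mt[np.isfinite(s_mt)] <= 0):
        raise ValueError("S_MT must be positive")
    if np.any(b1[np.isfinite(b1)] <= 0):
        raise ValueError("B1 must be positive")
    if not 0 < alpha < np.pi / 2:
        raise ValueError("alpha must be in (0, pi/2) radians")
    if tr <= 0:
        raise ValueError("TR must be positive")
    out = m0 * b1 * alpha * (r1 * tr) / s_mt - (b1 * alpha) ** 2 / 2.0 - r1 * tr
    floor = -r1 * tr
    bad = np.asarray(out < floor)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} MTsat value(s) below the physical floor -R1*TR",
            stacklevel=2,
        )
    return out if out.ndim else float(out)


def correct_mtv_r2star(mtv, r2star, te):
    """Correct MTV estimates for the R2*-induced signal decay at echo time TE.

        MTV_C = 1 - (1 - MTV) * exp(TE * R2*)

    ``te`` in seconds, ``r2star`` in s^-1.  Identity at R2* = 0 and strictly
    decreasing in TE*R2*; for large TE*R2* the corrected value can go
    negative — it is returned as-is with a warning, never clamped.
    """
    mtv = np.asarray(mtv, dtype=float)
    r2star = np.asarray(r2star, dtype=float)
    fin = np.isfinite(mtv)
    if np.any(mtv[fin] < 0) or np.any(mtv[fin] >= 1):
        raise ValueError("MTV must lie in [0, 1)")
    if np.any(r2star[np.isfinite(r2star)] < 0):
        raise ValueError("R2* must be nonnegative")
    if te <= 0:
        raise ValueError("TE must be positive")
    out = 1.0 - (1.0 - mtv) * np.exp(te * r2star)
    neg = np.asarray(out < 0) & np.isfinite(out)
    if neg.any():
        warnings.warn(
            f"{int(neg.sum())} corrected MTV value(s) negative (large TE*R2*)",
            stacklevel=2,
        )
    return out if out.ndim else float(out)


def mtv_from_dry_wet(w_wet, w_dry, convention: str = "AS_PRINTED"):
    """Tissue fraction from desiccation (dry-wet) weights.

    ``AS_PRINTED`` returns (W_wet - W_dry) / W_wet, the water mass fraction
    as conventionally printed; ``NON_WATER`` returns W_dry / W_wet, the
    non-water mass fraction that MTV denotes elsewhere.  The two sum to 1.
    """
    w_wet = np.asarray(w_wet, dtype=float)
    w_dry = np.asarray(w_dry, dtype=float)
    if np.any(w_wet <= 0):
        raise ValueError("wet weight must be positive")
    if np.any(w_dry <= 0) or np.any(w_dry > w_wet):
        raise ValueError("require 0 < W_dry <= W_wet")
    if convention == "AS_PRINTED":
        out = (w_wet - w_dry) / w_wet
    elif convention == "NON_WATER":
        out = w_dry / w_wet
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return out if out.ndim else float(out)
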