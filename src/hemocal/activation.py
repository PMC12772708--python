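"""Normalized ventricular activation shapes for time-varying elastance chambers.

An activation function maps the phase within the heart period to a value in
[0, 1]; chamber elastance is E_min + (E_max - E_min) * activation.  Shapes are
registered by name so chamber parameters stay fully serializable.
"""
from __future__ import annotations

import numpy as np

__all__ = ["activation_value", "ACTIVATION_LAWS"]


def _cosine(phase: np.ndarray, systolic_fraction: float) -> np.ndarray:
    """Shifted-cosine bump: 0 at onset, 1 at mid-systole, 0 after systole.

    Continuous and continuously differentiable (the sine-valued derivative
    vanishes at both ends of the activation window).
    """
    tau = np.asarray(phase, dtype=float)
    act = np.where(
        tau < systolic_fraction,
        0.5 * (1.0 - np.cos(2.0 * np.pi * np.minimum(tau, systolic_fraction)
                            / systolic_fraction)),
        0.0,
    )
    return act


ACTIVATION_LAWS = {"cosine": _cosine}


def activation_value(t, period: float, onset_fraction: float,
                     systolic_fraction: float, law: str = "cosine"):
    """Evaluate the periodic activation at time(s) ``t`` (seconds)."""
    if period <= 0:
        raise ValueError("period must be positive")
    if not 0.0 < systolic_fraction < 1.0:
        raise ValueError("systolic_fraction must lie in (0, 1)")
    phase = (np.asarray(t, dtype=float) / period - onset_fraction) % 1.0
    out = ACTIVATION_LAWS[law](phase, systolic_fraction)
    if np.ndim(t) == 0:
        return float(out)
    return out
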