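"""Rate laws and regulatory transfer functions for the hepatocyte model.

All enzymatic rate laws are homogeneous of degree one in their maximal
activity, so scaling every Vmax by a common factor scales every steady-state
flux by the same factor while leaving metabolite concentrations unchanged.
That property underpins the proteome-to-capacity scaling used throughout.

Hormonal control is collapsed into a single phenomenological phosphorylation
state gamma in [0, 1]: gamma -> 1 in the fasted (glucagon-dominated) state,
gamma -> 0 in the fed (insulin-dominated) state.  A phospho-sensitive enzyme
runs at ``gamma * v_phospho + (1 - gamma) * v_dephospho`` times its Vmax.
"""

from __future__ import annotations

import numpy as np
from scipy.constants import R as GAS_CONSTANT  # J/(mol K)
from scipy.constants import physical_constants

FARADAY = physical_constants["Faraday constant"][0]  # C/mol

__all__ = [
    "gamma_of_glucose",
    "fa_of_glucose",
    "ghk_flux",
    "phospho_activity",
]


def gamma_of_glucose(glucose, g_half: float = 6.0, hill: float = 4.0):
    """Phosphorylation state of interconvertible enzymes vs plasma glucose.

    gamma = 1 / (1 + (glucose / g_half)**hill), strictly decreasing in
    glucose: low glucose (fasting, high glucagon) drives gamma toward 1,
    high glucose (fed, high insulin) toward 0.

    Parameters
    ----------
    glucose : float or array, mM. Must be >= 0.
    g_half : glucose at which gamma = 0.5, mM.
    hill : steepness exponent (> 0).
    """
    glucose = np.asarray(glucose, dtype=float)
    if np.any(glucose < 0):
        raise ValueError("plasma glucose must be non-negative")
    if g_half <= 0 or hill <= 0:
        raise ValueError("g_half and hill must be positive")
    out = 1.0 / (1.0 + (glucose / g_half) ** hill)
    return float(out) if out.ndim == 0 else out


def fa_of_glucose(
    glucose,
    fed_plateau: float = 0.2,
    fasted_plateau: float = 1.0,
    g_half: float = 6.0,
    hill: float = 4.0,
):
    """Plasma free-fatty-acid concentration tied to plasma glucose (mM).

    Fasting (low glucose) means lipolysis and high plasma FFA; feeding
    suppresses FFA.  Implemented as a descending Hill sigmoid between the
    fasted and fed plateaus; at ``glucose == g_half`` the value is exactly
    the mean of the two plateaus.
    """
    glucose = np.asarray(glucose, dtype=float)
    if np.any(glucose < 0):
        raise ValueError("plasma glucose must be non-negative")
    if not (0 < fed_plateau < fasted_plateau):
        raise ValueError("require 0 < fed_plateau < fasted_plateau")
    frac = 1.0 / (1.0 + (glucose / g_half) ** hill)
    out = fed_plateau + (fasted_plateau - fed_plateau) * frac
    return float(out) if out.ndim == 0 else out


def ghk_flux(P: float, z: float, V: float, c_in, c_out, T: float = 310.0):
    """Goldman-Hodgkin-Katz constant-field flux across a charged membrane.

    J = P * u * (c_in - c_out * exp(-u)) / (1 - exp(-u)),  u = z F V / (R T)

    with P a permeability (flux units per mM), V the membrane potential in
    volts and concentrations in mM.  The apparent singularity at V = 0 is
    removed analytically: for |u| < 1e-8 the limit J = P * (c_in - c_out)
    is used (relative error of the truncation below 1e-8).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    u = z * FARADAY * V / (GAS_CONSTANT * T)
    c_in = np.asarray(c_in, dtype=float)
    c_out = np.asarray(c_out, dtype=float)
    if abs(u) < 1e-8:
        # first-order series around u = 0: J = P*[(c_in-c_out) + u*(c_in+c_out)/2]
        out = P * ((c_in - c_out) + 0.5 * u * (c_in + c_out))
    else:
        em = np.exp(-u)
        out = P * u * (c_in - c_out * em) / (1.0 - em)
    if np.ndim(out) == 0:
        return float(out)
    return out


def phospho_activity(gamma: float, v_phospho: float, v_dephospho: float) -> float:
    """Relative activity of a phospho-sensitive enzyme at state gamma."""
    return gamma * v_phospho + (1.0 - gamma) * v_dephospho
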