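"""Wet-lab validation arithmetic: qPCR ddCT fold change and percent viability."""

from __future__ import annotations

import numpy as np

from .datatypes import ValidationError


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCT method.

    dCT = Ct(target) - Ct(reference) within each condition; ddCT is the case
    dCT minus the control dCT; fold change = 2^-ddCT. Replicates should be
    averaged on the Ct scale before calling.
    """
    cts = [ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl]
    if not all(np.isfinite(c) for c in cts):
        raise ValidationError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0**-ddct)


def percent_viability(treated_readouts, vehicle_readouts) -> dict[str, float]:
    """Viability of treated wells as a percentage of vehicle-only wells.

    Returns the mean percent plus the replicate standard deviation of the
    treated wells expressed on the same percent scale.
    """
    treated = np.asarray(treated_readouts, dtype=float)
    vehicle = np.asarray(vehicle_readouts, dtype=float)
    if treated.size == 0 or vehicle.size == 0:
        raise ValidationError("empty readout vector")
    v_mean = vehicle.mean()
    if v_mean <= 0:
        raise ValidationError("vehicle mean must be positive")
    return {
        "percent": float(100.0 * treated.mean() / v_mean),
        "sd": float(100.0 * treated.std(ddof=1) / v_mean) if treated.size > 1 else 0.0,
        "n": int(treated.size),
    }
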