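"""Relative qPCR quantification by the 2^-ddCt (Livak) method.

Expression of a target gene is normalized to a reference gene (here
GAPDH) within each condition, then the treated condition is referenced
to the control: ``ddCt = (Ct_target - Ct_ref)_treated -
(Ct_target - Ct_ref)_control`` and the relative quantity is
``RQ = 2^-ddCt``.  RQ < 1 means downregulation under treatment (each
extra cycle is a twofold deficit); amplification efficiency is fixed at
2, as the method's name implies.  Replicate Ct lists are averaged on the
Ct scale per condition before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class RelQuantResult:
    delta_ct_treated: float
    delta_ct_control: float
    delta_delta_ct: float
    rq: float


def _mean_ct(value: float | Sequence[float], label: str) -> float:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 0:
        raise ValueError(f"empty Ct replicate list for {label}")
    if not np.isfinite(arr).all() or (arr <= 0).any():
        raise ValueError(f"Ct values for {label} must be finite and positive")
    return float(arr.mean())


def ddct(ct_target_treated: float | Sequence[float],
         ct_ref_treated: float | Sequence[float],
         ct_target_control: float | Sequence[float],
         ct_ref_control: float | Sequence[float]) -> RelQuantResult:
    """2^-ddCt relative quantification of a target vs. reference gene.

    Accepts scalar Ct values or per-replicate lists (averaged per
    condition).  ``log2(rq) == -ddCt`` exactly, and swapping treated with
    control inverts ``rq``.
    """
    d_treated = _mean_ct(ct_target_treated, "target/treated") - \
        _mean_ct(ct_ref_treated, "reference/treated")
    d_control = _mean_ct(ct_target_control, "target/control") - \
        _mean_ct(ct_ref_control, "reference/control")
    ddct_val = d_treated - d_control
    return RelQuantResult(delta_ct_treated=d_treated,
                          delta_ct_control=d_control,
                          delta_delta_ct=ddct_val,
                          rq=float(2.0 ** (-ddct_val)))
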