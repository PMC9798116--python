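"""Bench-side calculators: 2^-dCt relative expression and colorimetric
m6A ELISA percent quantification.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .errors import AssayError

logger = logging.getLogger(__name__)


def _mean_ct(ct: float | Sequence[float], label: str) -> float:
    """Average technical duplicates; a scalar passes through."""
    arr = np.atleast_1d(np.asarray(ct, dtype=float))
    if arr.size == 0 or not np.isfinite(arr).all():
        raise AssayError(f"non-finite or empty {label} Ct value(s): {ct!r}")
    return float(arr.mean())


def ddct_relative_expression(ct_target, ct_reference) -> float:
    """Relative expression of a target vs an internal reference, 2^-(dCt).

    dCt = Ct(target) - Ct(reference); each argument may be a scalar or a
    sequence of technical replicates, which are arithmetically averaged
    before the formula. Strictly decreasing in ct_target.
    """
    dct = _mean_ct(ct_target, "target") - _mean_ct(ct_reference, "reference")
    return float(2.0 ** (-dct))


def elisa_m6a_percent(
    od_sample: float,
    od_nc: float,
    od_pc: float,
    s_ng: float = 200.0,
    p_ng: float = 10.0,
) -> float:
    """Percent m6A in total RNA from OD450 readings (kit slope-ratio convention).

        percent = [(OD_sample - OD_nc) / S] / [(OD_pc - OD_nc) / P] * 100

    where S is the sample RNA input (default 200 ng, the standard test-well
    load) and P the positive-control amount in ng. A blank-subtracted OD
    below zero is clipped to 0 with a warning.
    """
    if not all(np.isfinite([od_sample, od_nc, od_pc])):
        raise AssayError("non-finite OD reading")
    if od_pc <= od_nc:
        raise AssayError(
            f"calibration error: positive-control OD ({od_pc}) must exceed "
            f"negative-control OD ({od_nc})"
        )
    if s_ng <= 0 or p_ng <= 0:
        raise AssayError(f"RNA amounts must be positive: s_ng={s_ng}, p_ng={p_ng}")
    signal = od_sample - od_nc
    if signal < 0:
        logger.warning("blank-subtracted OD %.4f below zero; clipped to 0", signal)
        signal = 0.0
    slope_sample = signal / s_ng
    slope_pc = (od_pc - od_nc) / p_ng
    return float(slope_sample / slope_pc * 100.0)
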