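"""Spike-in normalization and the detection-flag retention filter.

Each sample/channel is rescaled by a single factor so that its median spike-in
intensity equals a common target, which removes array-to-array and dye-channel
scale differences while preserving relative structure within a channel. Probes
detected (flag P or M) in at least ``min_pm`` samples form the retained
"all targets" set carried into quantification; with the study design of nine
arrays the default threshold is 3 of 9.

All derived quantities downstream are computed on normalized *linear*
intensities; log2 enters only inside the statistical tests and fold-change
reporting. A percentage of modification is only meaningful on the linear scale.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, NormalizationError
from .io import IntensityTable


def normalize_spikein(table: IntensityTable, target: float = 1000.0) -> IntensityTable:
    """Rescale every sample x channel so the spike-in median equals ``target``.

    Scale-equivariant: multiplying one channel of one sample by any positive
    constant before normalization does not change the output.
    """
    if target <= 0:
        raise ConfigError(f"spikein_target must be positive, got {target}")
    spike = table.is_spikein
    if not spike.any():
        raise NormalizationError("no spike-in probes in table")
    out = table.copy()
    for channel in (out.ip, out.sup):
        medians = channel.loc[spike].median(axis=0)
        if (medians <= 0).any():
            sample = medians.index[(medians <= 0).argmax()]
            raise NormalizationError(
                f"non-positive spike-in median in sample {sample!r}; cannot normalize"
            )
        channel.loc[:, :] = channel.to_numpy() * (target / medians).to_numpy()
    return out


def qc_filter(table: IntensityTable, min_pm: int = 3) -> IntensityTable:
    """Retain probes flagged Present or Marginal in at least ``min_pm`` samples.

    Spike-in probes are always retained (for audit); they are excluded from
    gene-level statistics by the quantification stage.
    """
    n_samples = len(table.samples)
    if min_pm > n_samples:
        raise ConfigError(f"min_pm={min_pm} exceeds sample count {n_samples}")
    if min_pm < 0:
        raise ConfigError(f"min_pm must be non-negative, got {min_pm}")
    pm_counts = table.flags.isin(("P", "M")).sum(axis=1)
    keep = (pm_counts >= min_pm) | table.is_spikein
    keep_index = table.probes[np.asarray(keep)]
    return IntensityTable(
        ip=table.ip.loc[keep_index],
        sup=table.sup.loc[keep_index],
        flags=table.flags.loc[keep_index],
        genes=table.genes.loc[keep_index],
        is_spikein=table.is_spikein.loc[keep_index],
    )
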