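"""The three derived measures of a MeRIP (IP/Sup) microarray.

For every gene and sample, from normalized linear channel intensities:

* **methylation level** — percentage of the gene's signal in the IP fraction,
  ``100 * IP / (IP + Sup)``;
* **m6A quantity** — absolute methylated-RNA signal, the IP intensity itself;
* **expression level** — total transcript signal, ``IP + Sup``.

Multi-probe genes are aggregated channel-first: probe intensities are combined
per channel per sample (median by default) and the ratio is formed from the
aggregated channels, never by averaging per-probe percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, M6AScreenError
from .io import IntensityTable, SampleSheet, write_table

_AGGREGATES = {"median", "mean", "sum"}


def methylation_level(ip: float, sup: float) -> float:
    """Percent of signal immunoprecipitated: ``100 * ip / (ip + sup)``.

    Raises if both channels are zero — the level is undefined there and the
    gene must be reported missing, not as 0%.
    """
    if ip < 0 or sup < 0:
        raise M6AScreenError(f"negative intensity: ip={ip}, sup={sup}")
    total = ip + sup
    if total == 0:
        raise M6AScreenError("methylation level undefined for ip + sup = 0")
    return 100.0 * ip / total


@dataclass
class QuantTable:
    """Gene x sample matrices of the three derived measures.

    ``level`` is percent in [0, 100] (NaN where IP+Sup = 0); ``quantity`` and
    ``expression`` are linear intensities with ``quantity <= expression``.
    """

    level: pd.DataFrame
    quantity: pd.DataFrame
    expression: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.level.index

    @property
    def samples(self) -> list[str]:
        return list(self.level.columns)

    def measure(self, name: str) -> pd.DataFrame:
        if name not in ("level", "quantity", "expression"):
            raise KeyError(f"unknown measure {name!r}")
        return getattr(self, name)

    def group_means(self, sheet: SampleSheet, measure: str, group: str) -> pd.Series:
        """Per-gene arithmetic mean of a measure over the samples of a group."""
        return self.measure(measure)[sheet.samples_in(group)].mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.genes)
        for s in self.samples:
            out[f"level_{s}"] = self.level[s]
            out[f"quantity_{s}"] = self.quantity[s]
            out[f"expression_{s}"] = self.expression[s]
        out.index.name = "gene_symbol"
        return out

    def write(self, path) -> None:
        write_table(self.to_frame().reset_index(), path)


def compute_quant_table(
    table: IntensityTable,
    sheet: SampleSheet | None = None,
    aggregate: str = "median",
) -> QuantTable:
    """Aggregate probes to genes and derive (level, quantity, expression).

    Spike-in probes are excluded. Expects a normalized, QC-filtered table.
    """
    if aggregate not in _AGGREGATES:
        raise ConfigError(f"unknown aggregation rule {aggregate!r} (allowed: {sorted(_AGGREGATES)})")
    keep = ~table.is_spikein
    if not keep.any():
        raise M6AScreenError("intensity table contains no non-spike-in probes")
    genes = table.genes[keep]
    ip = table.ip.loc[genes.index].groupby(genes).agg(aggregate)
    sup = table.sup.loc[genes.index].groupby(genes).agg(aggregate)
    ip, sup = ip.sort_index(), sup.sort_index()

    total = ip + sup
    if (total.sum(axis=1) == 0).any():
        dead = total.index[total.sum(axis=1) == 0][0]
        raise M6AScreenError(f"gene {dead!r} has zero total intensity in every sample")
    with np.errstate(invalid="ignore", divide="ignore"):
        level = 100.0 * ip / total
    level = level.where(total > 0)  # undefined level -> NaN, not 0
    quant = QuantTable(level=level, quantity=ip, expression=total)
    if sheet is not None:
        missing = set(quant.samples) - set(sheet.samples)
        if missing:
            raise M6AScreenError(f"samples without sheet entry: {sorted(missing)}")
    return quant
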