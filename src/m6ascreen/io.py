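"""Reading and writing the interchange tables.

Two-channel epitranscriptomic arrays hybridize the immunoprecipitated
(m6A-modified, "IP") and supernatant (unmodified, "Sup") RNA fractions of each
sample. The intensity table carries both channels plus a Present/Marginal/Absent
detection flag per probe per sample; the sample sheet maps arrays to the three
spermatogenic-impairment groups in their fixed severity order OA > HP > SOMA.

Dialects (documented in the README):

* intensity table — TSV, columns ``probe_id``, ``gene_symbol``, ``is_spikein``,
  then ``IP_<sample>``, ``Sup_<sample>``, ``flag_<sample>`` per sample;
* sample sheet — CSV, columns ``sample_id``, ``group``, ``replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

#: Group labels in the fixed order used by every tendency computation:
#: obstructive azoospermia (control), hypospermatogenesis, Sertoli-cell-only /
#: maturation arrest. Severity of spermatogenic impairment increases rightward.
GROUPS: tuple[str, ...] = ("OA", "HP", "SOMA")

#: The pooled idiopathic-NOA pseudo-group (HP + SOMA samples).
INOA = "iNOA"

VALID_FLAGS = frozenset({"P", "M", "A"})

_FLOAT_FORMAT = "%.10g"


@dataclass
class IntensityTable:
    """Probe-level two-channel intensities with per-sample QC flags.

    All frames share the probe_id index and the sample columns; intensities are
    linear (never log) and non-negative.
    """

    ip: pd.DataFrame
    sup: pd.DataFrame
    flags: pd.DataFrame
    genes: pd.Series
    is_spikein: pd.Series

    @property
    def probes(self) -> pd.Index:
        return self.ip.index

    @property
    def samples(self) -> list[str]:
        return list(self.ip.columns)

    def copy(self) -> "IntensityTable":
        return IntensityTable(
            self.ip.copy(), self.sup.copy(), self.flags.copy(),
            self.genes.copy(), self.is_spikein.copy(),
        )

    def validate(self) -> None:
        if self.probes.has_duplicates:
            dup = self.probes[self.probes.duplicated()][0]
            raise ParseError(f"duplicate probe_id {dup!r}")
        for name, frame in (("IP", self.ip), ("Sup", self.sup)):
            values = frame.to_numpy()
            if not np.isfinite(values).all():
                probe, sample = _first_offender(frame, ~np.isfinite(values))
                raise ParseError(f"non-finite {name} intensity at probe {probe!r}, sample {sample!r}")
            if (values < 0).any():
                probe, sample = _first_offender(frame, values < 0)
                raise ParseError(f"negative {name} intensity at probe {probe!r}, sample {sample!r}")
        bad = ~self.flags.isin(VALID_FLAGS)
        if bad.to_numpy().any():
            probe, sample = _first_offender(self.flags, bad.to_numpy())
            raise ParseError(
                f"unknown flag {self.flags.loc[probe, sample]!r} at probe {probe!r}, "
                f"sample {sample!r} (allowed: P, M, A)"
            )


def _first_offender(frame: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return frame.index[i], frame.columns[j]


@dataclass
class SampleSheet:
    """Sample → group assignment; groups are validated against :data:`GROUPS`."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"group", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ParseError(f"sample sheet missing column(s): {sorted(missing)}")
        bad = ~self.frame["group"].isin(GROUPS)
        if bad.any():
            label = self.frame.loc[bad, "group"].iloc[0]
            raise ParseError(
                f"unknown group label {label!r} (allowed: {', '.join(GROUPS)})"
            )
        if self.frame.index.has_duplicates:
            raise ParseError("duplicate sample_id in sample sheet")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    def samples_in(self, group: str) -> list[str]:
        """Samples belonging to a group; ``iNOA`` pools HP and SOMA."""
        if group == INOA:
            sel = self.frame["group"].isin(("HP", "SOMA"))
        elif group in GROUPS:
            sel = self.frame["group"] == group
        else:
            raise KeyError(f"unknown group {group!r} (allowed: {', '.join(GROUPS)}, {INOA})")
        return list(self.frame.index[sel])

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in GROUPS}


def read_intensity_table(path: str | Path) -> IntensityTable:
    """Parse an intensity TSV into a validated :class:`IntensityTable`.

    The header must declare matching ``IP_``/``Sup_``/``flag_`` column triples;
    validation errors carry the offending probe/sample coordinates.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    for col in ("probe_id", "gene_symbol", "is_spikein"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    samples = [c[len("IP_"):] for c in frame.columns if c.startswith("IP_")]
    if not samples:
        raise ParseError(f"{path}: no IP_<sample> columns found")
    for s in samples:
        for prefix in ("Sup_", "flag_"):
            if prefix + s not in frame.columns:
                raise ParseError(f"{path}: missing column {prefix + s!r}")
    frame = frame.set_index("probe_id")
    table = IntensityTable(
        ip=frame[[f"IP_{s}" for s in samples]].rename(columns=lambda c: c[3:]).astype(float),
        sup=frame[[f"Sup_{s}" for s in samples]].rename(columns=lambda c: c[4:]).astype(float),
        flags=frame[[f"flag_{s}" for s in samples]].rename(columns=lambda c: c[5:]).astype(str),
        genes=frame["gene_symbol"],
        is_spikein=frame["is_spikein"].astype(bool),
    )
    table.validate()
    return table


def write_intensity_table(table: IntensityTable, path: str | Path) -> None:
    """Serialize to the intensity TSV dialect (deterministic column order)."""
    out = pd.DataFrame({"gene_symbol": table.genes, "is_spikein": table.is_spikein})
    for s in table.samples:
        out[f"IP_{s}"] = table.ip[s]
        out[f"Sup_{s}"] = table.sup[s]
        out[f"flag_{s}"] = table.flags[s]
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    if "sample_id" not in frame.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    return SampleSheet(frame.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def check_samples_match(table: IntensityTable, sheet: SampleSheet) -> None:
    """Every intensity-table sample must appear in the sample sheet."""
    unknown = set(table.samples) - set(sheet.samples)
    if unknown:
        raise ParseError(f"samples in intensity table but not in sample sheet: {sorted(unknown)}")


def write_table(result: pd.DataFrame, path: str | Path, *, index: bool = False) -> None:
    """Write any result frame as deterministic TSV (stable order, fixed float format)."""
    result.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT)
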