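"""Synthetic MeRIP-array experiments with known ground truth.

The generative model mirrors the two-channel measurement: a gene g in group k
has true transcript abundance T_gk (arbitrary intensity units) of which a
fraction m_gk carries the m6A mark, so the immunoprecipitated and supernatant
channels measure

    IP_gs  = T_gk * m_gk      * eps_gs
    Sup_gs = T_gk * (1 - m_gk) * eps'_gs

with eps, eps' independent multiplicative log-normal noise (standard deviation
``noise_sigma`` in log2 units, the standard intensity-noise model for
two-channel arrays — it keeps intensities positive). Spike-in probes have a
constant true intensity in both channels; detection flags are Present by
default, Marginal at a small rate, and Absent for the dimmest probe/sample
pairs plus random dropout.

The default design is the study layout: three groups (OA, HP, SOMA) of three
replicates each, nine arrays. Planted genes realize each evidence category of
the candidate classifier; everything else is null (no group effect), so the
type-I behavior of the screen is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .evidence import (
    CATEGORIES,
    ExpressionChange,
    GeneEvidenceFeatures,
)
from .io import GROUPS, IntensityTable, SampleSheet
from . import differential

NULL = "null"


@dataclass(frozen=True)
class PlantedGene:
    """A simulated gene with per-group truth (order OA, HP, SOMA)."""

    gene: str
    category: str  # one of CATEGORIES or "null"
    m: tuple[float, float, float]  # true methylated fraction per group, in (0,1)
    t: tuple[float, float, float]  # true abundance per group, > 0


@dataclass
class SimConfig:
    """Study-design and noise parameters of one simulated experiment.

    ``n_genes`` counts all non-spike-in genes; planted genes beyond the list
    are filled with nulls whose (m, T) are drawn once per gene and shared by
    all groups.
    """

    n_genes: int = 1000
    n_per_group: int = 3
    groups: tuple[str, ...] = GROUPS
    planted: list[PlantedGene] = field(default_factory=list)
    noise_sigma: float = 0.15  # log2-scale sd of the multiplicative noise
    n_spikeins: int = 10
    spikein_level: float = 1000.0
    flag_absent_rate: float = 0.02  # random dropout to flag A
    absent_quantile: float = 0.02  # dimmest fraction of probe/samples flagged A
    marginal_rate: float = 0.05  # chance a detected probe is flagged M not P
    seed: int = 0

    def validate(self) -> None:
        if tuple(self.groups) != GROUPS:
            raise ConfigError(f"groups must be exactly {GROUPS} in order, got {tuple(self.groups)}")
        if self.n_per_group < 2:
            raise ConfigError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if len(self.planted) > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} smaller than planted list ({len(self.planted)})"
            )
        if self.noise_sigma < 0:
            raise ConfigError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        for name, rate in (
            ("flag_absent_rate", self.flag_absent_rate),
            ("absent_quantile", self.absent_quantile),
            ("marginal_rate", self.marginal_rate),
        ):
            if not 0 <= rate <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {rate}")
        if self.spikein_level <= 0:
            raise ConfigError(f"spikein_level must be > 0, got {self.spikein_level}")
        for g in self.planted:
            if g.category not in CATEGORIES and g.category != NULL:
                raise ConfigError(f"gene {g.gene!r}: unknown category {g.category!r}")
            for mk in g.m:
                if not 0 < mk < 1:
                    raise ConfigError(f"gene {g.gene!r}: m={mk} not strictly inside (0, 1)")
            for tk in g.t:
                if not tk > 0:
                    raise ConfigError(f"gene {g.gene!r}: T={tk} not positive")


# ---------------------------------------------------------------------------
# Planted per-category truth profiles

# Sub-cutoff effects must stay strictly inside the 2-fold window for the
# category to be expressible; they are fixed, only the significant (beyond
# cutoff) effects scale with effect_size.
_SUB_UP = 1.5  # category i quantity increase, deliberately < 2-fold
_SUB_DOWN = 0.9  # category iv SOMA expression decrease, deliberately mild


def planted_profile(category: str, effect_size: float = 4.0) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Per-group (m, T) truth realizing one evidence category noise-free.

    ``effect_size`` (> 1, typically >= 2 so significant changes clear the
    2-fold cutoff) scales the deliberately large fold changes; returns tuples
    in the group order OA, HP, SOMA.
    """
    if effect_size <= 1:
        raise ConfigError(f"effect_size must be > 1, got {effect_size}")
    e = float(effect_size)
    if category == NULL:
        return (0.4, 0.4, 0.4), (100.0, 100.0, 100.0)
    if category == "i":
        # level halves; T rises so quantity (m*T) goes up by the sub-cutoff
        # factor while expression triples
        t_inoa = 100.0 * _SUB_UP * (0.4 / 0.2)
        return (0.4, 0.2, 0.2), (100.0, t_inoa, t_inoa)
    if category == "ii":
        # quantity significantly up (fc = e) despite lower level
        return (0.6, 0.3, 0.3), (100.0, 200.0 * e, 200.0 * e)
    if category == "iii":
        # quantity mildly down, expression discordant between HP and SOMA
        return (0.4, 0.35, 0.35), (100.0, 130.0, 80.0)
    if category == "iv":
        # quantity significantly down, both expressions down, SOMA change mild
        # (not significant) and group means unordered
        return (0.5, 0.25, 0.2), (100.0, 100.0 / e, 100.0 * _SUB_DOWN)
    if category == "v":
        # significant loss of both mark and expression, monotone across groups
        return (0.6, 0.3, 0.15), (100.0, 100.0 / np.sqrt(e), 100.0 / e)
    raise ConfigError(f"unknown category {category!r}")


def profile_features(
    gene: str,
    m: Sequence[float],
    t: Sequence[float],
    fc_cutoff: float = 2.0,
) -> GeneEvidenceFeatures:
    """Noise-free evidence features implied by a truth profile.

    In the noise-free idealization a change is "significant" exactly when it
    clears the fold-change cutoff (an infinite-precision test detects any
    cutoff-sized effect); directions, magnitudes and tendency follow from the
    true per-group quantities.
    """
    m = np.asarray(m, float)
    t = np.asarray(t, float)
    q = m * t  # true m6A quantity per group
    log_cut = np.log2(fc_cutoff)

    def change(fc: float) -> ExpressionChange:
        big = abs(np.log2(fc)) >= log_cut
        return ExpressionChange(
            "up" if fc > 1 else "down",
            "double" if big else "single",
            significant=big,
        )

    fc_q = np.sqrt(q[1] * q[2]) / q[0]  # pooled iNOA geometric mean vs OA
    level_inoa = 100.0 * (m[1] + m[2]) / 2
    level_oa = 100.0 * m[0]
    return GeneEvidenceFeatures(
        gene_symbol=gene,
        level_inoa=level_inoa,
        level_oa=level_oa,
        level_significant=abs(np.log2(level_inoa / level_oa)) >= log_cut,
        quantity_direction="up" if fc_q > 1 else "down",
        quantity_significant=abs(np.log2(fc_q)) >= log_cut,
        expr_hp=change(t[1] / t[0]),
        expr_soma=change(t[2] / t[0]),
        tendency=differential.tendency(t),
    )


def planted_cohort(
    counts: Mapping[str, int],
    effect_size: float = 4.0,
    prefix: str = "PLANT",
) -> list[PlantedGene]:
    """Named planted genes, ``counts`` per category (e.g. {"v": 5})."""
    genes = []
    for category, n in counts.items():
        m, t = planted_profile(category, effect_size)
        for j in range(n):
            genes.append(PlantedGene(f"{prefix}_{category.upper()}_{j:03d}", category, m, t))
    return genes


# ---------------------------------------------------------------------------
# The generator

def simulate_experiment(config: SimConfig) -> tuple[IntensityTable, SampleSheet, pd.DataFrame]:
    """Draw one experiment; identical config+seed gives bit-identical output.

    Returns the intensity table (one probe per gene plus spike-ins), the
    sample sheet, and the truth table recording every planted parameter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_null = config.n_genes - len(config.planted)

    genes = list(config.planted)
    # null genes: one (m, T) per gene, identical across groups
    null_m = rng.uniform(0.1, 0.7, size=n_null)
    null_t = 10.0 ** rng.uniform(1.5, 3.0, size=n_null)
    for j in range(n_null):
        genes.append(
            PlantedGene(f"NULL_{j:05d}", NULL, (null_m[j],) * 3, (null_t[j],) * 3)
        )

    samples = [f"{g}_{r + 1}" for g in config.groups for r in range(config.n_per_group)]
    group_of = np.repeat(np.arange(len(config.groups)), config.n_per_group)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "group": [g for g in config.groups for _ in range(config.n_per_group)],
                "replicate": list(range(1, config.n_per_group + 1)) * len(config.groups),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )

    m = np.array([[g.m[k] for k in group_of] for g in genes])  # genes x samples
    t = np.array([[g.t[k] for k in group_of] for g in genes])
    shape = m.shape

    def noise(size):
        if config.noise_sigma == 0:
            return np.ones(size)
        return 2.0 ** rng.normal(0.0, config.noise_sigma, size=size)

    ip = t * m * noise(shape)
    sup = t * (1.0 - m) * noise(shape)

    spike_shape = (config.n_spikeins, len(samples))
    spike_ip = config.spikein_level * noise(spike_shape)
    spike_sup = config.spikein_level * noise(spike_shape)

    probe_ids = [f"PRB_{g.gene}" for g in genes] + [f"SPIKE_{j:02d}" for j in range(config.n_spikeins)]
    gene_ids = [g.gene for g in genes] + [f"SPIKE_{j:02d}" for j in range(config.n_spikeins)]
    index = pd.Index(probe_ids, name="probe_id")
    ip_all = np.vstack([ip, spike_ip])
    sup_all = np.vstack([sup, spike_sup])

    flags = _draw_flags(rng, ip + sup, config)
    spike_flags = np.full(spike_shape, "P")
    flags_all = np.vstack([flags, spike_flags])

    table = IntensityTable(
        ip=pd.DataFrame(ip_all, index=index, columns=samples),
        sup=pd.DataFrame(sup_all, index=index, columns=samples),
        flags=pd.DataFrame(flags_all, index=index, columns=samples),
        genes=pd.Series(gene_ids, index=index, name="gene_symbol"),
        is_spikein=pd.Series(
            [False] * len(genes) + [True] * config.n_spikeins, index=index, name="is_spikein"
        ),
    )
    table.validate()

    truth = pd.DataFrame(
        {
            "gene_symbol": [g.gene for g in genes],
            "category": [g.category for g in genes],
            **{f"m_{grp}": [g.m[k] for g in genes] for k, grp in enumerate(config.groups)},
            **{f"t_{grp}": [g.t[k] for g in genes] for k, grp in enumerate(config.groups)},
        }
    ).set_index("gene_symbol")
    return table, sheet, truth


def _draw_flags(rng: np.random.Generator, total: np.ndarray, config: SimConfig) -> np.ndarray:
    flags = np.where(rng.uniform(size=total.shape) < config.marginal_rate, "M", "P")
    if config.absent_quantile > 0 and total.size:
        cutoff = np.quantile(total, config.absent_quantile)
        flags = np.where(total < cutoff, "A", flags)
    if config.flag_absent_rate > 0:
        flags = np.where(rng.uniform(size=total.shape) < config.flag_absent_rate, "A", flags)
    return flags


def noise_free(config: SimConfig) -> SimConfig:
    """The same design with all stochastic corruption switched off."""
    return replace(config, noise_sigma=0.0, flag_absent_rate=0.0, absent_quantile=0.0, marginal_rate=0.0)
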