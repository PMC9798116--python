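"""Between-group contrasts of the three measures and their arrow coding.

Fold changes are geometric-mean ratios on linear values (equivalently 2^(mean
log2 difference)); p-values come from a two-sample test on the log2 values.
The screening rule marks a gene significant when p < alpha AND the fold change
is beyond the cutoff (default 2-fold) — the cutoff applies to the quantity and
expression screens; methylation-level contrasts use the test alone, since a
percentage difference is not naturally a fold change.

Directions and magnitudes are encoded as the arrow notation used in candidate
tables: one arrow for a sub-cutoff change, two arrows at or beyond the cutoff,
with a star appended for statistical significance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, M6AScreenError
from .io import GROUPS, INOA, SampleSheet
from .quantify import QuantTable

TEST_METHODS = ("t_student", "t_welch", "mannwhitney")

#: Contrasts of the study design; numerator/denominator group labels.
DEFAULT_CONTRASTS = ("HP/OA", "SOMA/OA", "SOMA/HP", "iNOA/OA")


def parse_contrast(contrast: str) -> tuple[str, str]:
    """Split ``"A/B"`` into numerator and denominator group labels."""
    parts = contrast.split("/")
    if len(parts) != 2:
        raise ConfigError(f"contrast must be 'GROUP/GROUP', got {contrast!r}")
    allowed = set(GROUPS) | {INOA}
    for g in parts:
        if g not in allowed:
            raise ConfigError(f"unknown group {g!r} in contrast {contrast!r}")
    return parts[0], parts[1]


def group_test(values_a, values_b, method: str = "t_student") -> float:
    """Two-sided p for a two-group comparison.

    ``t_student`` (the default) is the pooled-variance two-sample t, exact
    under the shared-noise model and exactly sized even at n=3 per group;
    ``t_welch`` is Welch's unequal-variance t (conservative at very small n
    because of the Satterthwaite df approximation); ``mannwhitney`` uses the
    exact Mann-Whitney null for combined n <= 16 without ties and the
    tie-corrected normal approximation otherwise.

    Degenerate-case rules (documented, never a crash): if both groups have zero
    variance, the t tests return p=1 for equal means and p=0 otherwise; if all
    values are tied across both groups, Mann-Whitney returns p=1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise M6AScreenError(f"each group needs >= 2 values, got {a.size} and {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise M6AScreenError("non-finite values in group comparison")
    if method in ("t_student", "t_welch"):
        if a.var() == 0 and b.var() == 0:
            return 1.0 if a.mean() == b.mean() else 0.0
        return float(stats.ttest_ind(a, b, equal_var=method == "t_student").pvalue)
    if method == "mannwhitney":
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            return 1.0
        has_ties = len(np.unique(pooled)) < pooled.size
        exact = pooled.size <= 16 and not has_ties
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return float(res.pvalue)
    raise ConfigError(f"unknown test method {method!r} (allowed: {TEST_METHODS})")


def anova_test(*groups) -> float:
    """One-way ANOVA p over >= 2 groups; all-identical data returns p=1."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise M6AScreenError("anova needs >= 2 groups with >= 2 values each")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 1.0
    if all(a.var() == 0 for a in arrays):
        return 0.0  # groups internally constant but different: effect certain
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.f_oneway(*arrays).pvalue)


def _t_p_matrix(la: np.ndarray, lb: np.ndarray, equal_var: bool) -> np.ndarray:
    """Vectorized two-sample t over gene rows with the degenerate-case rule."""
    va, vb = la.var(axis=1, ddof=1), lb.var(axis=1, ddof=1)
    both_const = (va == 0) & (vb == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(la, lb, axis=1, equal_var=equal_var).pvalue
    mean_diff = la.mean(axis=1) - lb.mean(axis=1)
    p = np.where(both_const, np.where(mean_diff == 0, 1.0, 0.0), p)
    return p


def compare_groups(
    quant: QuantTable,
    sheet: SampleSheet,
    measure: str,
    contrast: str,
    alpha: float = 0.05,
    fc_cutoff: float = 2.0,
    method: str = "t_student",
    apply_fc_cutoff: bool | None = None,
) -> pd.DataFrame:
    """Per-gene fold change, direction, magnitude and p for one contrast.

    Returns a frame indexed by gene with columns ``measure, contrast, fc,
    log2fc, direction, magnitude, p, significant, missing``. Genes with a
    non-positive value in any sample of the contrast (e.g. an undefined level)
    are flagged ``missing`` with NaN statistics rather than dropped.

    ``apply_fc_cutoff`` defaults to True for quantity/expression and False for
    level (see module docstring).
    """
    if apply_fc_cutoff is None:
        apply_fc_cutoff = measure != "level"
    num, den = parse_contrast(contrast)
    cols_a, cols_b = sheet.samples_in(num), sheet.samples_in(den)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise M6AScreenError(
            f"contrast {contrast}: need >= 2 replicates per group, "
            f"got {len(cols_a)} and {len(cols_b)}"
        )
    values = quant.measure(measure)
    a = values[cols_a].to_numpy(dtype=float)
    b = values[cols_b].to_numpy(dtype=float)
    ok = np.isfinite(a).all(axis=1) & np.isfinite(b).all(axis=1) & (a > 0).all(axis=1) & (b > 0).all(axis=1)

    log2fc = np.full(len(values), np.nan)
    p = np.full(len(values), np.nan)
    if ok.any():
        la, lb = np.log2(a[ok]), np.log2(b[ok])
        log2fc[ok] = la.mean(axis=1) - lb.mean(axis=1)
        if method in ("t_student", "t_welch"):
            p[ok] = _t_p_matrix(la, lb, equal_var=method == "t_student")
        else:
            p[ok] = [group_test(ra, rb, method=method) for ra, rb in zip(la, lb)]

    fc = 2.0 ** log2fc
    direction = np.where(log2fc > 0, "up", "down")
    ratio = np.maximum(fc, 1.0 / fc)
    magnitude = np.where(ratio >= fc_cutoff, "double", "single")
    significant = (p < alpha) & (ratio >= fc_cutoff if apply_fc_cutoff else True)
    out = pd.DataFrame(
        {
            "measure": measure,
            "contrast": contrast,
            "fc": fc,
            "log2fc": log2fc,
            "direction": direction,
            "magnitude": magnitude,
            "p": p,
            "significant": significant & ok,
            "missing": ~ok,
        },
        index=values.index,
    )
    out.index.name = "gene_symbol"
    return out


def arrow_code(fc: float, significant: bool, double_threshold: float = 2.0) -> str:
    """Encode a fold change as the candidate-table arrow notation.

    Single arrow for a change below ``double_threshold`` (in either direction),
    double at or beyond it; ``*`` appended when significant.
    """
    if not np.isfinite(fc) or fc <= 0:
        raise M6AScreenError(f"fold change must be positive and finite, got {fc}")
    arrow = "↑" if fc > 1 else "↓"
    ratio = fc if fc >= 1 else 1.0 / fc
    code = arrow * (2 if ratio >= double_threshold else 1)
    return code + ("*" if significant else "")


def arrow_codes(result: pd.DataFrame, alpha: float = 0.05, double_threshold: float = 2.0) -> pd.Series:
    """Arrow string per gene of a :func:`compare_groups` frame.

    The star marks test significance alone (p < alpha), matching the printed
    convention where a sub-2-fold change can still carry a star.
    """
    out = {}
    for gene, row in result.iterrows():
        if row["missing"] or not np.isfinite(row["fc"]):
            out[gene] = "NA"
        else:
            out[gene] = arrow_code(row["fc"], bool(row["p"] < alpha), double_threshold)
    return pd.Series(out, name="arrow")


def tendency(group_means) -> str:
    """Ordered trend of three group means in the fixed order OA, HP, SOMA.

    ``decreasing`` if OA >= HP >= SOMA with OA > SOMA (non-strict interior,
    strict ends); ``increasing`` symmetrically; otherwise ``unordered``.
    """
    m = np.asarray(group_means, dtype=float)
    if m.shape != (3,) or not np.isfinite(m).all():
        raise M6AScreenError(f"tendency needs three finite means, got {group_means!r}")
    oa, hp, soma = m
    if oa >= hp >= soma and oa > soma:
        return "decreasing"
    if oa <= hp <= soma and oa < soma:
        return "increasing"
    return "unordered"


def null_pvalues(
    n_genes: int, n_per_group: int, sigma: float, seed: int, method: str = "t_student"
) -> np.ndarray:
    """t-test p-values for pure-noise genes (type-I calibration utility)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sigma, size=(n_genes, n_per_group))
    b = rng.normal(0.0, sigma, size=(n_genes, n_per_group))
    return _t_p_matrix(a, b, equal_var=method == "t_student")
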