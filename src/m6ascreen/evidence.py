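"""The hierarchical five-evidence candidate-gene classifier.

Genes whose m6A methylation level drops in the impaired-spermatogenesis
(iNOA) groups are triaged by how their m6A quantity and expression move
together, into five mutually exclusive evidence categories of increasing
weight:

* **i** — level down but quantity up (not significantly): the mark is diluted
  by enhanced transcription rather than actively erased;
* **ii** — quantity significantly up: transcription strengthened while the
  m6A function is attenuated;
* **iii** — quantity down without significance, or changes unordered across
  groups: no coherent mechanism;
* **iv** — quantity significantly down together with decreased expression,
  but the SOMA/OA expression change is not significant;
* **v** — significantly lower m6A with decreased expression whose group means
  fall monotonically across OA → HP → SOMA, mirroring the loss of
  spermatogenesis.

Only categories iv and v are called a plausible m6A-driven mechanism
("mechanism = Yes"). The decision tree below is keyed on the quantity column's
direction and significance, the unique reading consistent with all fourteen
rows of the published worked example; it is total and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import MissingContrastError, ParseError, M6AScreenError
from . import differential
from .io import INOA, SampleSheet, write_table
from .quantify import QuantTable

Direction = Literal["up", "down"]
Magnitude = Literal["single", "double"]
Tendency = Literal["decreasing", "increasing", "unordered"]

CATEGORIES = ("i", "ii", "iii", "iv", "v")


@dataclass(frozen=True)
class ExpressionChange:
    """One expression contrast as printed: direction, arrow magnitude, star."""

    direction: Direction
    magnitude: Magnitude
    significant: bool


@dataclass(frozen=True)
class GeneEvidenceFeatures:
    """Exactly the information content of one candidate-table row."""

    gene_symbol: str
    level_inoa: float  # percent, pooled HP+SOMA
    level_oa: float  # percent
    level_significant: bool
    quantity_direction: Direction
    quantity_significant: bool
    expr_hp: ExpressionChange  # HP/OA
    expr_soma: ExpressionChange  # SOMA/OA
    tendency: Tendency  # expression means across OA -> HP -> SOMA

    def validate(self) -> None:
        for name, pct in (("level_inoa", self.level_inoa), ("level_oa", self.level_oa)):
            if not (np.isfinite(pct) and 0 <= pct <= 100):
                raise M6AScreenError(f"{self.gene_symbol}: {name}={pct!r} not a percent in [0, 100]")
        for name, d in (("quantity_direction", self.quantity_direction),):
            if d not in ("up", "down"):
                raise M6AScreenError(f"{self.gene_symbol}: {name}={d!r} not up/down")
        for name, ch in (("expr_hp", self.expr_hp), ("expr_soma", self.expr_soma)):
            if ch.direction not in ("up", "down") or ch.magnitude not in ("single", "double"):
                raise M6AScreenError(f"{self.gene_symbol}: malformed {name}: {ch!r}")
        if self.tendency not in ("decreasing", "increasing", "unordered"):
            raise M6AScreenError(f"{self.gene_symbol}: unknown tendency {self.tendency!r}")


@dataclass(frozen=True)
class EvidenceCall:
    gene_symbol: str
    category: str  # one of CATEGORIES
    mechanism: bool  # True iff category in {iv, v}


def classify_evidence(f: GeneEvidenceFeatures) -> EvidenceCall:
    """Assign exactly one evidence category by the hierarchical decision tree.

    Rules are evaluated in order; the fallback is category iii (unordered
    change without coherent significance). Total over valid feature tuples.
    """
    f.validate()
    both_down = f.expr_hp.direction == "down" and f.expr_soma.direction == "down"
    if f.quantity_direction == "up" and not f.quantity_significant and f.level_inoa < f.level_oa:
        category = "i"
    elif f.quantity_direction == "up" and f.quantity_significant:
        category = "ii"
    elif f.quantity_direction == "down" and not f.quantity_significant:
        category = "iii"
    elif (
        f.quantity_significant
        and both_down
        and f.expr_soma.significant
        and f.tendency == "decreasing"
    ):
        category = "v"
    elif f.quantity_significant and both_down and not f.expr_soma.significant:
        category = "iv"
    else:
        category = "iii"
    return EvidenceCall(f.gene_symbol, category, mechanism=category in ("iv", "v"))


# ---------------------------------------------------------------------------
# Parsing the printed notation

def parse_arrow(token: str) -> ExpressionChange:
    """Parse arrow notation: '↑↑*' -> (up, double, significant)."""
    token = token.strip()
    sig = token.endswith("*")
    body = token[:-1] if sig else token
    if body in ("↑", "↑↑"):
        direction = "up"
    elif body in ("↓", "↓↓"):
        direction = "down"
    else:
        raise ParseError(f"unparseable arrow token {token!r}")
    return ExpressionChange(direction, "double" if len(body) == 2 else "single", sig)


def parse_quantity(token: str) -> tuple[Direction, bool]:
    """Parse quantity notation: 'Down*' -> ('down', significant)."""
    token = token.strip()
    sig = token.endswith("*")
    body = (token[:-1] if sig else token).lower()
    if body not in ("up", "down"):
        raise ParseError(f"unparseable quantity token {token!r}")
    return body, sig


def _arrow_tendency(hp: ExpressionChange, soma: ExpressionChange) -> Tendency:
    """Tendency implied by the two printed contrasts vs the shared control.

    Monotone decrease across OA -> HP -> SOMA requires both contrasts down
    with the SOMA change at least as large as the HP change; with only arrow
    magnitudes available, the magnitude class orders the changes.
    """
    rank = {"single": 1, "double": 2}
    if hp.direction == "down" and soma.direction == "down" and rank[soma.magnitude] >= rank[hp.magnitude]:
        return "decreasing"
    if hp.direction == "up" and soma.direction == "up" and rank[soma.magnitude] >= rank[hp.magnitude]:
        return "increasing"
    return "unordered"


_FIXTURE = "table3_candidates.tsv"


def _fixture_frame(path: str | Path | None) -> pd.DataFrame:
    if path is None:
        with resources.as_file(resources.files("m6ascreen.data") / _FIXTURE) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def load_candidate_fixture(path: str | Path | None = None) -> list[GeneEvidenceFeatures]:
    """Load a candidate table in the printed arrow/star notation as features.

    With no path, loads the packaged fourteen-gene worked example. The level
    columns of the table carry significance by construction (the table is
    restricted to genes with significantly downregulated level), so
    ``level_significant`` is set True.
    """
    frame = _fixture_frame(path)
    required = {
        "gene_symbol", "level_inoa_pct", "level_oa_pct",
        "quantity_inoa_oa", "expr_fc_hp_oa", "expr_fc_soma_oa",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"candidate table missing column(s): {sorted(missing)}")
    features = []
    for _, row in frame.iterrows():
        q_dir, q_sig = parse_quantity(row["quantity_inoa_oa"])
        hp = parse_arrow(row["expr_fc_hp_oa"])
        soma = parse_arrow(row["expr_fc_soma_oa"])
        features.append(
            GeneEvidenceFeatures(
                gene_symbol=str(row["gene_symbol"]),
                level_inoa=float(row["level_inoa_pct"]),
                level_oa=float(row["level_oa_pct"]),
                level_significant=True,
                quantity_direction=q_dir,
                quantity_significant=q_sig,
                expr_hp=hp,
                expr_soma=soma,
                tendency=_arrow_tendency(hp, soma),
            )
        )
    return features


def load_candidate_calls(path: str | Path | None = None) -> dict[str, EvidenceCall]:
    """Printed verdicts ('Yes (v)' etc.) of a candidate table, for regression."""
    frame = _fixture_frame(path)
    calls = {}
    for _, row in frame.iterrows():
        text = str(row["printed_evidence"]).strip()
        mech, _, cat = text.partition("(")
        category = cat.rstrip(")").strip()
        if category not in CATEGORIES or mech.strip() not in ("Yes", "No"):
            raise ParseError(f"unparseable evidence verdict {text!r}")
        calls[str(row["gene_symbol"])] = EvidenceCall(
            str(row["gene_symbol"]), category, mechanism=mech.strip() == "Yes"
        )
    return calls


# ---------------------------------------------------------------------------
# Bridging pipeline contrasts to the classifier

def extract_features(
    gene: str,
    level_means: tuple[float, float],
    results: Mapping[str, pd.DataFrame],
    tendency: Tendency,
    alpha: float = 0.05,
) -> GeneEvidenceFeatures:
    """Build one gene's feature tuple from differential-contrast frames.

    ``level_means`` is (pooled iNOA percent, OA percent); ``results`` must
    hold frames (from :func:`m6ascreen.differential.compare_groups`) under the
    keys ``level``, ``quantity`` (both iNOA/OA), ``expr_hp`` and ``expr_soma``
    (HP/OA and SOMA/OA expression). Expression significance is the test alone
    (p < alpha); quantity significance is the screen flag carried in the
    frame (test AND fold-change cutoff).
    """
    needed = ("level", "quantity", "expr_hp", "expr_soma")
    absent = [k for k in needed if k not in results or gene not in results[k].index]
    if absent:
        raise MissingContrastError(f"gene {gene!r}: missing contrast(s) {absent}")
    rows = {k: results[k].loc[gene] for k in needed}
    if any(bool(r.get("missing", False)) for r in rows.values()):
        raise MissingContrastError(f"gene {gene!r}: contrast flagged missing")

    def _expr(row) -> ExpressionChange:
        return ExpressionChange(
            direction=row["direction"],
            magnitude=row["magnitude"],
            significant=bool(row["p"] < alpha),
        )

    return GeneEvidenceFeatures(
        gene_symbol=gene,
        level_inoa=float(level_means[0]),
        level_oa=float(level_means[1]),
        level_significant=bool(rows["level"]["p"] < alpha),
        quantity_direction=rows["quantity"]["direction"],
        quantity_significant=bool(rows["quantity"]["significant"]),
        expr_hp=_expr(rows["expr_hp"]),
        expr_soma=_expr(rows["expr_soma"]),
        tendency=tendency,
    )


def features_from_pipeline(
    quant: QuantTable,
    sheet: SampleSheet,
    alpha: float = 0.05,
    fc_cutoff: float = 2.0,
    double_threshold: float = 2.0,
    method: str = "t_student",
) -> list[GeneEvidenceFeatures]:
    """Run the four candidate-table contrasts and extract features per gene.

    Genes with any missing contrast (undefined level etc.) are skipped.
    """
    kw = dict(alpha=alpha, fc_cutoff=fc_cutoff, method=method)
    results = {
        "level": differential.compare_groups(quant, sheet, "level", f"{INOA}/OA", **kw),
        "quantity": differential.compare_groups(quant, sheet, "quantity", f"{INOA}/OA", **kw),
        "expr_hp": differential.compare_groups(quant, sheet, "expression", "HP/OA", **kw),
        "expr_soma": differential.compare_groups(quant, sheet, "expression", "SOMA/OA", **kw),
    }
    # magnitude class for the arrow coding may differ from the screen cutoff
    if double_threshold != fc_cutoff:
        for key in ("expr_hp", "expr_soma"):
            r = results[key]
            ratio = np.maximum(r["fc"], 1.0 / r["fc"])
            r["magnitude"] = np.where(ratio >= double_threshold, "double", "single")

    level_inoa = quant.level[sheet.samples_in(INOA)].mean(axis=1)
    level_oa = quant.level[sheet.samples_in("OA")].mean(axis=1)
    expr_means = {
        g: quant.expression[sheet.samples_in(g)].mean(axis=1) for g in ("OA", "HP", "SOMA")
    }

    features = []
    for gene in quant.genes:
        try:
            tend = differential.tendency(
                (expr_means["OA"][gene], expr_means["HP"][gene], expr_means["SOMA"][gene])
            )
            features.append(
                extract_features(
                    gene, (level_inoa[gene], level_oa[gene]), results, tend, alpha=alpha
                )
            )
        except (MissingContrastError, M6AScreenError):
            continue
    return features


def calls_to_frame(calls: list[EvidenceCall], features: list[GeneEvidenceFeatures] | None = None) -> pd.DataFrame:
    """Tabulate calls (and optionally the audit feature tuple) for export."""
    rows = []
    feat_by_gene = {f.gene_symbol: f for f in features} if features else {}
    for c in calls:
        row = {
            "gene_symbol": c.gene_symbol,
            "category": c.category,
            "mechanism": "Yes" if c.mechanism else "No",
        }
        f = feat_by_gene.get(c.gene_symbol)
        if f is not None:
            row.update(
                level_inoa_pct=f.level_inoa,
                level_oa_pct=f.level_oa,
                quantity=("Up" if f.quantity_direction == "up" else "Down")
                + ("*" if f.quantity_significant else ""),
                expr_hp=_format_arrow(f.expr_hp),
                expr_soma=_format_arrow(f.expr_soma),
                tendency=f.tendency,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _format_arrow(ch: ExpressionChange) -> str:
    arrow = "↑" if ch.direction == "up" else "↓"
    return arrow * (2 if ch.magnitude == "double" else 1) + ("*" if ch.significant else "")


def write_evidence_table(calls, features, path) -> None:
    frame = calls_to_frame(calls, features).sort_values("gene_symbol")
    write_table(frame, path)
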