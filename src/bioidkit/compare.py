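"""Set-level analytics over interactomes and curated reference gene sets.

Pairwise overlap/Jaccard statistics between bait interactomes or against
curated marker datasets, membership tallies across multiple reference
databases (e.g. lysosomal protein catalogues), a hypergeometric
over-representation test with Benjamini-Hochberg adjustment, and the
dot-plot data encoding (control-subtracted average counts capped at 50,
relative abundance across baits as size, BFDR bins as border colour).

Gene symbols are compared case-insensitively, per the human gene-symbol
convention; small synthetic stand-in gene lists ship with the package and
real curated lists (cellular-marker, lysosomal, ciliary gold-standard)
drop in as one-symbol-per-line text files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .experiment import ValidationError
from .scoring import ScoredInteraction


def _norm(genes: Iterable[str]) -> frozenset[str]:
    return frozenset(g.strip().upper() for g in genes if g and g.strip())


@dataclass(frozen=True)
class ReferenceGeneSet:
    """A named, curated gene list; symbols are uppercased for comparison."""

    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", _norm(self.genes))
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.strip().upper() in self.genes


def load_gene_set(path, name: str | None = None, source: str = "") -> ReferenceGeneSet:
    """Read a one-gene-symbol-per-line text file ('#' lines are comments)."""
    path = Path(path)
    genes = [
        line.strip()
        for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return ReferenceGeneSet(name=name or path.stem, genes=frozenset(genes), source=source)


def packaged_gene_sets() -> dict[str, ReferenceGeneSet]:
    """The small synthetic stand-in gene lists bundled with the package."""
    out = {}
    root = resources.files("bioidkit").joinpath("data/genesets")
    for entry in root.iterdir():
        if entry.name.endswith(".txt"):
            genes = [
                line.strip()
                for line in entry.read_text(encoding="utf-8").splitlines()
                if line.strip() and not line.lstrip().startswith("#")
            ]
            name = entry.name[:-4]
            out[name] = ReferenceGeneSet(name=name, genes=frozenset(genes),
                                         source="synthetic stand-in")
    return out


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapSummary:
    set_a_n: int
    set_b_n: int
    intersection_n: int
    union_n: int
    jaccard_similarity: float
    jaccard_distance: float
    both: int
    a_only: int
    b_only: int

    @property
    def pct_of_a(self) -> int:
        """Intersection as a percentage of |A|, rounded to the nearest whole %."""
        return round(100.0 * self.intersection_n / self.set_a_n)

    @property
    def pct_of_b(self) -> int:
        return round(100.0 * self.intersection_n / self.set_b_n)


def overlap(a: Iterable[str], b: Iterable[str]) -> OverlapSummary:
    """Exact set overlap and Jaccard statistics (case-insensitive symbols)."""
    sa, sb = _norm(a), _norm(b)
    if not sa or not sb:
        raise ValidationError("overlap requires two non-empty gene sets")
    inter = sa & sb
    union = sa | sb
    return OverlapSummary(
        set_a_n=len(sa),
        set_b_n=len(sb),
        intersection_n=len(inter),
        union_n=len(union),
        jaccard_similarity=len(inter) / len(union),
        jaccard_distance=1.0 - len(inter) / len(union),
        both=len(inter),
        a_only=len(sa - sb),
        b_only=len(sb - sa),
    )


def multi_db_membership(
    preys_by_bait: Mapping[str, Iterable[str]],
    databases: Sequence[ReferenceGeneSet],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate database-membership tiers by bait exclusivity.

    ``preys_by_bait`` must name exactly two bait datasets (order defines
    which is "a" and which "b").  Returns (per-prey table, contingency
    table) where the contingency rows are the tiers ``ge2`` (in at least
    two databases) and ``all`` (in every database) and the columns are
    ``both`` / ``a_only`` / ``b_only``.
    """
    if len(preys_by_bait) != 2:
        raise ValidationError("exclusivity tallies need exactly two bait datasets")
    if len(databases) < 2:
        raise ValidationError("at least two reference databases are required")
    (name_a, a), (name_b, b) = list(preys_by_bait.items())
    sa, sb = _norm(a), _norm(b)
    rows = []
    for prey in sorted(sa | sb):
        n_dbs = sum(prey in db.genes for db in databases)
        in_a, in_b = prey in sa, prey in sb
        rows.append(
            {
                "prey": prey,
                "n_databases": n_dbs,
                name_a: in_a,
                name_b: in_b,
                "exclusivity": "both" if (in_a and in_b) else ("a_only" if in_a else "b_only"),
            }
        )
    per_prey = pd.DataFrame(rows)
    table = pd.DataFrame(
        0, index=["ge2", "all"], columns=["both", "a_only", "b_only"]
    )
    if len(per_prey):
        for tier, sel in (
            ("ge2", per_prey["n_databases"] >= 2),
            ("all", per_prey["n_databases"] == len(databases)),
        ):
            vc = per_prey.loc[sel, "exclusivity"].value_counts()
            for cls in table.columns:
                table.loc[tier, cls] = int(vc.get(cls, 0))
    return per_prey, table


def overrepresentation(
    query: Iterable[str], reference: ReferenceGeneSet, universe_n: int
) -> tuple[float, float]:
    """Hypergeometric upper-tail enrichment of a query set in a reference set.

    Returns (p_value, fold_enrichment) where fold enrichment is the observed
    overlap rate in the query over the reference's rate in the universe.
    """
    q = _norm(query)
    if not q:
        raise ValidationError("query gene set is empty")
    if universe_n < len(q | reference.genes):
        raise ValidationError(
            f"universe ({universe_n}) smaller than query-union-reference "
            f"({len(q | reference.genes)})"
        )
    k = len(q & reference.genes)
    p = float(hypergeom.sf(k - 1, universe_n, len(reference.genes), len(q)))
    fold = (k / len(q)) / (len(reference.genes) / universe_n)
    return p, fold


def overrepresentation_table(
    query: Iterable[str],
    references: Sequence[ReferenceGeneSet],
    universe_n: int,
) -> pd.DataFrame:
    """ORA against several reference sets with BH-adjusted p-values."""
    rows = []
    q = _norm(query)
    for ref in references:
        p, fold = overrepresentation(q, ref, universe_n)
        rows.append(
            {
                "reference": ref.name,
                "reference_n": len(ref),
                "query_n": len(q),
                "overlap_n": len(q & ref.genes),
                "fold_enrichment": fold,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


# ----------------------------------------------------------------------
# dot-plot export

COLOR_CAP = 50.0


@dataclass(frozen=True)
class DotPlotRecord:
    bait_id: str
    condition: str | None
    prey_id: str
    color_value: float  # control-subtracted average count, capped at 50
    size_value: float  # this dataset's avg count / max across datasets
    border_class: str  # black (BFDR<=0.01), blue (<=0.05), light_blue (>0.05)


def border_class(bfdr: float) -> str:
    if bfdr <= 0.01:
        return "black"
    if bfdr <= 0.05:
        return "blue"
    return "light_blue"


def dotplot_export(
    scored: Iterable[ScoredInteraction],
    preys: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Dot-plot encoding for every scored pair (optionally restricted to preys).

    colour = max(0, AvgSpec - control average) capped at 50; size = the
    dataset's AvgSpec relative to the prey's maximum AvgSpec across all
    datasets; border encodes the BFDR bin.
    """
    recs = list(scored)
    if preys is not None:
        keep = _norm(preys)
        recs = [s for s in recs if s.prey_id.upper() in keep]
    if not recs:
        raise ValidationError("no scored records to export")
    max_by_prey: dict[str, float] = {}
    for s in recs:
        key = s.prey_id.upper()
        max_by_prey[key] = max(max_by_prey.get(key, 0.0), s.avg_spec)
    rows = []
    for s in recs:
        m = max_by_prey[s.prey_id.upper()]
        rows.append(
            DotPlotRecord(
                bait_id=s.bait_id,
                condition=s.condition,
                prey_id=s.prey_id,
                color_value=float(np.clip(s.avg_spec - s.ctrl_avg, 0.0, COLOR_CAP)),
                size_value=float(s.avg_spec / m) if m > 0 else 0.0,
                border_class=border_class(s.bfdr),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
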