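"""Monosynaptic rabies tracing quantification.

Starter cells are striatal neurons co-infected with helper and rabies
viruses; presynaptic inputs are rabies-labeled cells elsewhere in the brain.
Brains with >= 15% of starter cells outside the striatum are excluded.  Two
normalized metrics are computed per brain region:

* relative number — presynaptic count in the region divided by the number of
  co-infected striatal starter cells;
* relative proportion — presynaptic count in the region divided by the total
  number of extra-striatal presynaptic cells in the whole brain.

Groups (genotype x condition) are summarized as mean +/- SEM and compared
with a Kruskal-Wallis test plus post hoc Tukey (three conditions) or a
Wilcoxon rank-sum test (two groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionOntology",
    "RegionCountTable",
    "ConnectivityMetrics",
    "load_default_ontology",
    "check_starter_inclusion",
    "relative_number",
    "relative_proportion",
    "connectivity_metrics",
    "aggregate_groups",
]


class RegionOntology:
    """A small hierarchical brain-region ontology keyed by acronym.

    Backed by a table with columns ``acronym, name, parent, is_striatal``.
    Parent chains must be acyclic with exactly one root.  A minimal ontology
    (~25 acronyms around the striatal input map: motor/somatosensory cortex,
    thalamic nuclei, GPe, STN, SNc ...) ships with the package; users may
    supply their own CSV in the same schema.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"acronym", "name", "parent", "is_striatal"}
        if not required.issubset(table.columns):
            raise ValueError(f"ontology table must have columns {sorted(required)}")
        self.table = table.copy()
        self.table["parent"] = self.table["parent"].fillna("")
        self._parent = dict(zip(self.table["acronym"], self.table["parent"]))
        self._striatal = dict(
            zip(self.table["acronym"], self.table["is_striatal"].astype(bool))
        )
        roots = [a for a, p in self._parent.items() if p == ""]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {roots}")
        self.root = roots[0]
        self._children: dict[str, list[str]] = {a: [] for a in self._parent}
        for a, p in self._parent.items():
            if p:
                if p not in self._parent:
                    raise ValueError(f"parent {p!r} of {a!r} not in ontology")
                self._children[p].append(a)
        # cycle check: every node must reach the root
        for a in self._parent:
            seen = set()
            node = a
            while node != self.root:
                if node in seen:
                    raise ValueError(f"cycle in ontology at {node!r}")
                seen.add(node)
                node = self._parent[node]

    @classmethod
    def from_csv(cls, path) -> "RegionOntology":
        return cls(pd.read_csv(path))

    def __contains__(self, acronym: str) -> bool:
        return acronym in self._parent

    def descendants(self, acronym: str) -> list[str]:
        """The region itself plus all regions below it."""
        if acronym not in self._parent:
            raise KeyError(f"unknown region acronym {acronym!r}")
        out = [acronym]
        stack = list(self._children[acronym])
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self._children[node])
        return out

    def is_striatal(self, acronym: str) -> bool:
        return self._striatal[acronym]

    def extrastriatal_acronyms(self) -> list[str]:
        return [a for a in self._parent if not self._striatal[a]]


def load_default_ontology() -> RegionOntology:
    """The minimal packaged striatal-input ontology."""
    with resources.files("dyskpipe.data").joinpath("region_ontology.csv").open() as fh:
        return RegionOntology(pd.read_csv(fh))


@dataclass
class RegionCountTable:
    """Per-animal rabies cell counts keyed by region acronym.

    ``counts`` maps region acronym to the number of presynaptic
    (rabies-labeled) cells detected there.  Starter counts are split into
    striatal (co-infected, the relative-number denominator) and
    extra-striatal (the spread used for the inclusion criterion).
    """

    animal_id: str
    genotype: str  # e.g. D1-Cre | A2a-Cre | FosTRAP
    condition: str  # e.g. control | Park | LID
    counts: dict[str, int]
    striatal_starters: int
    extrastriatal_starters: int = 0

    def __post_init__(self) -> None:
        for region, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"count for {region!r} must be a non-negative integer")
        if self.striatal_starters < 0 or self.extrastriatal_starters < 0:
            raise ValueError("starter counts must be non-negative")

    @property
    def total_starters(self) -> int:
        return self.striatal_starters + self.extrastriatal_starters


@dataclass
class ConnectivityMetrics:
    relative_number: dict[str, float]
    relative_proportion: dict[str, float]


def check_starter_inclusion(table: RegionCountTable, max_fraction: float = 0.15) -> bool:
    """Starter-spread inclusion: strictly less than 15% of starter cells
    outside the striatum.  Exactly 15/100 fails."""
    if table.total_starters == 0:
        raise ValueError(f"animal {table.animal_id}: zero starter cells")
    return table.extrastriatal_starters / table.total_starters < max_fraction


def _subtree_count(table: RegionCountTable, region: str, ontology: RegionOntology) -> int:
    return sum(table.counts.get(a, 0) for a in ontology.descendants(region))


def _extrastriatal_total(table: RegionCountTable, ontology: RegionOntology) -> int:
    total = 0
    for region, c in table.counts.items():
        if region not in ontology:
            raise KeyError(f"region {region!r} not in ontology")
        if not ontology.is_striatal(region):
            total += c
    return total


def relative_number(
    table: RegionCountTable, region: str, ontology: RegionOntology
) -> float:
    """Presynaptic count under ``region`` per co-infected striatal starter.

    Counts are aggregated over the region's subtree, so a parent's relative
    number equals the sum over its children.
    """
    if table.striatal_starters <= 0:
        raise ValueError(f"animal {table.animal_id}: no striatal starter cells")
    return _subtree_count(table, region, ontology) / table.striatal_starters


def relative_proportion(
    table: RegionCountTable, region: str, ontology: RegionOntology
) -> float:
    """Fraction of all extra-striatal presynaptic cells found under ``region``.

    Striatal counts are excluded from the denominator, so proportions over a
    partition of extra-striatal regions sum to 1.
    """
    denom = _extrastriatal_total(table, ontology)
    if denom <= 0:
        raise ValueError(f"animal {table.animal_id}: no extra-striatal presynaptic cells")
    return _subtree_count(table, region, ontology) / denom


def connectivity_metrics(
    table: RegionCountTable, regions: list[str], ontology: RegionOntology
) -> ConnectivityMetrics:
    return ConnectivityMetrics(
        relative_number={r: relative_number(table, r, ontology) for r in regions},
        relative_proportion={r: relative_proportion(table, r, ontology) for r in regions},
    )


def aggregate_groups(
    tables: list[RegionCountTable],
    region: str,
    ontology: RegionOntology,
    metric: str = "relative_number",
    group_by: str = "condition",
    apply_inclusion: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Group summary (mean, SEM, n) of a connectivity metric plus comparisons.

    Animals failing the starter-spread inclusion criterion are excluded
    first (when ``apply_inclusion``).  Three or more groups are compared
    with a Kruskal-Wallis test followed by post hoc Tukey HSD; exactly two
    with a Wilcoxon rank-sum test; a single group yields descriptives only.
    p-values are reported, never thresholded.
    """
    if metric not in ("relative_number", "relative_proportion"):
        raise ValueError("metric must be 'relative_number' or 'relative_proportion'")
    fn = relative_number if metric == "relative_number" else relative_proportion
    rows = []
    for t in tables:
        if apply_inclusion and not check_starter_inclusion(t):
            continue
        rows.append(
            {
                "animal_id": t.animal_id,
                "genotype": t.genotype,
                "condition": t.condition,
                "value": fn(t, region, ontology),
            }
        )
    df = pd.DataFrame(rows, columns=["animal_id", "genotype", "condition", "value"])
    summary = (
        df.groupby(group_by)["value"]
        .agg(mean="mean", sem=lambda v: v.sem(), n="size")
        .reset_index()
    )
    groups = [g["value"].to_numpy() for _, g in df.groupby(group_by)]
    names = [name for name, _ in df.groupby(group_by)]
    comparisons: dict = {"groups": names}
    if len(groups) >= 3:
        kw = stats.kruskal(*groups)
        comparisons["kruskal_p"] = float(kw.pvalue)
        tukey = stats.tukey_hsd(*groups)
        comparisons["posthoc_p"] = {
            (names[i], names[j]): float(tukey.pvalue[i, j])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        }
    elif len(groups) == 2:
        rs = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        comparisons["ranksum_p"] = float(rs.pvalue)
    return summary, comparisons


def read_count_tables(
    counts_csv, starters_csv
) -> list[RegionCountTable]:
    """Build per-animal tables from the documented CSV schemas.

    ``counts_csv``: ``animal_id,genotype,condition,region_acronym,count``;
    ``starters_csv``: ``animal_id,striatal_starters,extrastriatal_starters``.
    """
    counts = pd.read_csv(counts_csv)
    starters = pd.read_csv(starters_csv).set_index("animal_id")
    tables = []
    for (animal, genotype, condition), grp in counts.groupby(
        ["animal_id", "genotype", "condition"]
    ):
        s = starters.loc[animal]
        tables.append(
            RegionCountTable(
                animal_id=str(animal),
                genotype=str(genotype),
                condition=str(condition),
                counts=dict(zip(grp["region_acronym"], grp["count"].astype(int))),
                striatal_starters=int(s["striatal_starters"]),
                extrastriatal_starters=int(s["extrastriatal_starters"]),
            )
        )
    return tables
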