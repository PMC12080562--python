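"""Per-cell fluorescent in situ hybridization (RNAscope) quantification.

Per-cell probe intensity sums (Drd1, Drd2, Pdyn, tdTomato) over D1-positive
cells are normalized in two steps: a "cell" normalization dividing the summed
pixel intensity by the cell area, then a "slice" normalization dividing by
the mean cell-normalized value over the slice (or striatal subregion), which
makes the group mean exactly 1 and removes slice-to-slice staining
variability.  TRAPed cells are flagged by a tdTomato intensity threshold per
slice.  TRAPed vs unTRAPed direct-pathway neurons are compared per probe with
a Wilcoxon signed-rank test over per-slice class means, Bonferroni-corrected
across subregions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PROBES",
    "classify_trap",
    "cell_normalize",
    "slice_normalize",
    "normalize_cells",
    "paired_slice_comparison",
]

PROBES = ("drd1", "drd2", "pdyn")
SUBREGIONS = ("DLS", "DMS", "VLS")


def cell_normalize(cells: pd.DataFrame, probe: str) -> pd.Series:
    """Cell-normalized expression: summed pixel intensity / cell area (um^2)."""
    if (cells["area_um2"] <= 0).any():
        raise ValueError("all cell areas must be positive")
    return cells[probe] / cells["area_um2"]


def slice_normalize(values: pd.Series, groups: pd.Series) -> pd.Series:
    """Divide each value by the mean of its normalization group.

    Groups are slices (pooled across the striatum) or slice x subregion
    units.  The mean of the output within every group is exactly 1.  Groups
    with zero mean are flagged and returned as NaN.
    """
    means = values.groupby(groups).transform("mean")
    bad = means == 0
    if bad.any():
        logger.warning(
            "%d group(s) have zero mean intensity; normalized values undefined",
            groups[bad].nunique(),
        )
    out = values / means.where(~bad)
    return out


def classify_trap(
    cells: pd.DataFrame,
    percentile: float = 90.0,
    fixed_threshold: float | None = None,
) -> pd.Series:
    """TRAP flags from the tdTomato channel, per slice.

    The cell-normalized tdTomato value is compared to a per-slice threshold:
    the given percentile of the slice's values by default, or a fixed value
    when supplied.  Strictly-greater comparison: a cell exactly at threshold
    is not TRAPed.  Only D1-positive cells receive a flag; others are False.
    """
    if "tdtomato" not in cells.columns:
        raise ValueError("cells table must have a 'tdtomato' column")
    values = cell_normalize(cells, "tdtomato")
    if fixed_threshold is not None:
        thr = pd.Series(fixed_threshold, index=cells.index)
    else:
        thr = values.groupby(cells["slice_id"]).transform(
            lambda v: np.percentile(v, percentile)
        )
    trap = values > thr
    if "d1_positive" in cells.columns:
        trap &= cells["d1_positive"].astype(bool)
    return trap


def normalize_cells(
    cells: pd.DataFrame,
    grouping: str = "slice",
    probes: tuple[str, ...] = PROBES + ("tdtomato",),
) -> pd.DataFrame:
    """Add cell- and slice-normalized columns for each probe.

    ``grouping`` is ``'slice'`` (normalize over all cells in the slice) or
    ``'subregion'`` (over slice x subregion units).  Adds
    ``{probe}_cellnorm`` and ``{probe}_norm`` columns.
    """
    if grouping == "slice":
        group = cells["slice_id"].astype(str)
    elif grouping == "subregion":
        group = cells["slice_id"].astype(str) + "/" + cells["subregion"].astype(str)
    else:
        raise ValueError("grouping must be 'slice' or 'subregion'")
    out = cells.copy()
    for probe in probes:
        if probe not in cells.columns:
            continue
        cn = cell_normalize(cells, probe)
        out[f"{probe}_cellnorm"] = cn
        out[f"{probe}_norm"] = slice_normalize(cn, group)
    return out


@dataclass
class PairedComparison:
    probe: str
    subregion: str | None
    n_slices: int
    trap_mean: float
    untrap_mean: float
    p_value: float
    p_adjusted: float


def paired_slice_comparison(
    cells: pd.DataFrame,
    trap: pd.Series,
    probes: tuple[str, ...] = PROBES,
    by_subregion: bool = False,
    min_slices: int = 6,
) -> pd.DataFrame:
    """TRAPed vs unTRAPed comparison per probe, paired over slices.

    For each slice the mean slice-normalized value is taken per class; the
    per-slice TRAP and unTRAP means are compared with a Wilcoxon signed-rank
    test (n = slices).  Slices missing one class are dropped and logged.
    With ``by_subregion`` the test runs per striatal subregion and p-values
    are Bonferroni-corrected across the three subregions.

    Expects ``{probe}_norm`` columns (see :func:`normalize_cells`).
    """
    cells = cells.copy()
    cells["_trap"] = trap.astype(bool).to_numpy()
    units = [None] if not by_subregion else sorted(cells["subregion"].unique())
    n_tests = len(units) if by_subregion else 1
    rows = []
    for unit in units:
        sub = cells if unit is None else cells[cells["subregion"] == unit]
        for probe in probes:
            col = f"{probe}_norm"
            if col not in sub.columns:
                raise ValueError(f"missing normalized column {col!r}; run normalize_cells")
            per_slice = sub.groupby(["slice_id", "_trap"])[col].mean().unstack("_trap")
            if True not in per_slice.columns or False not in per_slice.columns:
                paired = per_slice.iloc[0:0]
            else:
                n_before = len(per_slice)
                paired = per_slice.dropna(subset=[True, False])
                if len(paired) < n_before:
                    logger.info(
                        "probe %s%s: dropped %d slice(s) missing one class",
                        probe, f" ({unit})" if unit else "", n_before - len(paired),
                    )
            n = len(paired)
            if n < min_slices:
                raise ValueError(
                    f"probe {probe}: only {n} slices with both classes; "
                    f"need >= {min_slices}"
                )
            diffs = paired[True] - paired[False]
            if np.allclose(diffs, 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(paired[True], paired[False]).pvalue)
            rows.append(
                PairedComparison(
                    probe=probe,
                    subregion=unit,
                    n_slices=n,
                    trap_mean=float(paired[True].mean()),
                    untrap_mean=float(paired[False].mean()),
                    p_value=p,
                    p_adjusted=min(1.0, p * n_tests),
                ).__dict__
            )
    return pd.DataFrame(rows)
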