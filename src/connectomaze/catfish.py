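"""Arc catFISH ensemble classification and overlap statistics.

Arc mRNA appears in the nucleus 1-2 min after a neuron fires and reaches
the cytoplasm ~15-20 min later, so after two behavioral epochs separated by
a 20 min rest, cytoplasmic label marks epoch-1 activity and nuclear label
marks epoch-2 activity.  This module consumes per-cell, per-plane
measurements from confocal z-stacks (foci counts and perimeter-coverage
fractions; upstream image segmentation is out of scope), applies the
inclusion and classification rules, attributes compartments to tasks under
counterbalanced ordering, aggregates per rat, and computes ensemble-overlap
similarity scores.

Classification rules (per included cell):

* nuclear positive — one or two foci on at least four consecutive planes;
* cytoplasmic positive — perimeter coverage >= 1/3 on at least two adjacent
  planes;
* double — both; negative — neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "EnsembleCounts",
    "inclusion_filter",
    "classify_cell",
    "count_population",
    "ensemble_counts",
    "epoch_to_task",
    "similarity_score",
]

CLASS_LABELS = ("negative", "nuclear", "cytoplasmic", "double")


class UndefinedSimilarityError(ValueError):
    """Similarity score denominator is not positive."""


@dataclass
class CellRecord:
    """One candidate cell from a z-stack.

    ``foci_per_plane`` holds above-threshold intranuclear foci counts and
    ``coverage_per_plane`` the fraction of the nuclear perimeter surrounded
    by cytoplasmic label, one entry per optical plane (1 um spacing).
    ``visible_plane_range`` is the 1-indexed (first, last) plane on which the
    nucleus appears.
    """

    cell_id: str
    n_planes_in_stack: int
    foci_per_plane: np.ndarray
    coverage_per_plane: np.ndarray
    visible_plane_range: tuple[int, int]
    edge_cut: bool = False
    region: str = ""
    hemisphere: str = ""
    rat_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        self.foci_per_plane = np.asarray(self.foci_per_plane, dtype=int)
        self.coverage_per_plane = np.asarray(self.coverage_per_plane, dtype=float)
        n = self.n_planes_in_stack
        if self.foci_per_plane.shape != (n,) or self.coverage_per_plane.shape != (n,):
            raise ValueError("need one foci count and one coverage value per plane")
        if ((self.coverage_per_plane < 0) | (self.coverage_per_plane > 1)).any():
            raise ValueError("coverage fractions must lie in [0, 1]")
        first, last = self.visible_plane_range
        if not 1 <= first <= last <= n:
            raise ValueError("visible range must lie within the stack")


def central_window(n_planes: int, median_fraction: float = 0.2) -> tuple[int, int]:
    """The median window of the stack: ``round(median_fraction * n_planes)``
    planes centered on the stack midpoint, 1-indexed inclusive.

    For a 20-plane stack at the default fraction this is planes 9-12."""
    width = max(1, round(median_fraction * n_planes))
    start = (n_planes - width) // 2 + 1
    return start, start + width - 1


def inclusion_filter(
    cells: Iterable[CellRecord],
    median_fraction: float = 0.2,
    mode: str = "intersects",
) -> list[CellRecord]:
    """Keep cells usable for counting: not cut off by the tissue edge and
    visible within the median window of the optical planes.

    ``mode='intersects'`` (default) keeps a cell whose visible range overlaps
    the window; ``mode='covers'`` requires the range to contain it.
    """
    if mode not in ("intersects", "covers"):
        raise ValueError("mode must be 'intersects' or 'covers'")
    out = []
    for cell in cells:
        if cell.edge_cut:
            continue
        if cell.n_planes_in_stack < 5:
            raise ValueError("stacks must have at least 5 planes")
        lo, hi = central_window(cell.n_planes_in_stack, median_fraction)
        first, last = cell.visible_plane_range
        ok = (first <= hi and last >= lo) if mode == "intersects" else (first <= lo and last >= hi)
        if ok:
            out.append(cell)
    return out


def _has_run(mask: np.ndarray, min_len: int) -> bool:
    """True when ``mask`` contains a run of >= min_len consecutive True."""
    run = 0
    for v in mask:
        run = run + 1 if v else 0
        if run >= min_len:
            return True
    return False


def classify_cell(
    cell: CellRecord,
    nuclear_run: int = 4,
    cyto_run: int = 2,
    coverage_min: float = 1.0 / 3.0,
    foci_rule: str = "one_or_two",
) -> str:
    """Label one cell as negative / nuclear / cytoplasmic / double.

    ``foci_rule='one_or_two'`` (default) counts a plane toward the nuclear
    criterion only when it shows exactly one or two foci; ``'at_least_one'``
    relaxes this to >= 1.
    """
    if foci_rule == "one_or_two":
        nuc_mask = (cell.foci_per_plane == 1) | (cell.foci_per_plane == 2)
    elif foci_rule == "at_least_one":
        nuc_mask = cell.foci_per_plane >= 1
    else:
        raise ValueError("foci_rule must be 'one_or_two' or 'at_least_one'")
    nuclear = _has_run(nuc_mask, nuclear_run)
    cyto = _has_run(cell.coverage_per_plane >= coverage_min, cyto_run)
    if nuclear and cyto:
        return "double"
    if nuclear:
        return "nuclear"
    if cyto:
        return "cytoplasmic"
    return "negative"


@dataclass
class EnsembleCounts:
    """Class fractions for one rat x region (cells pooled per image, then
    averaged across images so each rat contributes one value)."""

    rat_id: str
    region: str
    n_cells: int
    frac_nuclear: float
    frac_cytoplasmic: float
    frac_double: float
    frac_negative: float

    def __post_init__(self) -> None:
        total = (self.frac_nuclear + self.frac_cytoplasmic
                 + self.frac_double + self.frac_negative)
        if self.n_cells and abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, expected 1")


def count_population(cells: Sequence[CellRecord], **classify_kwargs) -> dict[str, float]:
    """Class fractions of one cell collection (e.g. one image)."""
    labels = [classify_cell(c, **classify_kwargs) for c in cells]
    n = len(labels)
    if n == 0:
        return {f"frac_{k}": np.nan for k in CLASS_LABELS} | {"n_cells": 0}
    out = {f"frac_{k}": labels.count(k) / n for k in CLASS_LABELS}
    out["n_cells"] = n
    return out


def ensemble_counts(
    cells: Sequence[CellRecord],
    median_fraction: float = 0.2,
    **classify_kwargs,
) -> list[EnsembleCounts]:
    """Filter, classify and aggregate cells into per-rat x region fractions.

    Fractions are computed per image and averaged across a rat's images, so
    every rat contributes a single mean regardless of how many images or
    cells it has — sample size downstream is the number of animals.
    """
    included = inclusion_filter(cells, median_fraction=median_fraction)
    rows = []
    for cell in included:
        rows.append({
            "rat_id": cell.rat_id, "region": cell.region, "image_id": cell.image_id,
            "label": classify_cell(cell, **classify_kwargs),
        })
    if not rows:
        return []
    df = pd.DataFrame(rows)
    out = []
    for (rat, region), sub in df.groupby(["rat_id", "region"], sort=True):
        per_image = (
            sub.groupby("image_id")["label"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=CLASS_LABELS, fill_value=0.0)
        )
        means = per_image.mean(axis=0)
        out.append(EnsembleCounts(
            rat_id=str(rat), region=str(region), n_cells=int(len(sub)),
            frac_nuclear=float(means["nuclear"]),
            frac_cytoplasmic=float(means["cytoplasmic"]),
            frac_double=float(means["double"]),
            frac_negative=float(means["negative"]),
        ))
    return out


def epoch_to_task(counts: EnsembleCounts, task_order: str,
                  double_mode: str = "both") -> dict[str, float]:
    """Attribute compartment fractions to tasks under counterbalanced order.

    Cytoplasmic label reflects the first epoch (mRNA had ~20 min to leave
    the nucleus) and nuclear label the second.  ``task_order`` is
    ``'task_first'`` (WM/BAT ran in epoch 1) or ``'task_second'``.  Output
    keys are task names: ``wmbat`` and ``alternation``.  ``double_mode``
    controls double-labelled cells: ``'both'`` adds them to both tasks'
    activity (needed for the similarity-score event algebra),
    ``'excluded'`` drops them.
    """
    if task_order not in ("task_first", "task_second"):
        raise ValueError("task_order must be 'task_first' or 'task_second'")
    if double_mode not in ("both", "excluded"):
        raise ValueError("double_mode must be 'both' or 'excluded'")
    double = counts.frac_double if double_mode == "both" else 0.0
    epoch1 = counts.frac_cytoplasmic + double
    epoch2 = counts.frac_nuclear + double
    if task_order == "task_first":
        return {"wmbat": epoch1, "alternation": epoch2}
    return {"wmbat": epoch2, "alternation": epoch1}


def similarity_score(p_a: float, p_b: float, p_ab: float) -> float:
    """Ensemble overlap normalized for activity levels.

    (p_ab - p_a p_b) / (min(p_a, p_b) - p_a p_b): 0 when the two epochs'
    ensembles overlap exactly as expected under independence, 1 when the
    smaller ensemble is entirely contained in the larger.
    """
    if not (0 <= p_ab <= min(p_a, p_b) + 1e-12):
        raise ValueError("need 0 <= p_ab <= min(p_a, p_b)")
    if p_a <= 0 or p_b <= 0:
        raise UndefinedSimilarityError("both ensembles must be non-empty")
    denom = min(p_a, p_b) - p_a * p_b
    if denom <= 0:
        raise UndefinedSimilarityError(
            "maximal overlap equals the independence expectation; score undefined"
        )
    return (p_ab - p_a * p_b) / denom
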