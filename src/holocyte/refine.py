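"""Training-set refinement by histogram-tail selective search.

Cell-level labels inherited from donor status are noisy: most cells in an SCD
sample look morphologically normal. The selective search scans every
morphological parameter for a histogram-tail threshold at which the fraction
of the SCD population in the tail exceeds the fraction of the normal
population by at least a fixed ratio (default 21:1). Cells in any qualifying
tail are termed *critically sickled*; their union, balanced by an equal-size
random draw of normal cells, forms the refined training set.

The tail ratio is defined on population fractions with pseudo-count smoothing:

    r(t) = [n_s(t) / N_s] / [(n_n(t) + c) / (N_n + c)]

where n(t) counts values in the closed tail (<= t for a lower tail, >= t for
an upper tail) and c is the pseudo-count (default 1), which prevents empty
normal tails from qualifying through division by zero. Among thresholds with
r(t) >= ratio the most inclusive one (maximal n_s) is returned, balancing
selectivity against a usable diseased-cell count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .morphometry import FEATURE_NAMES

__all__ = [
    "RefineConfig",
    "TailCriterion",
    "RefinedSet",
    "find_tail_criterion",
    "search_all_parameters",
    "build_refined_set",
    "refine_training_set",
]


@dataclass(frozen=True)
class RefineConfig:
    """Selective-search settings.

    ratio: minimum SCD:normal population-fraction ratio in a qualifying tail.
    min_refined_size: below this union size a warning is attached (the model
        downstream benefits from at least ~5000 training cells).
    pseudo_count: smoothing count added to the normal tail; 0 for the strict
        unsmoothed ratio.
    parameters_searched: feature names to scan (default: all 25).
    seed: RNG seed for drawing the matched normal subset.
    """

    ratio: float = 21.0
    min_refined_size: int = 5000
    pseudo_count: int = 1
    parameters_searched: tuple[str, ...] = FEATURE_NAMES
    seed: int = 0

    def __post_init__(self):
        if self.ratio <= 1:
            raise ConfigurationError("ratio must be > 1")
        if self.min_refined_size < 1:
            raise ConfigurationError("min_refined_size must be >= 1")
        if self.pseudo_count < 0:
            raise ConfigurationError("pseudo_count must be >= 0")


@dataclass(frozen=True)
class TailCriterion:
    """One qualifying tail rule: parameter, direction, threshold, bookkeeping."""

    parameter: str
    direction: str  # "lower" | "upper"
    threshold: float
    achieved_ratio: float
    n_scd_tail: int
    n_nor_tail: int

    def selects(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of values in the criterion's closed tail."""
        values = np.asarray(values, dtype=float)
        if self.direction == "lower":
            return values <= self.threshold
        return values >= self.threshold


@dataclass
class RefinedSet:
    """The refined training set: critically sickled cells + matched normals."""

    scd_indices: pd.Index
    provenance: dict  # cell index -> list of "parameter:direction" labels
    matched_nor_indices: pd.Index
    warning: str | None = None

    @property
    def size(self) -> int:
        return len(self.scd_indices)


def find_tail_criterion(
    values_scd,
    values_nor,
    direction: str,
    config: RefineConfig | None = None,
) -> TailCriterion | None:
    """Search one parameter/direction for a qualifying tail threshold.

    Candidate thresholds are the sorted unique values of the pooled data; the
    tail is closed (values equal to the threshold are included). Returns the
    most inclusive qualifying criterion, or None if no threshold achieves the
    configured ratio with at least one SCD cell in the tail.
    """
    config = config or RefineConfig()
    if direction not in ("lower", "upper"):
        raise ConfigurationError(f"direction must be 'lower' or 'upper', got {direction!r}")
    vs = np.sort(np.asarray(values_scd, dtype=float))
    vn = np.sort(np.asarray(values_nor, dtype=float))
    if vs.size == 0 or vn.size == 0:
        raise ConfigurationError("both value lists must be non-empty")
    n_s, n_n = vs.size, vn.size
    cands = np.unique(np.concatenate([vs, vn]))
    if direction == "lower":
        tail_s = np.searchsorted(vs, cands, side="right")
        tail_n = np.searchsorted(vn, cands, side="right")
    else:
        tail_s = n_s - np.searchsorted(vs, cands, side="left")
        tail_n = n_n - np.searchsorted(vn, cands, side="left")
    c = config.pseudo_count
    ratio = (tail_s / n_s) / ((tail_n + c) / (n_n + c))
    ok = (ratio >= config.ratio) & (tail_s >= 1)
    if not ok.any():
        return None
    qi = np.flatnonzero(ok)
    best = qi[np.argmax(tail_s[qi])]
    return TailCriterion(
        parameter="",
        direction=direction,
        threshold=float(cands[best]),
        achieved_ratio=float(ratio[best]),
        n_scd_tail=int(tail_s[best]),
        n_nor_tail=int(tail_n[best]),
    )


def search_all_parameters(
    table: pd.DataFrame, config: RefineConfig | None = None
) -> list[TailCriterion]:
    """Scan every configured parameter, both tail directions, for criteria.

    ``table`` must carry a ``label`` column with both classes plus the feature
    columns (post-QC). Each qualifying (parameter, direction) pair contributes
    at most one criterion; the list may be empty.
    """
    config = config or RefineConfig()
    if "label" not in table.columns:
        raise ConfigurationError("table must carry a 'label' column")
    scd = table[table["label"] == "SCD"]
    nor = table[table["label"] == "NOR"]
    if scd.empty or nor.empty:
        raise ConfigurationError("table must contain both SCD and NOR cells")
    criteria: list[TailCriterion] = []
    for param in config.parameters_searched:
        if param not in table.columns:
            raise ConfigurationError(f"table lacks feature {param!r}")
        vs = scd[param].to_numpy()
        vn = nor[param].to_numpy()
        for direction in ("lower", "upper"):
            crit = find_tail_criterion(vs, vn, direction, config)
            if crit is not None:
                criteria.append(
                    TailCriterion(
                        parameter=param,
                        direction=crit.direction,
                        threshold=crit.threshold,
                        achieved_ratio=crit.achieved_ratio,
                        n_scd_tail=crit.n_scd_tail,
                        n_nor_tail=crit.n_nor_tail,
                    )
                )
    return criteria


def build_refined_set(
    table: pd.DataFrame,
    criteria: list[TailCriterion],
    config: RefineConfig | None = None,
) -> RefinedSet:
    """Union the criterion tails into the refined SCD set and match normals.

    Matched normal cells are drawn uniformly without replacement using
    ``config.seed``. If fewer normals exist than selected SCD cells the set
    cannot be balanced and an error is raised; if the union is smaller than
    ``min_refined_size`` a warning is attached but the set is still returned.
    """
    config = config or RefineConfig()
    if not criteria:
        raise ConfigurationError("criteria list is empty")
    scd = table[table["label"] == "SCD"]
    nor = table[table["label"] == "NOR"]
    selected = pd.Series(False, index=scd.index)
    provenance: dict = {}
    for crit in criteria:
        hits = scd.index[crit.selects(scd[crit.parameter].to_numpy())]
        selected.loc[hits] = True
        tag = f"{crit.parameter}:{crit.direction}"
        for idx in hits:
            provenance.setdefault(idx, []).append(tag)
    scd_idx = scd.index[selected]
    if len(nor) < len(scd_idx):
        raise ConfigurationError(
            f"cannot balance: {len(scd_idx)} selected SCD cells but only {len(nor)} normals"
        )
    rng = np.random.default_rng(config.seed)
    pick = rng.choice(len(nor), size=len(scd_idx), replace=False)
    nor_idx = nor.index[np.sort(pick)]
    warning = None
    if len(scd_idx) < config.min_refined_size:
        warning = (
            f"refined set has {len(scd_idx)} cells, below the recommended "
            f"minimum of {config.min_refined_size}"
        )
    return RefinedSet(
        scd_indices=scd_idx,
        provenance=provenance,
        matched_nor_indices=nor_idx,
        warning=warning,
    )


def refine_training_set(
    table: pd.DataFrame, config: RefineConfig | None = None
) -> tuple[list[TailCriterion], RefinedSet]:
    """Convenience: search all parameters, then build the refined set."""
    config = config or RefineConfig()
    criteria = search_all_parameters(table, config)
    if not criteria:
        raise ConfigurationError("no parameter tail satisfied the search ratio")
    return criteria, build_refined_set(table, criteria, config)
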