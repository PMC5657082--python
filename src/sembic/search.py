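"""Noise-tolerant greedy binary biclustering.

The searcher minimizes an explicit cost combining the description length of
the bicluster system (sum of row and column counts over biclusters) with a
noise penalty ``rho * (false positives + false negatives)``, where a false
positive is a covered 0-cell and a false negative an uncovered 1-cell.
Biclusters are grown greedily from dense seed columns of the residual
(still-uncovered) 1-cells and accepted only while they strictly decrease
the total cost, which guarantees termination.  The trade-off parameter
``rho`` plays the role of the accepted-noise level: small ``rho`` favours
few large noisy biclusters, large ``rho`` forces near-exact covers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Bicluster, BiclusterSystem, ExpressionMatrix, _extension_mask
from .errors import DimensionError, ParameterError

__all__ = ["SearchConfig", "CostReport", "cost", "greedy_search", "select_rho"]


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the greedy search.

    rho
        Noise-versus-description trade-off; the cost of one false cell
        relative to one row/column of description.
    max_biclusters
        Hard cap on the number of extracted biclusters.
    min_rows, min_cols
        Candidates smaller than this on either dimension are discarded.
    seed
        Reserved for stochastic variants; the default search is
        deterministic and uses it only for reproducibility bookkeeping.
    """

    rho: float = 1.0
    max_biclusters: int = 50
    min_rows: int = 1
    min_cols: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ParameterError("rho must be > 0")
        if self.max_biclusters < 1 or self.min_rows < 1 or self.min_cols < 1:
            raise ParameterError("max_biclusters, min_rows and min_cols must be >= 1")


@dataclass(frozen=True)
class CostReport:
    """Decomposition of the total cost of a bicluster system on a matrix."""

    description_cost: int
    false_positives: int
    false_negatives: int
    total: float


def cost(system: BiclusterSystem, matrix: ExpressionMatrix, rho: float = 1.0) -> CostReport:
    """Total cost = description + rho * (covered 0s + uncovered 1s)."""
    if rho <= 0:
        raise ParameterError("rho must be > 0")
    mask = _extension_mask(system, matrix)
    ones = matrix.values.astype(bool)
    fp = int((mask & ~ones).sum())
    fn = int((~mask & ones).sum())
    desc = sum(len(bc.genes) + len(bc.situations) for bc in system)
    return CostReport(desc, fp, fn, desc + rho * (fp + fn))


def greedy_search(matrix: ExpressionMatrix, config: SearchConfig | None = None) -> BiclusterSystem:
    """Iteratively extract cost-decreasing biclusters from a binary matrix.

    Each round seeds a candidate with the column holding the most uncovered
    1-cells, grows it by strictly cost-decreasing column/row extension, and accepts it
    only if it strictly lowers the total system cost.  Deterministic:
    all ties are broken by index order.
    """
    if config is None:
        config = SearchConfig()
    if matrix.values.size == 0:
        raise DimensionError("cannot search an empty matrix")

    ones = matrix.values.astype(bool)
    covered = np.zeros_like(ones)  # union of accepted rectangles
    rho = config.rho
    system = BiclusterSystem([])

    for _ in range(config.max_biclusters):
        residual1 = ones & ~covered
        col_freq = residual1.sum(axis=0)
        if col_freq.max(initial=0) == 0:
            break
        seed_col = int(np.argmax(col_freq))

        # --- phase 1: exact core.  Rows are kept only while they hold a 1 in
        # every selected column, so the core rectangle contains no 0-cells.
        # Columns are added one at a time, each time picking the column that
        # maximizes the candidate's net benefit rho*new_tp - (|R|+|C|).
        rows = residual1[:, seed_col].copy()
        cols = np.zeros(ones.shape[1], dtype=bool)
        cols[seed_col] = True
        best_f = rho * residual1[rows][:, cols].sum() - (rows.sum() + 1)
        while True:
            tp_in_c = residual1[:, cols].sum(axis=1)  # per-row tp inside C
            cand_f = np.full(ones.shape[1], -np.inf)
            for d in np.flatnonzero(~cols):
                r_d = rows & ones[:, d]
                if not r_d.any():
                    continue
                tp = (tp_in_c + residual1[:, d])[r_d].sum()
                cand_f[d] = rho * tp - (r_d.sum() + cols.sum() + 1)
            d = int(np.argmax(cand_f))
            if not np.isfinite(cand_f[d]) or cand_f[d] <= best_f:
                break
            best_f = cand_f[d]
            rows &= ones[:, d]
            cols[d] = True

        # --- phase 2: noise-tolerant extension.  Rows/columns are appended
        # while each one strictly decreases the total cost: the marginal
        # change 1 + rho*new_fp - rho*new_tp must be negative.
        new0 = ~ones & ~covered  # cells that would incur a fresh fp penalty
        for _ in range(ones.shape[0] + ones.shape[1]):
            changed = False
            gain1 = residual1[rows].sum(axis=0).astype(float)
            loss0 = new0[rows].sum(axis=0).astype(float)
            add_cols = (rho * (gain1 - loss0) > 1.0) & ~cols
            if add_cols.any():
                cols |= add_cols
                changed = True
            gain1 = residual1[:, cols].sum(axis=1).astype(float)
            loss0 = new0[:, cols].sum(axis=1).astype(float)
            add_rows = (rho * (gain1 - loss0) > 1.0) & ~rows
            if add_rows.any():
                rows |= add_rows
                changed = True
            if not changed:
                break

        if rows.sum() < config.min_rows or cols.sum() < config.min_cols:
            break
        rect = np.ix_(np.flatnonzero(rows), np.flatnonzero(cols))
        new_fp = int(new0[rect].sum())
        new_tp = int(residual1[rect].sum())
        delta_total = (int(rows.sum()) + int(cols.sum())) + rho * (new_fp - new_tp)
        if delta_total >= 0:
            break  # candidate does not strictly decrease the total cost
        covered[rect] = True
        system.biclusters.append(
            Bicluster(
                frozenset(matrix.gene_ids[i] for i in np.flatnonzero(rows)),
                frozenset(matrix.situation_ids[j] for j in np.flatnonzero(cols)),
            )
        )
    return system


def select_rho(
    matrix: ExpressionMatrix,
    candidate_rhos: list[float],
    config: SearchConfig | None = None,
) -> float:
    """Pick the accepted-noise level minimizing realized total cost.

    Each candidate ``rho`` drives its own greedy search; the resulting
    systems are compared on a common reference scale (total cost at
    rho = 1).  Ties resolve to the smallest candidate.
    """
    if not candidate_rhos:
        raise ParameterError("candidate_rhos must be non-empty")
    base = config or SearchConfig()
    best_rho, best_cost = None, np.inf
    for r in sorted(candidate_rhos):
        cfg = SearchConfig(
            rho=r,
            max_biclusters=base.max_biclusters,
            min_rows=base.min_rows,
            min_cols=base.min_cols,
            seed=base.seed,
        )
        system = greedy_search(matrix, cfg)
        total = cost(system, matrix, rho=1.0).total
        if total < best_cost:
            best_rho, best_cost = r, total
    return float(best_rho)
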