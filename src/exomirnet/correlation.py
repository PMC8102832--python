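"""Anti-correlation screening of miRNA-gene pairs across paired samples.

Each candidate regulatory pair is scored by the sample Pearson correlation
between the miRNA's and the gene's expression over samples shared by the two
matrices, with the analytic p-value from the t transform (n - 2 degrees of
freedom) and an optional permutation p-value as a randomization control
against spurious correlations. BH q-values are computed over all tested
pairs, and the final screen keeps pairs with |r| >= 0.6, q <= 0.05 and a
negative sign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .enrichment import bh_adjust
from .io_formats import ExpressionMatrix

__all__ = [
    "CorrelationRecord",
    "pearson",
    "permutation_control",
    "strength_label",
    "correlate_pairs",
    "screen_pairs",
]


@dataclass(frozen=True)
class CorrelationRecord:
    """One miRNA-gene pair's correlation evidence over n paired samples."""

    mirna_id: str
    gene_id: str
    n: int
    r: float
    p: float
    q: float = float("nan")
    perm_p: float | None = None
    undefined: bool = False

    @property
    def strength(self) -> str:
        """|r| bins: weak < 0.4 <= moderate < 0.6 <= strong < 0.8 <= very_strong."""
        a = abs(self.r)
        if a < 0.4:
            return "weak"
        if a < 0.6:
            return "moderate"
        if a < 0.8:
            return "strong"
        return "very_strong"


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and its analytic p (t transform, n-2 df).

    Constant input is undefined: returns (nan, nan); callers flag and
    exclude such records from screening.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def permutation_control(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for |r|: (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1).

    The gene vector ``y`` is permuted with a seeded generator, so results
    are reproducible given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs, _ = pearson(x, y)
    if np.isnan(r_obs):
        return float("nan")
    xc = x - x.mean()
    xs = xc / np.sqrt((xc**2).sum())
    n_hit = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        yc = yp - yp.mean()
        denom = np.sqrt((yc**2).sum())
        r = float(xs @ yc / denom) if denom > 0 else 1.0
        if abs(r) >= abs(r_obs) - 1e-12:
            n_hit += 1
    return (1 + n_hit) / (n_perm + 1)


def strength_label(r: float) -> str:
    return CorrelationRecord("", "", 3, r, 1.0).strength


def correlate_pairs(
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    n_perm: int = 0,
    seed: int = 0,
) -> list[CorrelationRecord]:
    """Pearson (and optional permutation) statistics for each (miRNA, gene) pair.

    Samples are paired on shared sample ids; unmatched samples are dropped.
    BH q-values are computed over all non-degenerate tested pairs.
    """
    shared = [s for s in mirna_expr.sample_ids if s in set(gene_expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples between the matrices")
    rng = np.random.default_rng(seed)
    records: list[CorrelationRecord] = []
    for mirna, gene in pairs:
        if mirna not in mirna_expr.values.index or gene not in gene_expr.values.index:
            continue
        x = mirna_expr.values.loc[mirna, shared].to_numpy(dtype=float)
        y = gene_expr.values.loc[gene, shared].to_numpy(dtype=float)
        r, p = pearson(x, y)
        undefined = bool(np.isnan(r))
        perm_p = None
        if n_perm > 0 and not undefined:
            perm_p = permutation_control(x, y, n_perm=n_perm, seed=rng)
        records.append(
            CorrelationRecord(
                mirna_id=mirna, gene_id=gene, n=len(shared),
                r=r, p=p, perm_p=perm_p, undefined=undefined,
            )
        )
    tested = [rec for rec in records if not rec.undefined]
    if tested:
        qvals = bh_adjust([rec.p for rec in tested])
        qmap = {(rec.mirna_id, rec.gene_id): float(qv) for rec, qv in zip(tested, qvals)}
        records = [
            rec if rec.undefined else replace(rec, q=qmap[(rec.mirna_id, rec.gene_id)])
            for rec in records
        ]
    return records


def screen_pairs(
    records: Sequence[CorrelationRecord],
    r_cut: float = 0.6,
    q_cut: float = 0.05,
    require_negative: bool = True,
) -> list[CorrelationRecord]:
    """Final anti-correlation screen: |r| >= r_cut, q <= q_cut, r < 0.

    Records flagged undefined (constant expression) never pass. Output is
    sorted by r ascending (strongest negative correlation first).
    """
    kept = [
        rec
        for rec in records
        if not rec.undefined
        and abs(rec.r) >= r_cut
        and rec.q <= q_cut
        and (rec.r < 0 or not require_negative)
    ]
    return sorted(kept, key=lambda rec: (rec.r, rec.mirna_id, rec.gene_id))
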