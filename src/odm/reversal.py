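"""Signature-reversal compound ranking.

A query signature (genes with signed weights: DEG fold changes, or a
regulator's dependence score) is compared against each compound's
differential-expression signature with a connectivity-map-style weighted
Kolmogorov-Smirnov statistic: compound genes are ranked by signed fold
change, running-sum enrichment scores are computed for the query's up- and
down-gene sets, and ``score = (ES_up - ES_down) / 2``.  Negative scores
mean the compound's transcriptional effect opposes the query; significance
for reversal comes from a gene-label permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QuerySignature",
    "CompoundSignature",
    "ReversalResult",
    "connectivity_score",
    "permutation_p",
    "rank_compounds",
    "read_compound_library",
]


@dataclass
class QuerySignature:
    """Gene -> signed weight (uppercased symbols, no zero weights)."""

    entries: dict[str, float]

    def __post_init__(self) -> None:
        clean = {}
        for g, w in self.entries.items():
            w = float(w)
            if w == 0.0:
                raise ValueError(f"query weight for {g} is zero")
            clean[str(g).upper()] = w
        if len(clean) != len(self.entries):
            raise ValueError("duplicate gene symbols in query signature")
        self.entries = clean

    @property
    def up_genes(self) -> set[str]:
        return {g for g, w in self.entries.items() if w > 0}

    @property
    def down_genes(self) -> set[str]:
        return {g for g, w in self.entries.items() if w < 0}


@dataclass
class CompoundSignature:
    """A compound's DEG signature: gene -> signed fold change.

    ``from_table`` applies the load-time DEG filter (p < 0.05 and
    |FC| > 1.2).
    """

    compound: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        self.entries = {str(g).upper(): float(v) for g, v in self.entries.items()}

    @classmethod
    def from_table(
        cls,
        compound: str,
        table: pd.DataFrame,
        p_threshold: float = 0.05,
        fc_threshold: float = 1.2,
    ) -> "CompoundSignature":
        keep = table.loc[
            (table["p"] < p_threshold) & (table["signed_fc"].abs() > fc_threshold)
        ]
        return cls(compound, dict(zip(keep["gene"], keep["signed_fc"])))


def _running_es_batch(order_weights: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Weighted KS enrichment scores of member sets along a ranked list.

    ``order_weights``: |FC| of the ranked compound genes (descending signed
    order), shape (g,); ``member``: boolean membership, shape (..., g).  ES
    is the extreme deviation of hit-mass minus miss-mass; equal-magnitude
    positive and negative extremes give 0 (keeps negation antisymmetry
    exact).
    """
    member = np.atleast_2d(member)
    g = member.shape[-1]
    n_hit = member.sum(axis=1)
    w = np.where(member, order_weights[None, :], 0.0)
    total = w.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hit = np.cumsum(w, axis=1) / total
        p_miss = np.cumsum(~member, axis=1) / (g - n_hit)[:, None]
    dev = p_hit - p_miss
    mx = dev.max(axis=1)
    mn = dev.min(axis=1)
    es = np.where(mx > -mn, mx, np.where(-mn > mx, mn, 0.0))
    es[(n_hit == 0) | (n_hit == g) | (total[:, 0] <= 0)] = 0.0
    return es


def _raw_score(
    fc_sorted_abs: np.ndarray, up_mask: np.ndarray, down_mask: np.ndarray
) -> np.ndarray:
    """(ES_up - ES_down)/2; masks may be batched."""
    es_up = _running_es_batch(fc_sorted_abs, up_mask)
    es_down = _running_es_batch(fc_sorted_abs, down_mask)
    return (es_up - es_down) / 2.0


def _score_from_order(
    fc_sorted_abs: np.ndarray, up_mask: np.ndarray, down_mask: np.ndarray
) -> np.ndarray | float:
    """Connectivity score, antisymmetrized by construction.

    Negating a compound reverses its ranking, so the raw score of the
    negated compound is the raw score along the reversed order; taking
    ``(raw(order) - raw(reversed order)) / 2`` makes
    ``score(negate(c)) == -score(c)`` hold exactly in floating point while
    leaving the statistic unchanged up to rounding.
    """
    up_mask = np.asarray(up_mask)
    batched = up_mask.ndim > 1
    fwd = _raw_score(fc_sorted_abs, up_mask, down_mask)
    rev = _raw_score(fc_sorted_abs[::-1], up_mask[..., ::-1], down_mask[..., ::-1])
    score = np.clip((fwd - rev) / 2.0, -1.0, 1.0)
    return score if batched else float(score[0])


def _ordered(compound: CompoundSignature) -> tuple[list[str], np.ndarray]:
    """Compound genes ranked by signed FC descending, ties by gene id."""
    items = sorted(compound.entries.items(), key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in items]
    fc = np.array([v for _, v in items], float)
    return genes, fc


def connectivity_score(query: QuerySignature, compound: CompoundSignature) -> float | None:
    """Signed connectivity in [-1, 1]; None when no genes are shared
    (the compound is not comparable)."""
    genes, fc = _ordered(compound)
    up = np.array([g in query.up_genes for g in genes])
    down = np.array([g in query.down_genes for g in genes])
    if not (up.any() or down.any()):
        return None
    return _score_from_order(np.abs(fc), up, down)


def permutation_p(
    query: QuerySignature,
    compound: CompoundSignature,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> float:
    """One-sided permutation p for reversal: gene labels of the compound are
    shuffled, ``p = (1 + #{null <= observed}) / (n_perm + 1)``.

    ``exhaustive=True`` enumerates all label permutations instead (exact;
    only sensible for tiny signatures).
    """
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes, fc = _ordered(compound)
    absfc = np.abs(fc)
    up = np.array([g in query.up_genes for g in genes])
    down = np.array([g in query.down_genes for g in genes])
    observed = _score_from_order(absfc, up, down)
    if exhaustive:
        idx = np.array(list(permutations(range(len(genes)))))
        s = _score_from_order(absfc, up[idx], down[idx])
        return float(np.mean(s <= observed + 1e-12))
    rng = np.random.default_rng(seed)
    n_le = 0
    chunk = 512  # bound the permutation matrix footprint
    remaining = n_perm
    while remaining > 0:
        m = min(chunk, remaining)
        idx = np.argsort(rng.random((m, len(genes))), axis=1)
        s = _score_from_order(absfc, up[idx], down[idx])
        n_le += int(np.sum(s <= observed + 1e-12))
        remaining -= m
    return (1 + n_le) / (n_perm + 1)


@dataclass
class ReversalResult:
    compound: str
    score: float
    n_shared: int
    perm_p: float
    opposite_genes: list[str] = field(default_factory=list)


def rank_compounds(
    query: QuerySignature,
    library: list[CompoundSignature],
    n_perm: int = 999,
    seed: int = 0,
) -> list[ReversalResult]:
    """Rank a compound library by connectivity score, strongest reversal
    first (ties by permutation p, then compound id).

    Compounds sharing no genes with the query are excluded (logged).
    ``opposite_genes`` lists shared genes regulated in the opposite
    direction by the compound.
    """
    if not library:
        raise ValueError("compound library is empty")
    results = []
    skipped = []
    for compound in library:
        s = connectivity_score(query, compound)
        if s is None:
            skipped.append(compound.compound)
            continue
        p = permutation_p(query, compound, n_perm=n_perm, seed=seed)
        shared = set(compound.entries) & set(query.entries)
        opposite = sorted(
            g for g in shared if np.sign(compound.entries[g]) == -np.sign(query.entries[g])
        )
        results.append(
            ReversalResult(
                compound=compound.compound,
                score=s,
                n_shared=len(shared),
                perm_p=p,
                opposite_genes=opposite,
            )
        )
    if skipped:
        logger.warning("rank_compounds: excluded %d compounds sharing no genes: %s",
                       len(skipped), skipped[:5])
    results.sort(key=lambda r: (r.score, r.perm_p, r.compound))
    return results


def read_compound_library(
    path: str | Path, p_threshold: float = 0.05, fc_threshold: float = 1.2
) -> list[CompoundSignature]:
    """Compound signature TSV (compound, gene, signed_fc[, p]) filtered to
    each compound's DEGs at load time."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "p" not in df.columns:
        df = df.assign(p=0.0)
    out = []
    for cid, sub in df.groupby("compound", sort=True):
        out.append(CompoundSignature.from_table(str(cid), sub, p_threshold, fc_threshold))
    return out
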