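"""Hypergeometric over-representation and regulator target assignment.

Two enrichment modes share one engine: *functional* mode tests user gene
sets (GMT) against per-cluster DE genes at nominal p < 0.05; *regulator*
mode tests regulator target sets (derived from peak intervals and a 1000-bp
window upstream of the TSS and downstream of the TTS) against
dependence-associated DE genes, with Benjamini-Hochberg FDR control.

All coordinates are 0-based half-open internally (BED convention; GFF3 is
converted at parse time).  Gene symbols are uppercased at every boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "RegulatorSet",
    "hypergeom_upper_tail",
    "bh_adjust",
    "read_gmt",
    "read_annotation",
    "read_peaks",
    "assign_targets",
    "build_regulator_sets",
    "enrich",
]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe of symbols."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = {g.upper() for g in self.universe}
        restricted = {}
        for name, members in self.sets.items():
            restricted[name] = {g.upper() for g in members} & self.universe
        self.sets = restricted


@dataclass
class RegulatorSet:
    """A regulator's target genes with per-gene supporting peak counts."""

    regulator: str
    targets: set[str]
    peak_counts: dict[str, int] = field(default_factory=dict)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvals, float), method="bh")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: ``name <tab> description <tab> gene...`` per line."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
            sets[name] = [g.upper() for g in parts[2:] if g]
    return sets


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation (GFF3 or BED) as chrom/start/end/gene/strand,
    0-based half-open."""
    import pyranges as pr

    p = str(path)
    if p.endswith((".gff3", ".gff", ".gtf")):
        df = pr.read_gff3(p).df
        name_col = "Name" if "Name" in df.columns else "ID"
        out = pd.DataFrame(
            {
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
                "gene": df[name_col].astype(str).str.upper(),
                "strand": df["Strand"].astype(str),
            }
        )
    else:
        df = pr.read_bed(p).df
        out = pd.DataFrame(
            {
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
                "gene": df["Name"].astype(str).str.upper(),
                "strand": df["Strand"].astype(str) if "Strand" in df.columns else "+",
            }
        )
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Peak intervals (BED) as chrom/start/end/regulator (name column
    optional; unnamed peaks get regulator 'PEAK')."""
    import pyranges as pr

    df = pr.read_bed(str(path)).df
    return pd.DataFrame(
        {
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "regulator": df["Name"].astype(str) if "Name" in df.columns else "PEAK",
        }
    )


def assign_targets(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    window_bp: int = 1000,
    regulator: str | None = None,
) -> RegulatorSet:
    """Genes whose flanking window any peak overlaps.

    A gene is a target iff some peak overlaps the interval spanning the gene
    body extended by ``window_bp`` upstream of the strand-oriented TSS and
    ``window_bp`` downstream of the TTS (for a ``+`` gene:
    ``[start - w, end + w)``; for a ``-`` gene the genomic interval is the
    same because TSS/TTS swap ends).  Windows are clipped at 0.  Peaks on
    chromosomes absent from the annotation are skipped with a log message.
    """
    if regulator is None:
        regs = peaks["regulator"].unique() if "regulator" in peaks.columns else ["PEAK"]
        regulator = regs[0] if len(regs) == 1 else "PEAKSET"
    known = set(annotation["chrom"])
    unknown = peaks.loc[~peaks["chrom"].isin(known)]
    if len(unknown):
        logger.warning(
            "assign_targets: skipping %d peaks on unknown chromosomes %s",
            len(unknown), sorted(set(unknown["chrom"]))[:5],
        )
        peaks = peaks.loc[peaks["chrom"].isin(known)]
    targets: set[str] = set()
    counts: dict[str, int] = {}
    for chrom, anno_c in annotation.groupby("chrom", sort=False):
        pk = peaks.loc[peaks["chrom"] == chrom]
        if pk.empty:
            continue
        win_lo = np.maximum(anno_c["start"].to_numpy(int) - window_bp, 0)
        win_hi = anno_c["end"].to_numpy(int) + window_bp
        ps = pk["start"].to_numpy(int)
        pe = pk["end"].to_numpy(int)
        # half-open interval overlap, genes x peaks
        hit = (ps[None, :] < win_hi[:, None]) & (pe[None, :] > win_lo[:, None])
        n_hits = hit.sum(axis=1)
        for g, c in zip(anno_c["gene"], n_hits):
            if c > 0:
                targets.add(g)
                counts[g] = counts.get(g, 0) + int(c)
    return RegulatorSet(regulator=regulator, targets=targets, peak_counts=counts)


def build_regulator_sets(
    peaks: pd.DataFrame, annotation: pd.DataFrame, window_bp: int = 1000
) -> GeneSetCollection:
    """One target set per regulator (peaks grouped by their name column);
    universe = all annotated genes."""
    sets = {}
    for reg, pk in peaks.groupby("regulator", sort=True):
        sets[reg] = assign_targets(pk, annotation, window_bp, regulator=reg).targets
    return GeneSetCollection(sets=sets, universe=set(annotation["gene"]))


def enrich(
    query: set[str] | list[str],
    collection: GeneSetCollection,
    mode: str = "functional",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of every set in ``collection``
    among ``query`` genes.

    Query symbols are uppercased and restricted to the universe (dropped
    genes are counted in a log message).  Rows are sorted by p-value.  In
    ``regulator`` mode a Benjamini-Hochberg ``fdr_p`` column is added and
    significance is ``fdr_p < alpha``; in ``functional`` mode it is
    ``p < alpha``.
    """
    if mode not in ("functional", "regulator"):
        raise ValueError(f"unknown mode {mode!r}")
    q = {str(g).upper() for g in query}
    dropped = q - collection.universe
    if dropped:
        logger.warning("enrich: dropped %d query genes outside the universe", len(dropped))
    q &= collection.universe
    if not q:
        logger.warning("enrich: empty query after restriction to the universe")
        return pd.DataFrame(
            columns=["set", "k", "K", "n", "N", "p", "fdr_p", "significant"]
        ).set_index("set")
    N = len(collection.universe)
    n = len(q)
    rows = []
    for name, members in collection.sets.items():
        k = len(q & members)
        K = len(members)
        p = hypergeom_upper_tail(k, K, n, N) if K else 1.0
        rows.append((name, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"]).set_index("set")
    if mode == "regulator":
        out["fdr_p"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["fdr_p"] < alpha
    else:
        out["fdr_p"] = np.nan
        out["significant"] = out["p"] < alpha
    return out.sort_values(["p", "k"], kind="mergesort")
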