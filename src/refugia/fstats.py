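"""Allele-frequency based affinity statistics with block-jackknife errors.

Implements the standard unbiased moment estimators used in ancient-DNA
work:

* Hudson's Fst as a ratio of averages, with the small-sample correction
  of each population's heterozygosity (allele counts n1, n2):

      num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
      den = p1(1-p2) + p2(1-p1)

* outgroup f3(X, Y; O) = mean[(pO-pX)(pO-pY) - pO(1-pO)/(nO-1)], the
  shared drift of X and Y since their divergence from the outgroup (the
  bias term corrects the outgroup's finite sample size);

* f4(A, B; C, D) = mean[(pA-pB)(pC-pD)].  With A an outgroup and B a
  test population, f4 < 0 means the test population is closer to C and
  f4 > 0 closer to D.

Standard errors come from a weighted delete-one block jackknife over
contiguous SNP blocks that respect chromosome boundaries (Busing et al.
1999), robust to linkage between nearby SNPs.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FStatResult",
    "BlockPartition",
    "make_blocks",
    "block_jackknife",
    "fst_hudson",
    "f3_outgroup",
    "f4",
    "results_to_tsv",
]

#: default block density, about one block per this many SNPs
SNPS_PER_BLOCK = 200


@dataclass
class FStatResult:
    statistic: str  # fst | f3 | f4
    pops: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_snps: int
    n_blocks: int


@dataclass
class BlockPartition:
    """Per-SNP block labels: contiguous runs within chromosomes."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_blocks(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_blocks)


def _apportion(counts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` blocks over chromosomes,
    at least one block per chromosome."""
    n = counts.sum()
    quota = counts / n * total
    base = np.maximum(np.floor(quota).astype(int), 1)
    while base.sum() > total:  # forced minimums may overshoot
        i = int(np.argmax(base - quota))
        if base[i] <= 1:
            break
        base[i] -= 1
    remainder = total - base.sum()
    if remainder > 0:
        order = np.argsort(-(quota - base))
        for i in order[:remainder]:
            base[i] += 1
    return base


def make_blocks(
    snps: pd.DataFrame,
    target_blocks: int | None = None,
    block_span: float | None = None,
) -> BlockPartition:
    """Partition position-sorted SNPs into contiguous jackknife blocks.

    With ``target_blocks``, blocks are allocated to chromosomes in
    proportion to their SNP counts and split so sizes differ by at most
    one SNP within a chromosome.  With ``block_span`` (bp), blocks are
    fixed-width position windows.
    """
    m = len(snps)
    if target_blocks is None and block_span is None:
        target_blocks = max(2, m // SNPS_PER_BLOCK)
    labels = np.empty(m, dtype=int)
    chrom_groups = list(snps.groupby("chrom", sort=False))
    if target_blocks is not None:
        if target_blocks > m:
            raise ValueError(f"target_blocks={target_blocks} exceeds {m} SNPs")
        counts = np.array([len(sub) for _, sub in chrom_groups])
        alloc = _apportion(counts, target_blocks)
        next_label = 0
        for (chrom, sub), k in zip(chrom_groups, alloc):
            k = min(k, len(sub))
            pieces = np.array_split(np.arange(len(sub)), k)
            pos = snps.index.get_indexer(sub.index)
            for piece in pieces:
                labels[pos[piece]] = next_label
                next_label += 1
    else:
        next_label = 0
        for chrom, sub in chrom_groups:
            pos = snps.index.get_indexer(sub.index)
            start = sub["pos"].to_numpy()
            bins = ((start - start[0]) // block_span).astype(int)
            for b in np.unique(bins):
                labels[pos[bins == b]] = next_label
                next_label += 1
    return BlockPartition(labels=labels)


def block_jackknife(
    block_num: np.ndarray,
    block_den: np.ndarray,
    block_sizes: np.ndarray | None = None,
) -> tuple[float, float]:
    """Weighted delete-one-block jackknife for a ratio-of-sums statistic.

    ``block_num`` and ``block_den`` are per-block sums; the estimate is
    sum(num)/sum(den).  ``block_sizes`` (default: ``block_den``) weight
    the deletion (Busing et al. 1999); blocks of zero weight are dropped.
    For equal weights this reduces to the textbook delete-one jackknife.
    """
    num = np.asarray(block_num, dtype=float)
    den = np.asarray(block_den, dtype=float)
    m = np.asarray(block_sizes, dtype=float) if block_sizes is not None else den.copy()
    keep = m > 0
    if not keep.all():
        logger.info("block_jackknife: dropping %d zero-weight blocks",
                    int((~keep).sum()))
        num, den, m = num[keep], den[keep], m[keep]
    g = len(num)
    if g < 2:
        raise ValueError("need at least 2 usable blocks")
    N, D = num.sum(), den.sum()
    if D == 0:
        raise ValueError("denominator sums to zero")
    theta = N / D
    loo = (N - num) / (D - den)
    if np.ptp(loo) == 0 and loo[0] == theta:  # exact: no between-block spread
        return float(theta), 0.0
    n = m.sum()
    h = n / m
    theta_tilde = g * theta - ((1 - m / n) * loo).sum()
    tau = h * theta - (h - 1) * loo
    var = np.sum((tau - theta_tilde) ** 2 / (h - 1)) / g
    return float(theta), float(np.sqrt(var))


def _complete_case(blocks: BlockPartition, *freqs: np.ndarray) -> np.ndarray:
    ok = np.ones(len(blocks.labels), dtype=bool)
    for p in freqs:
        ok &= np.isfinite(np.asarray(p, dtype=float))
    return ok


def _jackknife_mean(
    d: np.ndarray, labels: np.ndarray
) -> tuple[float, float, int]:
    """Jackknife SE of a per-SNP mean with block SNP counts as weights."""
    nb = int(labels.max()) + 1
    num = np.bincount(labels, weights=d, minlength=nb)
    den = np.bincount(labels, minlength=nb).astype(float)
    used = den > 0
    if used.sum() < 2:
        raise ValueError("fewer than 2 usable blocks after SNP exclusion")
    est, se = block_jackknife(num[used], den[used])
    return est, se, int(used.sum())


def _zscore(est: float, se: float) -> float:
    if se > 0:
        return est / se
    return 0.0 if est == 0 else float(np.sign(est)) * np.inf


def fst_hudson(
    p1: np.ndarray, p2: np.ndarray,
    n1: np.ndarray, n2: np.ndarray,
    blocks: BlockPartition,
    pops: tuple[str, str] = ("pop1", "pop2"),
) -> FStatResult:
    """Hudson's Fst, ratio of averages, with block-jackknife SE.

    ``n1``, ``n2`` are per-SNP non-missing allele counts.  SNPs missing
    in either population are excluded (complete-case).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = _complete_case(blocks, p1, p2) & (n1 > 1) & (n2 > 1)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    labels = blocks.labels[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    nb = int(labels.max()) + 1 if labels.size else 0
    bn = np.bincount(labels, weights=num, minlength=nb)
    bd = np.bincount(labels, weights=den, minlength=nb)
    bs = np.bincount(labels, minlength=nb).astype(float)
    used = bs > 0
    if den.sum() == 0:
        raise ValueError("Fst undefined: denominator sums to zero")
    est, se = block_jackknife(bn[used], bd[used], bs[used])
    return FStatResult(
        statistic="fst", pops=pops, estimate=est, se=se, z=_zscore(est, se),
        n_snps=int(ok.sum()), n_blocks=int(used.sum()),
    )


def f3_outgroup(
    pX: np.ndarray, pY: np.ndarray, pO: np.ndarray,
    nO: np.ndarray, blocks: BlockPartition,
    pops: tuple[str, str, str] = ("X", "Y", "O"),
) -> FStatResult:
    """Outgroup f3(X, Y; O): shared drift of X and Y since the outgroup."""
    pX = np.asarray(pX, dtype=float)
    pY = np.asarray(pY, dtype=float)
    pO = np.asarray(pO, dtype=float)
    nO = np.asarray(nO, dtype=float)
    ok = _complete_case(blocks, pX, pY, pO) & (nO > 1)
    d = (pO[ok] - pX[ok]) * (pO[ok] - pY[ok]) - pO[ok] * (1 - pO[ok]) / (nO[ok] - 1)
    est, se, nb = _jackknife_mean(d, blocks.labels[ok])
    return FStatResult(
        statistic="f3", pops=pops, estimate=est, se=se, z=_zscore(est, se),
        n_snps=int(ok.sum()), n_blocks=nb,
    )


def f4(
    pA: np.ndarray, pB: np.ndarray, pC: np.ndarray, pD: np.ndarray,
    blocks: BlockPartition,
    pops: tuple[str, str, str, str] = ("A", "B", "C", "D"),
) -> FStatResult:
    """f4(A, B; C, D) = mean[(pA - pB)(pC - pD)] with jackknife SE."""
    arrs = [np.asarray(p, dtype=float) for p in (pA, pB, pC, pD)]
    ok = _complete_case(blocks, *arrs)
    a, b, c, d_ = (p[ok] for p in arrs)
    d = (a - b) * (c - d_)
    est, se, nb = _jackknife_mean(d, blocks.labels[ok])
    return FStatResult(
        statistic="f4", pops=pops, estimate=est, se=se, z=_zscore(est, se),
        n_snps=int(ok.sum()), n_blocks=nb,
    )


def results_to_tsv(results: list[FStatResult], path: str | os.PathLike) -> None:
    rows = []
    for r in results:
        p = list(r.pops) + [""] * (4 - len(r.pops))
        rows.append({
            "statistic": r.statistic,
            "popA": p[0], "popB": p[1], "popC": p[2], "popD": p[3],
            "estimate": r.estimate, "se": r.se, "z": r.z,
            "n_snps": r.n_snps, "n_blocks": r.n_blocks,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
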