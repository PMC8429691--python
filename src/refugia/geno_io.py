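"""Genotype and population-metadata I/O, filtering and per-population summaries.

The package works on diploid alt-allele dosage matrices (0/1/2, NaN for
missing) together with a population table that carries, for every
population, a representative coordinate (a hub for modern groups, an
averaged centroid for ancient ones), a mean age in years before present
and a geographic grouping label.

Two on-disk genotype representations are supported:

* a plain text matrix: whitespace-separated, ``NA`` for missing calls,
  a header row of SNP identifiers and the sample identifier in the first
  column.  SNP chromosome/position either come from a companion
  ``<stem>.map`` file (three whitespace-separated columns: chromosome,
  snp id, position) or, failing that, from identifiers of the form
  ``chrom:pos`` or ``chrom:pos:name``;
* the PLINK binary triplet (``.bed``/``.bim``/``.fam``, SNP-major),
  decoded with the usual 2-bit code (00 = two A1 alleles, 10 = one,
  11 = none, 01 = missing).  Calls count A1 alleles.  Haploid male X
  calls are expected on the diploid {0, 2} scale.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PopulationTable",
    "FilterConfig",
    "InbreedingResult",
    "read_genotypes",
    "write_genotypes",
    "merge_genotypes",
    "filter_maf",
    "ld_prune",
    "allele_frequencies",
    "inbreeding_fhat2",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# byte -> four alt-allele counts (NaN = missing), little-endian 2-bit pairs
_BED_DECODE = np.empty((256, 4), dtype=float)
_CODE_TO_CALL = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
for _byte in range(256):
    for _slot in range(4):
        _BED_DECODE[_byte, _slot] = _CODE_TO_CALL[(_byte >> (2 * _slot)) & 0b11]
_CALL_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


class GenotypeFormatError(ValueError):
    """Raised when a genotype file is malformed or internally inconsistent."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alt-allele dosage matrix.

    ``calls`` is float with values in {0, 1, 2} and NaN for missing.
    SNP metadata lives in ``snps`` (columns ``chrom``, ``pos``, ``id``),
    position-sorted within each chromosome.
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        self.snps = self.snps.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        n, m = len(self.samples), len(self.snps)
        if self.calls.shape != (n, m):
            raise GenotypeFormatError(
                f"calls shape {self.calls.shape} != ({n} samples, {m} snps)"
            )
        if len(set(self.samples)) != n:
            raise GenotypeFormatError("duplicate sample ids")
        if m:
            if self.snps["id"].duplicated().any():
                dup = self.snps.loc[self.snps["id"].duplicated(), "id"].iloc[0]
                raise GenotypeFormatError(f"duplicate snp id {dup!r}")
            for chrom, sub in self.snps.groupby("chrom", sort=False):
                if not sub["pos"].is_monotonic_increasing:
                    raise GenotypeFormatError(
                        f"positions not sorted on chromosome {chrom}"
                    )
        finite = self.calls[np.isfinite(self.calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise GenotypeFormatError("calls must be in {0,1,2} or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping SNP columns ``index`` (order preserved)."""
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.iloc[index],
            calls=self.calls[:, index],
        )


@dataclass
class PopulationTable:
    """Population metadata plus sample membership.

    ``table`` is indexed by population id with columns ``longitude``,
    ``latitude``, ``mean_bp``, ``interval_lo``, ``interval_hi``, ``group``.
    Modern populations have ``mean_bp == 0``; ancient ones carry a
    non-empty age interval.  ``membership`` maps sample id -> population id
    (every sample belongs to exactly one population).
    """

    table: pd.DataFrame
    membership: pd.Series

    def __post_init__(self) -> None:
        self.membership = pd.Series(self.membership)
        if self.membership.index.duplicated().any():
            raise ValueError("a sample occurs in more than one population")
        if (self.table["mean_bp"] < 0).any():
            raise ValueError("mean_bp must be >= 0")
        ancient = self.table["mean_bp"] > 0
        if ancient.any():
            lo = self.table.loc[ancient, "interval_lo"]
            hi = self.table.loc[ancient, "interval_hi"]
            if lo.isna().any() or hi.isna().any():
                raise ValueError("ancient populations need an age interval")
        unknown = set(self.membership) - set(self.table.index)
        if unknown:
            raise ValueError(f"members reference unknown populations: {sorted(unknown)}")

    @property
    def pop_ids(self) -> list[str]:
        return list(self.table.index)

    def members(self, pop_id: str) -> list[str]:
        return list(self.membership.index[self.membership == pop_id])

    def modern_ids(self, exclude_groups: tuple[str, ...] = ("outgroup",)) -> list[str]:
        t = self.table
        keep = (t["mean_bp"] == 0) & ~t["group"].isin(exclude_groups)
        return list(t.index[keep])

    def ancient_ids(self) -> list[str]:
        return list(self.table.index[self.table["mean_bp"] > 0])

    def coords(self, pop_id: str) -> tuple[float, float]:
        row = self.table.loc[pop_id]
        return float(row["longitude"]), float(row["latitude"])

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "PopulationTable":
        df = pd.read_csv(path)
        required = {"pop_id", "sample_id", "longitude", "latitude", "mean_bp"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"population CSV missing columns {sorted(missing)}")
        for col in ("interval_lo", "interval_hi"):
            if col not in df.columns:
                df[col] = np.nan
        if "group" not in df.columns:
            df["group"] = ""
        meta = (
            df.drop(columns=["sample_id"])
            .drop_duplicates("pop_id")
            .set_index("pop_id")
        )
        membership = pd.Series(
            df["pop_id"].to_numpy(), index=df["sample_id"].to_numpy()
        )
        return cls(table=meta, membership=membership)

    def to_csv(self, path: str | os.PathLike) -> None:
        rows = []
        for sample, pop in self.membership.items():
            row = {"pop_id": pop, "sample_id": sample}
            row.update(self.table.loc[pop].to_dict())
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class FilterConfig:
    """MAF and windowed LD-pruning settings (PLINK ``--maf``/``--indep-pairwise``
    style: the window and step count variants, not base pairs)."""

    maf_min: float = 0.05
    ld_window: int = 50
    ld_step: int = 10
    r2_max: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.ld_step > self.ld_window:
            raise ValueError("ld_step must not exceed ld_window")
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must be in (0, 1]")


@dataclass
class InbreedingResult:
    """Excess-homozygosity inbreeding summary for one population."""

    pop_id: str
    fhat2: pd.Series  # per-sample
    average: float
    median: float
    sd: float


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _snp_frame_from_ids(ids: list[str]) -> pd.DataFrame:
    """SNP metadata from bare identifiers: parse ``chrom:pos[:name]`` when
    possible, otherwise fall back to chromosome "1" and serial positions."""
    chroms, positions = [], []
    parsed = True
    for s in ids:
        parts = str(s).split(":")
        if len(parts) >= 2:
            try:
                positions.append(int(parts[1]))
                chroms.append(parts[0])
                continue
            except ValueError:
                pass
        parsed = False
        break
    if not parsed:
        chroms = ["1"] * len(ids)
        positions = list(range(1, len(ids) + 1))
    return pd.DataFrame({"chrom": chroms, "pos": positions, "id": ids})


def _read_text_matrix(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise GenotypeFormatError(f"{path}: empty header row")
        snp_ids = header[1:]
        samples: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            tokens = line.split()
            if not tokens:
                continue
            samples.append(tokens[0])
            if len(tokens) - 1 != len(snp_ids):
                raise GenotypeFormatError(
                    f"{path}:{lineno}: expected {len(snp_ids)} calls, "
                    f"got {len(tokens) - 1}"
                )
            row = np.array(
                [np.nan if t == "NA" else float(t) for t in tokens[1:]], dtype=float
            )
            rows.append(row)
    calls = (
        np.vstack(rows) if rows else np.empty((0, len(snp_ids)))
    )
    map_path = path.with_suffix(".map")
    if map_path.exists():
        snps = pd.read_csv(
            map_path, sep=r"\s+", header=None, names=["chrom", "id", "pos"],
            dtype={"chrom": str},
        )[["chrom", "pos", "id"]]
        if len(snps) != len(snp_ids) or list(snps["id"]) != snp_ids:
            raise GenotypeFormatError(
                f"{map_path}: snp list does not match header of {path}"
            )
    else:
        snps = _snp_frame_from_ids(snp_ids)
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def _read_plink_binary(prefix: Path) -> GenotypeMatrix:
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise GenotypeFormatError(f"missing PLINK file {p}")
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None)
    samples = fam_df.iloc[:, 1].astype(str).tolist()
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    snps = bim_df[["chrom", "pos", "id"]]
    n, m = len(samples), len(snps)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeFormatError(f"{bed}: bad magic bytes (not SNP-major .bed)")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise GenotypeFormatError(
            f"{bed}: size {body.size} does not match {n} samples x {m} snps"
        )
    decoded = _BED_DECODE[body.reshape(m, bytes_per_snp)].reshape(m, -1)[:, :n]
    return GenotypeMatrix(samples=samples, snps=snps, calls=decoded.T)


def read_genotypes(path: str | os.PathLike, format: str = "text-matrix") -> GenotypeMatrix:
    """Read a genotype matrix from disk.

    ``format`` is ``"text-matrix"`` (path to the matrix file) or
    ``"plink-binary"`` (path prefix of the ``.bed/.bim/.fam`` triplet).
    """
    path = Path(path)
    if format == "text-matrix":
        return _read_text_matrix(path)
    if format == "plink-binary":
        return _read_plink_binary(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str | os.PathLike,
                    format: str = "text-matrix") -> None:
    """Write ``g`` in the given format (text matrix + ``.map`` companion, or
    the PLINK binary triplet with placeholder alleles A/B)."""
    path = Path(path)
    if format == "text-matrix":
        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(g.snps["id"].astype(str)) + "\n")
            for i, s in enumerate(g.samples):
                vals = [
                    "NA" if not np.isfinite(v) else str(int(v))
                    for v in g.calls[i]
                ]
                fh.write(s + "\t" + "\t".join(vals) + "\n")
        g.snps[["chrom", "id", "pos"]].to_csv(
            path.with_suffix(".map"), sep="\t", header=False, index=False
        )
        return
    if format == "plink-binary":
        n, m = g.n_samples, g.n_snps
        fam = pd.DataFrame({
            0: g.samples, 1: g.samples, 2: 0, 3: 0, 4: 0, 5: -9,
        })
        fam.to_csv(path.with_suffix(".fam"), sep="\t", header=False, index=False)
        bim = pd.DataFrame({
            "chrom": g.snps["chrom"], "id": g.snps["id"], "cm": 0,
            "pos": g.snps["pos"], "a1": "A", "a2": "B",
        })
        bim.to_csv(path.with_suffix(".bim"), sep="\t", header=False, index=False)
        bytes_per_snp = (n + 3) // 4
        out = np.zeros((m, bytes_per_snp), dtype=np.uint8)
        for j in range(m):
            for i in range(n):
                v = g.calls[i, j]
                code = 0b01 if not np.isfinite(v) else _CALL_TO_CODE[float(v)]
                out[j, i // 4] |= code << (2 * (i % 4))
        with open(path.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC)
            fh.write(out.tobytes())
        return
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Merging and filtering
# ---------------------------------------------------------------------------

def merge_genotypes(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Union of samples on the intersection of SNPs keyed by (chrom, pos)."""
    clash = set(a.samples) & set(b.samples)
    if clash:
        raise ValueError(f"duplicate sample ids across inputs: {sorted(clash)[:5]}")
    key_a = pd.MultiIndex.from_frame(a.snps[["chrom", "pos"]])
    key_b = pd.MultiIndex.from_frame(b.snps[["chrom", "pos"]])
    common = key_a.intersection(key_b)
    ia = np.flatnonzero(key_a.isin(common))
    pos_b = pd.Series(np.arange(len(key_b)), index=key_b)
    ib = pos_b.loc[key_a[ia]].to_numpy()
    calls = np.vstack([a.calls[:, ia], b.calls[:, ib]]) if len(ia) else np.empty(
        (a.n_samples + b.n_samples, 0)
    )
    return GenotypeMatrix(
        samples=a.samples + b.samples,
        snps=a.snps.iloc[ia],
        calls=calls,
    )


def pooled_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP alt-allele frequency over all samples (NaN if all missing)."""
    with np.errstate(invalid="ignore"):
        alt = np.nansum(g.calls, axis=0)
        n = 2.0 * np.sum(np.isfinite(g.calls), axis=0)
        return np.where(n > 0, alt / np.where(n > 0, n, 1), np.nan)


def filter_maf(g: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs whose pooled minor-allele frequency is >= ``maf_min``.

    All-missing SNPs are dropped (logged).  SNP order is preserved.
    """
    p = pooled_frequencies(g)
    all_missing = ~np.isfinite(p)
    if all_missing.any():
        logger.info("filter_maf: dropping %d all-missing SNPs", all_missing.sum())
    maf = np.minimum(p, 1 - p)
    keep = np.flatnonzero(np.isfinite(p) & (maf >= maf_min))
    logger.info("filter_maf: kept %d / %d SNPs at maf >= %g", len(keep), g.n_snps, maf_min)
    return g.take_snps(keep)


def _pairwise_r2(calls: np.ndarray, min_obs: int = 3) -> np.ndarray:
    """Squared Pearson correlation of call vectors, pairwise-complete.

    Pairs with fewer than ``min_obs`` complete observations get r^2 = 0.
    """
    m = calls.shape[1]
    r2 = np.zeros((m, m))
    finite = np.isfinite(calls)
    for i in range(m):
        for j in range(i + 1, m):
            ok = finite[:, i] & finite[:, j]
            if ok.sum() < min_obs:
                continue
            x, y = calls[ok, i], calls[ok, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return r2


def ld_prune(g: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Greedy windowed LD pruning.

    Windows of ``cfg.ld_window`` SNPs slide by ``cfg.ld_step`` within each
    chromosome.  Inside a window, while any surviving pair exceeds
    ``cfg.r2_max`` in squared correlation (pairwise-complete), the later SNP
    of the worst pair is removed; removed SNPs are never reconsidered.
    """
    alive = np.ones(g.n_snps, dtype=bool)
    for chrom, sub in g.snps.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        start = 0
        while start < len(idx):
            window = idx[start:start + cfg.ld_window]
            w_alive = window[alive[window]]
            if len(w_alive) >= 2:
                r2 = _pairwise_r2(g.calls[:, w_alive])
                np.fill_diagonal(r2, 0.0)
                while True:
                    i, j = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, j] <= cfg.r2_max:
                        break
                    drop = max(i, j)  # later SNP of the worst pair
                    alive[w_alive[drop]] = False
                    r2[drop, :] = 0.0
                    r2[:, drop] = 0.0
            if start + cfg.ld_window >= len(idx):
                break
            start += cfg.ld_step
    kept = np.flatnonzero(alive)
    logger.info("ld_prune: kept %d / %d SNPs", len(kept), g.n_snps)
    return g.take_snps(kept)


# ---------------------------------------------------------------------------
# Per-population summaries
# ---------------------------------------------------------------------------

def allele_frequencies(
    g: GenotypeMatrix, pops: PopulationTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population alt-allele frequencies and non-missing allele counts.

    Returns (freqs, n_alleles), both SNP x population DataFrames indexed by
    SNP id.  A population with no calls at a SNP gets frequency NaN there.
    X-chromosome SNPs are treated identically to autosomal ones.
    """
    freqs = {}
    counts = {}
    for pop in pops.pop_ids:
        members = pops.members(pop)
        if not members:
            raise ValueError(f"population {pop!r} has no members")
        rows = [g.samples.index(s) for s in members]
        sub = g.calls[rows]
        n = 2.0 * np.sum(np.isfinite(sub), axis=0)
        alt = np.nansum(sub, axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(n > 0, alt / np.where(n > 0, n, 1), np.nan)
        if (n == 0).any():
            logger.info(
                "allele_frequencies: pop %s has %d all-missing SNPs",
                pop, int((n == 0).sum()),
            )
        freqs[pop] = p
        counts[pop] = n
    index = pd.Index(g.snps["id"], name="snp")
    return (
        pd.DataFrame(freqs, index=index),
        pd.DataFrame(counts, index=index),
    )


def inbreeding_fhat2(
    g: GenotypeMatrix, pops: PopulationTable
) -> dict[str, InbreedingResult]:
    """Excess-homozygosity inbreeding coefficient per sample, summarized per
    population.

    For each sample, F = (O - E) / (L - E) where O is the observed count of
    homozygous calls over the sample's L non-missing SNPs, and E sums the
    HWE-expected homozygosity 1 - 2 p (1-p) * 2n/(2n-1) with p the pooled
    full-sample frequency and n the pooled non-missing sample count at the
    SNP (small-sample correction).  Samples with no informative SNPs
    (L == E) are flagged NaN.
    """
    p = pooled_frequencies(g)
    n_samp = np.sum(np.isfinite(g.calls), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_het = 2 * p * (1 - p) * (2 * n_samp) / np.maximum(2 * n_samp - 1, 1)
    exp_hom = 1.0 - exp_het
    informative = np.isfinite(p) & (n_samp > 0)

    results: dict[str, InbreedingResult] = {}
    for pop in pops.pop_ids:
        per_sample = {}
        for s in pops.members(pop):
            i = g.samples.index(s)
            ok = np.isfinite(g.calls[i]) & informative
            L = float(ok.sum())
            O = float(np.isin(g.calls[i, ok], (0.0, 2.0)).sum())
            E = float(exp_hom[ok].sum())
            if L - E == 0:
                logger.warning("inbreeding_fhat2: sample %s has no informative SNPs", s)
                per_sample[s] = np.nan
            else:
                per_sample[s] = (O - E) / (L - E)
        vals = pd.Series(per_sample)
        results[pop] = InbreedingResult(
            pop_id=pop,
            fhat2=vals,
            average=float(vals.mean()),
            median=float(vals.median()),
            sd=float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        )
    return results
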