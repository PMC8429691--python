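"""Seeded synthetic landscapes, populations and genotypes.

The generator emulates isolation-by-resistance with time decay: K
populations sit on a raster landscape, and the shared drift between two
populations decays exponentially with the least-cost distance between
them (under a designated *true* friction model) and with their age gap.
Per SNP, an ancestral frequency p0 ~ Uniform(0.1, 0.9) is perturbed by a
multivariate-normal drift vector with covariance

    Sigma_ij = p0 (1 - p0) * s * exp(-beta_d * LCD_ij - beta_t * |dt|/1000)

(s an overall drift scale), an outgroup population drifts independently
with its own larger scale, frequencies are truncated to [0, 1], and
diploid genotypes are Binomial(2, p) with uniform missingness.  The
multivariate-normal form gives closed-form expected f-statistics, so
estimator output can be checked against theory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .friction import (
    FeatureLayer, FrictionGrid, FrictionModel, Raster, assemble_friction,
    write_ascii_grid,
)
from .geno_io import GenotypeMatrix, PopulationTable
from .least_cost import LCDMatrix, lcd_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "SynthDataset",
    "generate_landscape",
    "place_populations",
    "simulate_genotypes",
    "generate_dataset",
    "make_fixture",
    "theoretical_f3",
    "expected_f3_mc",
    "PERMEABLE_MODEL",
]

#: the permeable-landscape cost model (all surface features costed, straits
#: open): the configuration found to explain ancient ancestry best.
PERMEABLE_MODEL = FrictionModel.from_dict({
    "river": "costed",
    "glacier": "costed",
    "desert": "costed",
    "swamp": "costed",
    "bosporus": "costed",
    "channel": "costed",
    "riverside_desert": "costed",
})


def _default_prevalence() -> dict[str, float]:
    return {"glacier": 0.18, "desert": 0.22, "swamp": 0.12, "river": 0.08}


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults are desk-scale: a 40x40 grid of 50 km cells (a 2000 km
    domain), 12 populations (5 modern, 6 ancient, 1 outgroup), 5000
    SNPs on 10 chromosomes.  ``beta_d`` is drift decay per cost-km of
    least-cost distance, ``beta_t`` per kyr of age gap; ``drift_scale``
    and ``outgroup_drift`` multiply the binomial variance p0(1-p0) and
    are sized to give pairwise Fst of order 0.01-0.05, the magnitude
    seen between human populations at this depth.
    """

    shape: tuple[int, int] = (40, 40)
    cell_size: float = 50.0  # km
    elev_scale: float = 1.5  # controls TRI magnitude (cost units)
    elev_smooth: float = 2.0  # cells
    feature_smooth: float = 4.0  # cells; longer range -> few large blobs
    sea_fraction: float = 0.0
    feature_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    n_modern: int = 5
    n_ancient: int = 6
    samples_modern: int = 10
    samples_ancient: int = 10
    samples_outgroup: int = 10
    n_snps: int = 5000
    n_chrom: int = 10
    true_model: FrictionModel = field(default_factory=lambda: PERMEABLE_MODEL)
    beta_d: float = 3.2e-4  # per cost-km
    beta_t: float = 0.02    # per kyr
    drift_scale: float = 0.10
    outgroup_drift: float = 0.10
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "sea_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for v in self.feature_prevalence.values():
            if not 0 <= v <= 1:
                raise ValueError("feature prevalence must be in [0, 1]")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.beta_d < 0 or self.beta_t < 0:
            raise ValueError("beta_d and beta_t must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["true_model"] = self.true_model.as_dict()
        d["shape"] = list(self.shape)
        return json.dumps(d, sort_keys=True, indent=1)


@dataclass
class SynthDataset:
    config: SynthConfig
    elevation: Raster
    layers: dict[str, FeatureLayer]
    pops: PopulationTable
    grid_true: FrictionGrid
    lcd_true: LCDMatrix
    genotypes: GenotypeMatrix


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_landscape(
    cfg: SynthConfig, rng: np.random.Generator | None = None,
    max_retries: int = 10,
) -> tuple[Raster, dict[str, FeatureLayer]]:
    """Seeded elevation plus contiguous feature blobs at the configured
    prevalence.

    Elevation is Gaussian-smoothed white noise; each feature mask is a
    quantile threshold of an independent smoothed field (so the mask
    fraction matches the prevalence), intersected with land.  Riverside
    corridors in desert are additionally intersected with the desert
    mask.  Regenerates (up to ``max_retries``) until the largest land
    component holds at least 90% of land, so population sites share one
    component.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    geo = dict(x0=0.0, y0=cfg.shape[0] * cfg.cell_size, cell_size=cfg.cell_size)

    for attempt in range(max_retries):
        f = _smooth_field(rng, cfg.shape, cfg.elev_smooth)
        elev_values = cfg.elev_scale * f**3  # heavy tails: concentrated ridges
        if cfg.sea_fraction > 0:
            sea_field = _smooth_field(rng, cfg.shape, cfg.elev_smooth * 1.5)
            land = sea_field > np.quantile(sea_field, cfg.sea_fraction)
        else:
            land = np.ones(cfg.shape, dtype=bool)

        layers: dict[str, FeatureLayer] = {
            "land": FeatureLayer("land", Raster(land, **geo)),
        }
        desert_mask = None
        order = sorted(cfg.feature_prevalence)
        for klass in order:
            prev = cfg.feature_prevalence[klass]
            if prev <= 0:
                mask = np.zeros(cfg.shape, dtype=bool)
            else:
                f = _smooth_field(rng, cfg.shape, cfg.feature_smooth)
                mask = f > np.quantile(f, 1 - prev)
                if klass in ("glacier", "desert", "swamp", "river",
                             "riverside_desert"):
                    mask &= land
                if klass == "riverside_desert" and desert_mask is not None:
                    mask &= desert_mask
            if klass == "desert":
                desert_mask = mask
            layers[klass] = FeatureLayer(klass, Raster(mask, **geo))

        lab, n_comp = ndimage.label(land, structure=np.ones((3, 3)))
        if n_comp == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        if sizes.max() >= 0.9 * land.sum():
            elevation = Raster(elev_values, **geo)
            return elevation, layers
    raise RuntimeError(
        f"could not generate a connected landscape in {max_retries} attempts"
    )


def _largest_land_component(land: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(land, structure=np.ones((3, 3)))
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def place_populations(
    cfg: SynthConfig,
    elevation: Raster,
    layers: dict[str, FeatureLayer],
    rng: np.random.Generator,
) -> PopulationTable:
    """Spread population sites over the largest land component by greedy
    farthest-point sampling; assign ancient ages on 2 kyr intervals and
    geographic groups by grid quadrant."""
    land = _largest_land_component(layers["land"].mask.values)
    rr, cc = np.nonzero(land)
    n_total = cfg.n_modern + cfg.n_ancient + 1
    if len(rr) < n_total:
        raise ValueError("not enough land cells for the requested populations")

    chosen = [int(rng.integers(len(rr)))]
    d_min = np.full(len(rr), np.inf)
    for _ in range(n_total - 1):
        last = chosen[-1]
        d = (rr - rr[last]) ** 2 + (cc - cc[last]) ** 2
        d_min = np.minimum(d_min, d)
        chosen.append(int(np.argmax(d_min)))

    nrows = elevation.shape[0]
    rows = []
    for k, cell_i in enumerate(chosen):
        r, c = int(rr[cell_i]), int(cc[cell_i])
        x, y = elevation.cell_center(r, c)
        if k == 0:
            pid, bp, lo, hi, group = "OUT", 0.0, np.nan, np.nan, "outgroup"
        elif k <= cfg.n_modern:
            pid, bp, lo, hi = f"MOD{k}", 0.0, np.nan, np.nan
            group = "modern"
        else:
            j = k - cfg.n_modern
            interval = int(rng.integers(3, 15))  # 6-28 kyr BP, 2 kyr bins
            lo, hi = 2000.0 * interval, 2000.0 * interval + 2000.0
            bp = lo + 1000.0
            ns = "N" if r < nrows / 2 else "S"
            ew = "W" if c < elevation.shape[1] / 2 else "E"
            pid, group = f"ANC{j}", f"{ns}{ew}"
        rows.append(dict(pop_id=pid, longitude=x, latitude=y, mean_bp=bp,
                         interval_lo=lo, interval_hi=hi, group=group))
    table = pd.DataFrame(rows).set_index("pop_id")
    return PopulationTable(table=table, membership=pd.Series(dtype=object))


def _nearest_psd_factor(K: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of K, repairing indefiniteness by clipping
    negative eigenvalues to zero (nearest PSD in Frobenius norm)."""
    w, V = np.linalg.eigh((K + K.T) / 2)
    if w.min() < -1e-10:
        logger.info("covariance repaired: clipped eigenvalues down to %.3g", w.min())
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_genotypes(
    cfg: SynthConfig,
    lcd_true: LCDMatrix,
    pops: PopulationTable,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, PopulationTable]:
    """Draw per-population allele frequencies under the LCD/time-decay
    covariance and sample diploid genotypes with missingness."""
    ids = lcd_true.ids
    out_ids = [p for p in ids if pops.table.loc[p, "group"] == "outgroup"]
    bp = pops.table.loc[ids, "mean_bp"].to_numpy(dtype=float)
    npop = len(ids)

    K = np.empty((npop, npop))
    lcd = lcd_true.values
    for i in range(npop):
        for j in range(npop):
            dt = abs(bp[i] - bp[j]) / 1000.0
            K[i, j] = cfg.drift_scale * np.exp(-cfg.beta_d * lcd[i, j]
                                               - cfg.beta_t * dt)
    for o in out_ids:
        i = ids.index(o)
        K[i, :] = 0.0
        K[:, i] = 0.0
        K[i, i] = cfg.outgroup_drift
    L = _nearest_psd_factor(K)

    p0 = rng.uniform(0.1, 0.9, size=cfg.n_snps)
    z = rng.standard_normal(size=(npop, cfg.n_snps))
    drift = (L @ z) * np.sqrt(p0 * (1 - p0))
    freqs = np.clip(p0 + drift, 0.0, 1.0)

    samples: list[str] = []
    membership: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for i, pid in enumerate(ids):
        group = pops.table.loc[pid, "group"]
        if group == "outgroup":
            ns = cfg.samples_outgroup
        elif pops.table.loc[pid, "mean_bp"] > 0:
            ns = cfg.samples_ancient
        else:
            ns = cfg.samples_modern
        calls = rng.binomial(2, freqs[i], size=(ns, cfg.n_snps)).astype(float)
        blocks.append(calls)
        for k in range(ns):
            name = f"{pid}_{k}"
            samples.append(name)
            membership[name] = pid
    calls = np.vstack(blocks)
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls[miss] = np.nan

    per_chrom = np.array_split(np.arange(cfg.n_snps), max(1, cfg.n_chrom))
    chroms = np.empty(cfg.n_snps, dtype=object)
    positions = np.empty(cfg.n_snps, dtype=int)
    for ci, idx in enumerate(per_chrom, start=1):
        chroms[idx] = str(ci)
        positions[idx] = np.arange(1, len(idx) + 1) * 1000
    snps = pd.DataFrame({
        "chrom": chroms, "pos": positions,
        "id": [f"snp{ci}_{p}" for ci, p in zip(chroms, positions)],
    })

    geno = GenotypeMatrix(samples=samples, snps=snps, calls=calls)
    pops_full = PopulationTable(
        table=pops.table.copy(), membership=pd.Series(membership)
    )
    return geno, pops_full


def theoretical_f3(cfg: SynthConfig, c_xy: float) -> float:
    """Closed-form expected outgroup-f3 for a pair with decay factor
    ``c_xy`` (ignoring [0,1] truncation of frequencies).

    E[f3] = E[p0(1-p0)] * (outgroup_drift + drift_scale * c_xy) with
    p0 ~ Uniform(0.1, 0.9), so E[p0(1-p0)] = 59/300.
    """
    vbar = 59.0 / 300.0
    return vbar * (cfg.outgroup_drift + cfg.drift_scale * c_xy)


def expected_f3_mc(
    cfg: SynthConfig, c_xy: float, n_draws: int = 400_000, seed: int = 987_654,
) -> float:
    """Exact expected outgroup-f3 for a pair with decay factor ``c_xy``,
    including the [0, 1] truncation of frequencies, by direct Monte
    Carlo of the generative law (independent of the estimator path).

    The f3 estimator is unbiased for E[(pO - pX)(pO - pY)] at the
    population-frequency level (its correction removes the outgroup's
    finite-sample term), so no genotype sampling is needed here.
    """
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.1, 0.9, size=n_draws)
    s, so = cfg.drift_scale, cfg.outgroup_drift
    cov = np.array([
        [s, s * c_xy, 0.0],
        [s * c_xy, s, 0.0],
        [0.0, 0.0, so],
    ])
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(3))
    e = (L @ rng.standard_normal((3, n_draws))) * np.sqrt(p0 * (1 - p0))
    p = np.clip(p0 + e, 0.0, 1.0)
    return float(np.mean((p[2] - p[0]) * (p[2] - p[1])))


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Full seeded bundle: landscape -> sites -> true-model LCD ->
    genotypes."""
    rng = np.random.default_rng(cfg.seed)
    elevation, layers = generate_landscape(cfg, rng)
    pops = place_populations(cfg, elevation, layers, rng)
    grid_true = assemble_friction(elevation, layers, cfg.true_model)
    lcd_true = lcd_matrix(grid_true, pops)
    geno, pops = simulate_genotypes(cfg, lcd_true, pops, rng)
    return SynthDataset(
        config=cfg, elevation=elevation, layers=layers, pops=pops,
        grid_true=grid_true, lcd_true=lcd_true, genotypes=geno,
    )


def make_fixture(seed: int, outdir: str | os.PathLike,
                 cfg: SynthConfig | None = None) -> SynthDataset:
    """Write a small deterministic dataset bundle (text formats only).

    Defaults to 10 populations (4 modern, 5 ancient, 1 outgroup), 2000
    SNPs on a 40x40 grid; regeneration with the same seed reproduces
    byte-identical files.
    """
    from .geno_io import write_genotypes

    if cfg is None:
        cfg = SynthConfig(seed=seed, n_modern=4, n_ancient=5, n_snps=2000)
    else:
        cfg = dataclasses.replace(cfg, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(cfg)
    write_genotypes(ds.genotypes, outdir / "genotypes.txt", format="text-matrix")
    ds.pops.to_csv(outdir / "populations.csv")
    write_ascii_grid(ds.elevation, outdir / "elevation.asc")
    for klass, layer in ds.layers.items():
        write_ascii_grid(
            Raster(layer.mask.values.astype(int), layer.mask.x0, layer.mask.y0,
                   layer.mask.cell_size),
            outdir / f"mask_{klass}.asc",
        )
    (outdir / "true_model.json").write_text(cfg.true_model.to_json() + "\n")
    (outdir / "config.json").write_text(cfg.to_json() + "\n")
    ds.lcd_true.to_tsv(outdir / "lcd_true.tsv")
    return ds
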