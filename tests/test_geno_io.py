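import numpy as np
import pandas as pd
import pytest

from refugia.geno_io import (
    FilterConfig, GenotypeFormatError, GenotypeMatrix, allele_frequencies,
    filter_maf, inbreeding_fhat2, ld_prune, merge_genotypes, read_genotypes,
    write_genotypes,
)

from conftest import make_genotypes, make_pops


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

def test_text_matrix_parsing(tmp_path):
    path = tmp_path / "g.txt"
    path.write_text("sample\trs1\trs2\trs3\nA\t0\t1\t2\nB\t2\tNA\t0\n")
    g = read_genotypes(path)
    assert g.samples == ["A", "B"]
    assert g.calls[0, 2] == 2
    assert np.isnan(g.calls[1, 1])
    assert g.calls[1, 0] == 2


def test_empty_snp_list_is_valid(tmp_path):
    path = tmp_path / "g.txt"
    path.write_text("sample\nA\nB\n")
    g = read_genotypes(path)
    assert g.n_snps == 0 and g.n_samples == 2


@pytest.mark.parametrize("format", ["text-matrix", "plink-binary"])
def test_roundtrip(tmp_path, format):
    rng = np.random.default_rng(7)
    g = make_genotypes(rng, 10, 50)
    path = tmp_path / ("g.txt" if format == "text-matrix" else "g")
    write_genotypes(g, path, format=format)
    back = read_genotypes(path, format=format)
    assert back.samples == g.samples
    assert list(back.snps["id"]) == list(g.snps["id"])
    np.testing.assert_array_equal(np.isnan(back.calls), np.isnan(g.calls))
    np.testing.assert_array_equal(back.calls[~np.isnan(g.calls)],
                                  g.calls[~np.isnan(g.calls)])


def test_bad_magic_bytes_named(tmp_path):
    g = make_genotypes(np.random.default_rng(0), 4, 6)
    write_genotypes(g, tmp_path / "g", format="plink-binary")
    (tmp_path / "g.bed").write_bytes(b"\x00\x00\x00garbage")
    with pytest.raises(GenotypeFormatError, match="g.bed"):
        read_genotypes(tmp_path / "g", format="plink-binary")


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _tiny(samples, snp_keys, calls):
    snps = pd.DataFrame(
        [{"chrom": c, "pos": p, "id": f"{c}:{p}"} for c, p in snp_keys]
    )
    return GenotypeMatrix(samples=samples, snps=snps,
                          calls=np.asarray(calls, dtype=float))


def test_merge_intersects_snps():
    a = _tiny(["s1"], [("1", 10), ("1", 20)], [[0, 1]])
    b = _tiny(["s2"], [("1", 20), ("1", 30)], [[2, 0]])
    merged = merge_genotypes(a, b)
    assert list(merged.snps["pos"]) == [20]
    assert merged.calls[:, 0].tolist() == [1, 2]


def test_merge_disjoint_gives_zero_columns():
    a = _tiny(["s1"], [("1", 10)], [[0]])
    b = _tiny(["s2"], [("2", 10)], [[1]])
    assert merge_genotypes(a, b).n_snps == 0


def test_merge_doubles_rows_keeps_columns():
    rng = np.random.default_rng(1)
    a = make_genotypes(rng, 5, 20, missing_rate=0)
    b = GenotypeMatrix(samples=[s + "_b" for s in a.samples],
                       snps=a.snps, calls=a.calls.copy())
    merged = merge_genotypes(a, b)
    assert merged.n_samples == 10 and merged.n_snps == 20


def test_merge_duplicate_sample_errors():
    a = _tiny(["s1"], [("1", 10)], [[0]])
    with pytest.raises(ValueError, match="duplicate sample"):
        merge_genotypes(a, a)


def test_merge_commutative_up_to_row_order():
    rng = np.random.default_rng(2)
    a = make_genotypes(rng, 3, 15)
    b = make_genotypes(rng, 4, 15)
    b.samples = [s + "x" for s in b.samples]
    ab, ba = merge_genotypes(a, b), merge_genotypes(b, a)
    assert set(ab.samples) == set(ba.samples)
    order = [ba.samples.index(s) for s in ab.samples]
    np.testing.assert_array_equal(
        np.nan_to_num(ab.calls, nan=-1), np.nan_to_num(ba.calls[order], nan=-1)
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_filter_maf_edges():
    g = _tiny(["a", "b"], [("1", 1), ("1", 2)], [[0, 1], [0, 1]])
    # first SNP monomorphic (p=0), second p=0.5
    out = filter_maf(g, 0.05)
    assert list(out.snps["pos"]) == [2]


def test_filter_maf_matches_brute_force():
    rng = np.random.default_rng(3)
    g = make_genotypes(rng, 20, 100)
    out = filter_maf(g, 0.1)
    kept = 0
    for j in range(g.n_snps):  # independent per-SNP tally
        col = g.calls[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        p = col.sum() / (2 * col.size)
        if min(p, 1 - p) >= 0.1:
            kept += 1
    assert out.n_snps == kept


def _ld_prune_reference(g, cfg):
    """Independent O(n^2)-per-window reimplementation of the greedy rule."""
    def r2(x, y):
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            return 0.0
        return np.corrcoef(x[ok], y[ok])[0, 1] ** 2

    alive = set(range(g.n_snps))
    for chrom in g.snps["chrom"].unique():
        idx = list(g.snps.index[g.snps["chrom"] == chrom])
        start = 0
        while start < len(idx):
            window = [i for i in idx[start:start + cfg.ld_window] if i in alive]
            changed = True
            while changed and len(window) >= 2:
                worst, pair = 0.0, None
                for ii in range(len(window)):
                    for jj in range(ii + 1, len(window)):
                        v = r2(g.calls[:, window[ii]], g.calls[:, window[jj]])
                        if v > worst:
                            worst, pair = v, (ii, jj)
                if worst > cfg.r2_max:
                    drop = window[max(pair)]
                    alive.discard(drop)
                    window.remove(drop)
                else:
                    changed = False
            if start + cfg.ld_window >= len(idx):
                break
            start += cfg.ld_step
    return sorted(alive)


def test_ld_prune_removes_later_of_perfect_pair():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 3, 30).astype(float)
    calls = np.column_stack([x, x])
    g = _tiny([f"i{k}" for k in range(30)], [("1", 1), ("1", 2)], calls)
    out = ld_prune(g, FilterConfig(r2_max=0.3, ld_window=50, ld_step=10))
    assert list(out.snps["pos"]) == [1]


def test_ld_prune_keeps_uncorrelated():
    g = _tiny(
        ["a", "b", "c", "d"], [("1", 1), ("1", 2)],
        [[0, 0], [0, 2], [2, 0], [2, 2]],  # r = 0 exactly
    )
    out = ld_prune(g, FilterConfig(r2_max=0.3))
    assert out.n_snps == 2


def test_ld_prune_matches_reference_oracle():
    rng = np.random.default_rng(5)
    base = rng.integers(0, 3, size=(40, 20)).astype(float)
    base[:, 7] = base[:, 3]          # exact duplicates across the window
    base[:, 15] = 2 - base[:, 12]
    base[rng.random(base.shape) < 0.05] = np.nan
    g = make_genotypes(rng, 40, 20, missing_rate=0, n_chrom=1)
    g.calls = base
    cfg = FilterConfig(r2_max=0.3, ld_window=8, ld_step=3)
    out = ld_prune(g, cfg)
    expected = _ld_prune_reference(g, cfg)
    assert list(out.snps["id"]) == list(g.snps["id"].iloc[expected])


def test_maf_then_ld_prune_idempotent(small_dataset):
    cfg = FilterConfig()
    g1 = ld_prune(filter_maf(small_dataset.genotypes, cfg.maf_min), cfg)
    g2 = ld_prune(filter_maf(g1, cfg.maf_min), cfg)
    assert g2.n_snps == g1.n_snps


# ---------------------------------------------------------------------------
# frequencies and inbreeding
# ---------------------------------------------------------------------------

def test_allele_frequencies_small_cases():
    g = _tiny(["a", "b", "c"], [("1", 1), ("1", 2)],
              [[1, 2], [np.nan, 2], [np.nan, 2]])
    pops = make_pops({"P": ["a"], "Q": ["b", "c"]})
    freqs, counts = allele_frequencies(g, pops)
    assert freqs.loc["1:1", "P"] == 0.5      # one het sample
    assert freqs.loc["1:2", "Q"] == 1.0      # all hom-alt
    assert np.isnan(freqs.loc["1:1", "Q"])   # all-missing flagged
    assert counts.loc["1:2", "Q"] == 4


def test_allele_frequencies_match_direct_tally():
    rng = np.random.default_rng(6)
    g = make_genotypes(rng, 12, 40)
    pops = make_pops({"P": g.samples[:5], "Q": g.samples[5:]})
    freqs, counts = allele_frequencies(g, pops)
    for j, snp in enumerate(g.snps["id"]):
        col = g.calls[:5, j]
        col = col[~np.isnan(col)]
        if col.size:
            assert freqs.loc[snp, "P"] == pytest.approx(col.sum() / (2 * col.size))
    # pooled frequency = member-count-weighted mean without missingness
    g2 = make_genotypes(rng, 10, 30, missing_rate=0)
    pops2 = make_pops({"P": g2.samples[:4], "Q": g2.samples[4:]})
    f2, c2 = allele_frequencies(g2, pops2)
    pooled = g2.calls.sum(axis=0) / (2 * g2.n_samples)
    weighted = (f2["P"] * 4 + f2["Q"] * 6) / 10
    np.testing.assert_allclose(weighted.to_numpy(), pooled, atol=1e-12)


def test_fhat2_hand_cases():
    # fully homozygous sample at p=0.5 SNPs -> F -> 1
    calls = np.array([[0, 2, 0, 2]] * 2 + [[1, 1, 1, 1]] * 2, dtype=float)
    g = _tiny([f"i{k}" for k in range(4)],
              [("1", p) for p in (1, 2, 3, 4)], calls)
    pops = make_pops({"P": g.samples})
    res = inbreeding_fhat2(g, pops)["P"]
    assert res.fhat2["i0"] > 0.9
    assert res.fhat2["i2"] < -0.9  # fully heterozygous, the opposite limit


def test_fhat2_matches_manual_recomputation():
    rng = np.random.default_rng(8)
    g = make_genotypes(rng, 5, 60, missing_rate=0.1)
    pops = make_pops({"P": g.samples})
    res = inbreeding_fhat2(g, pops)["P"]
    # spreadsheet-style recomputation for one sample
    p = np.nansum(g.calls, axis=0) / (2 * np.sum(~np.isnan(g.calls), axis=0))
    n = np.sum(~np.isnan(g.calls), axis=0)
    ehom = 1 - 2 * p * (1 - p) * (2 * n) / (2 * n - 1)
    for i, s in enumerate(g.samples):
        ok = ~np.isnan(g.calls[i]) & ~np.isnan(p)
        O = np.isin(g.calls[i, ok], (0.0, 2.0)).sum()
        E = ehom[ok].sum()
        L = ok.sum()
        assert res.fhat2[s] == pytest.approx((O - E) / (L - E), abs=1e-12)


def test_fhat2_panmictic_average_near_zero():
    rng = np.random.default_rng(9)
    p = rng.uniform(0.1, 0.9, 2000)
    calls = rng.binomial(2, p, size=(100, 2000)).astype(float)
    g = make_genotypes(rng, 100, 2000, missing_rate=0)
    g.calls = calls
    pops = make_pops({"P": g.samples})
    res = inbreeding_fhat2(g, pops)["P"]
    assert abs(res.average) < 0.02
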