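"""Panel construction: HWE exact test, QC, relatedness, CN pseudo-marker codec."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from starimpute.panel import (
    CopyNumberCall,
    GenotypeMatrix,
    decode_copy_number,
    encode_copy_number,
    estimate_relatedness,
    hwe_exact_test,
    make_marker_table,
    merge_pseudo_markers,
    qc_filter,
    remove_pseudo_markers,
)


def hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-rational enumeration of the conditional HWE test (independent oracle)."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    if min(na, 2 * n - na) == 0:
        return 1.0
    na = min(na, 2 * n - na)
    probs = {}
    for het in range(na % 2, na + 1, 2):
        hom_minor = (na - het) // 2
        hom_major = n - hom_minor - het
        if hom_major < 0:
            continue
        probs[het] = (
            Fraction(math.factorial(n), math.factorial(hom_minor)
                     * math.factorial(het) * math.factorial(hom_major))
            * Fraction(2) ** het
            * Fraction(math.factorial(na) * math.factorial(2 * n - na),
                       math.factorial(2 * n))
        )
    obs_het = n_ab if 2 * n_aa + n_ab == na else n_ab  # symmetric in het count
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


def all_genotype_configs(max_n):
    for n in range(1, max_n + 1):
        for n_aa in range(n + 1):
            for n_ab in range(n - n_aa + 1):
                yield n_aa, n_ab, n - n_aa - n_ab


def test_hwe_matches_exhaustive_oracle_up_to_ten_samples():
    for n_aa, n_ab, n_bb in all_genotype_configs(10):
        got = hwe_exact_test(n_aa, n_ab, n_bb)
        want = hwe_oracle(n_aa, n_ab, n_bb)
        assert got == pytest.approx(want, abs=1e-10), (n_aa, n_ab, n_bb)


@pytest.mark.parametrize(
    "counts,expected",
    [((0, 2, 0), 1.0), ((1, 0, 1), 1 / 3), ((0, 0, 50), 1.0)],
)
def test_hwe_worked_examples(counts, expected):
    assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-9)


def test_hwe_rejects_empty_input():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------- CN codec

@pytest.mark.parametrize("cn,expected", [(0, (2, 0)), (1, (1, 0)), (2, (0, 0)),
                                         (3, (0, 1)), (4, (0, 2))])
def test_encode_copy_number(cn, expected):
    df = encode_copy_number([CopyNumberCall("s", cn)])
    assert (df.loc[0, "del_count"], df.loc[0, "dup_count"]) == expected


def test_encode_rejects_cn_above_four():
    with pytest.raises(ValueError, match="CN=5"):
        encode_copy_number([CopyNumberCall("s", 5)])


@pytest.mark.parametrize("cn", range(5))
def test_encode_decode_roundtrip(cn):
    df = encode_copy_number([CopyNumberCall("s", cn)])
    call = decode_copy_number(df.loc[0, "del_count"], df.loc[0, "dup_count"])
    assert call.cn == cn
    assert call.expected_cn == pytest.approx(cn)


def test_decode_fractional_dosage_and_ties():
    assert decode_copy_number(0.2, 0.9).expected_cn == pytest.approx(2.7)
    assert decode_copy_number(0.2, 0.9).cn == 3
    # exact half-way ties resolve toward the reference state CN=2
    assert decode_copy_number(0.5, 0.0).cn == 2
    assert decode_copy_number(0.0, 0.5).cn == 2
    with pytest.raises(ValueError):
        decode_copy_number(2.5, 0.0)


# ---------------------------------------------------------------- QC filter

def _matrix(geno, sample_prefix="s"):
    geno = np.asarray(geno, dtype=float)
    n, m = geno.shape
    markers = make_marker_table(
        [f"m{j}" for j in range(m)], ["22"] * m, np.arange(1, m + 1) * 100,
        ["A"] * m, ["G"] * m,
    )
    return GenotypeMatrix([f"{sample_prefix}{i}" for i in range(n)], markers, geno)


def _clean_matrix(rng, n=60, m=40):
    freqs = rng.uniform(0.3, 0.5, size=m)  # common variants: MAF and HWE safe
    geno = rng.binomial(2, freqs, size=(n, m)).astype(float)
    return _matrix(geno)


def test_qc_excludes_high_missingness_marker(rng):
    g = _clean_matrix(rng)
    g.geno[:3, 0] = np.nan  # 5% missing > 3% threshold
    out, report = qc_filter(g)
    assert report.excluded_markers["marker_missingness"] == 1
    assert "m0" not in out.markers["id"].tolist()


def test_qc_clean_matrix_is_identity_and_idempotent(rng):
    g = _clean_matrix(rng)
    out1, r1 = qc_filter(g)
    assert out1.n_samples == g.n_samples and out1.n_markers == g.n_markers
    out2, r2 = qc_filter(out1)
    np.testing.assert_array_equal(out1.geno, out2.geno)
    assert all(v == 0 for v in r2.excluded_markers.values())
    assert all(v == 0 for v in r2.excluded_samples.values())


def test_qc_excludes_heterozygosity_outlier(rng):
    g = _clean_matrix(rng, n=80)
    g.geno[5, :] = 1.0  # fully heterozygous sample, > 3 SD above the rest
    out, report = qc_filter(g)
    assert report.excluded_samples["heterozygosity"] >= 1
    assert "s5" not in out.samples


def test_qc_report_conserves_counts(rng):
    g = _clean_matrix(rng)
    g.geno[:3, 0] = np.nan
    g.geno[5, :] = 1.0
    out, rep = qc_filter(g)
    assert rep.n_markers_in == sum(rep.excluded_markers.values()) + rep.n_markers_out
    assert rep.n_samples_in == sum(rep.excluded_samples.values()) + rep.n_samples_out


def test_qc_error_names_emptying_step(rng):
    g = _clean_matrix(rng, n=10, m=5)
    g.geno[:, :] = np.nan
    with pytest.raises(ValueError, match="marker_missingness"):
        qc_filter(g)


# ---------------------------------------------------------------- relatedness

def _random_genotypes(rng, n, m=300):
    freqs = rng.uniform(0.1, 0.5, size=m)
    return rng.binomial(2, freqs, size=(n, m)).astype(float), freqs


def test_duplicate_sample_has_pihat_one_and_is_excluded(rng):
    geno, _ = _random_genotypes(rng, 20)
    geno[1] = geno[0]
    g = _matrix(geno)
    excluded, pihat = estimate_relatedness(g, cutoff=0.15)
    assert pihat[("s0", "s1")] > 0.9
    assert "s1" in excluded and "s0" not in excluded


def test_unrelated_pairs_have_near_zero_pihat(rng):
    geno, _ = _random_genotypes(rng, 20, m=500)
    # strongly negative cutoff reports every pair, so the full distribution is visible
    _, pihat = estimate_relatedness(_matrix(geno), cutoff=-10.0)
    values = np.array(list(pihat.values()))
    assert abs(values.mean()) < 0.02  # Monte-Carlo error around 0
    excluded, flagged = estimate_relatedness(_matrix(geno), cutoff=0.15)
    assert excluded == []


def test_parent_offspring_pihat_near_half(rng):
    m = 600
    freqs = rng.uniform(0.2, 0.5, size=m)
    haps = (rng.random((6, m)) < freqs).astype(float)
    father = haps[0] + haps[1]
    mother = haps[2] + haps[3]
    child = haps[0] + haps[2]  # one transmitted haplotype per parent
    background = rng.binomial(2, freqs, size=(10, m)).astype(float)
    geno = np.vstack([father, mother, child, background])
    excluded, pihat = estimate_relatedness(_matrix(geno), cutoff=0.15)
    assert pihat[("s0", "s2")] == pytest.approx(0.5, abs=0.12)
    assert pihat[("s1", "s2")] == pytest.approx(0.5, abs=0.12)


def test_relatedness_needs_enough_markers(rng):
    geno, _ = _random_genotypes(rng, 5, m=20)
    with pytest.raises(ValueError, match="markers"):
        estimate_relatedness(_matrix(geno))


# ---------------------------------------------------------------- merge

def _panel_with_calls(rng, n=8, m=6):
    geno = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    g = _matrix(geno)
    g.markers["chrom"] = "22"
    g.markers["pos"] = np.linspace(42_400_000, 42_700_000, m).astype(int)
    calls = [CopyNumberCall(f"s{i}", cn) for i, cn in
             enumerate([2, 2, 1, 3, 2, 0, 4, 2][:n])]
    return g, calls


def test_merge_roundtrip_and_ordering(rng):
    g, calls = _panel_with_calls(rng)
    merged = merge_pseudo_markers(g, encode_copy_number(calls))
    assert merged.n_markers == g.n_markers + 2
    assert merged.markers["pos"].is_monotonic_increasing
    back = remove_pseudo_markers(merged)
    np.testing.assert_array_equal(back.geno, g.geno)
    assert back.markers["id"].tolist() == g.markers["id"].tolist()


def test_merge_passes_encoded_genotypes_through(rng):
    g, calls = _panel_with_calls(rng)
    enc = encode_copy_number(calls)
    merged = merge_pseudo_markers(g, enc)
    j_del = merged.markers.index[merged.markers["id"] == "CYP2D6_DEL"][0]
    j_dup = merged.markers.index[merged.markers["id"] == "CYP2D6_DUP"][0]
    np.testing.assert_array_equal(merged.geno[:, j_del], enc["del_count"].to_numpy(float))
    np.testing.assert_array_equal(merged.geno[:, j_dup], enc["dup_count"].to_numpy(float))


def test_merge_rejects_sample_mismatch_and_collision(rng):
    g, calls = _panel_with_calls(rng)
    with pytest.raises(ValueError, match="sample sets differ"):
        merge_pseudo_markers(g, encode_copy_number(calls[:-1]))
    g2 = g.subset()
    g2.markers.loc[0, "pos"] = 42522500
    with pytest.raises(ValueError, match="collides"):
        merge_pseudo_markers(g2, encode_copy_number(calls))
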