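"""Li–Stephens haplotype-copying HMM for pseudo-marker imputation.

A target haplotype is modelled as an imperfect mosaic copy of the K phased
reference haplotypes.  The hidden state at marker m is the reference
haplotype being copied; between adjacent markers the chain switches to a
uniformly chosen haplotype with probability rho_m, and at each typed site
the emitted allele matches the copied haplotype with probability 1 - theta
(miscopy/genotype error theta).  Untyped sites emit uniformly, so the
posterior copying distribution there is shaped purely by the flanking typed
sites — which is exactly how a CNV pseudo-marker, absent from every target,
is imputed from its tag haplotypes.

The recursions are the scaled forward–backward standard; the uniform-switch
structure keeps each update O(K), so a whole cohort is linear in
markers × haplotypes × samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from starimpute.panel import (
    PSEUDO_DEL_ID,
    PSEUDO_DUP_ID,
    CopyNumberCall,
    GenotypeMatrix,
    decode_copy_number,
)

MISSING = -1  # allele code for untyped sites in a target haplotype


@dataclass
class HMMParams:
    """Copying-model parameters.

    rho : scalar or per-interval vector of switch probabilities in (0, 1)
    theta : per-site miscopy probability, in (0, 0.5)
    """

    rho: float | np.ndarray = 0.05
    theta: float = 0.01

    def __post_init__(self) -> None:
        rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if np.any(rho <= 0) or np.any(rho >= 1):
            raise ValueError("switch probabilities must lie in (0, 1)")
        if not 0 < self.theta < 0.5:
            raise ValueError("theta must lie in (0, 0.5)")

    def rho_vector(self, n_intervals: int) -> np.ndarray:
        rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if rho.size == 1:
            return np.full(n_intervals, rho[0])
        if rho.size != n_intervals:
            raise ValueError(f"rho has {rho.size} entries, need {n_intervals}")
        return rho


@dataclass
class HaplotypePanel:
    """K phased reference haplotypes over M position-sorted markers."""

    haplotypes: np.ndarray  # K x M, int 0/1 (pseudo-marker alleles included)
    markers: pd.DataFrame
    hap_samples: list[str] | None = None  # sample label per haplotype (2 per diploid)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D K x M array")
        if self.haplotypes.shape[1] != len(self.markers):
            raise ValueError("haplotype width does not match marker table")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("panel haplotypes must be fully called 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.markers["id"].to_numpy() == marker_id)
        if hits.size == 0:
            raise KeyError(f"marker {marker_id!r} not in panel")
        return int(hits[0])

    def drop_markers(self, idx) -> "HaplotypePanel":
        keep = np.setdiff1d(np.arange(self.n_markers), np.asarray(idx))
        return HaplotypePanel(
            self.haplotypes[:, keep],
            self.markers.iloc[keep].reset_index(drop=True),
            self.hap_samples,
        )


def compute_switch_probs(
    intervals: int | np.ndarray, K: int, scale: float
) -> np.ndarray:
    """Per-interval switch probabilities rho_m = 1 - exp(-scale * d_m / K).

    ``intervals`` is either the number of intervals (unit distances) or a
    vector of inter-marker distances.  Monotone increasing in distance.
    """
    if K < 2:
        raise ValueError("panel must contain at least 2 haplotypes")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if np.isscalar(intervals):
        d = np.ones(int(intervals), dtype=float)
    else:
        d = np.asarray(intervals, dtype=float)
        if np.any(d <= 0):
            raise ValueError("inter-marker distances must be positive")
    return -np.expm1(-scale * d / K)


def default_scale(K: int, switch_at_unit: float = 0.05) -> float:
    """Scale giving rho ≈ ``switch_at_unit`` at unit distance for panel size K."""
    return -K * np.log1p(-switch_at_unit)


def _emission(panel_col: np.ndarray, allele: int, theta: float) -> np.ndarray:
    if allele == MISSING:
        return np.ones_like(panel_col, dtype=float)
    return np.where(panel_col == allele, 1.0 - theta, theta)


def forward_backward(
    target_hap: np.ndarray, panel: HaplotypePanel, params: HMMParams
) -> np.ndarray:
    """Posterior copying probabilities, one row per marker.

    ``target_hap`` holds alleles 0/1 with :data:`MISSING` at untyped sites.
    Returns an M × K matrix whose rows each sum to 1.
    """
    target_hap = np.asarray(target_hap)
    K, M = panel.n_haplotypes, panel.n_markers
    if K == 0:
        raise ValueError("empty reference panel")
    if target_hap.shape != (M,):
        raise ValueError(f"target length {target_hap.shape} != panel markers ({M},)")
    if np.all(target_hap == MISSING):
        raise ValueError("target haplotype has no typed sites")
    rho = params.rho_vector(M - 1) if M > 1 else np.empty(0)
    theta = params.theta
    H = panel.haplotypes

    fwd = np.empty((M, K))
    f = np.full(K, 1.0 / K) * _emission(H[:, 0], target_hap[0], theta)
    f /= f.sum()
    fwd[0] = f
    for m in range(1, M):
        f = (1.0 - rho[m - 1]) * f + rho[m - 1] / K
        f *= _emission(H[:, m], target_hap[m], theta)
        f /= f.sum()
        fwd[m] = f

    post = np.empty((M, K))
    b = np.ones(K)
    post[M - 1] = fwd[M - 1]
    for m in range(M - 2, -1, -1):
        be = b * _emission(H[:, m + 1], target_hap[m + 1], theta)
        b = (1.0 - rho[m]) * be + rho[m] * be.mean()
        b /= b.sum()
        row = fwd[m] * b
        post[m] = row / row.sum()
    return post


def impute_alleles(
    post: np.ndarray, panel: HaplotypePanel, untyped: np.ndarray
) -> np.ndarray:
    """P(allele = 1) at each requested site: sum_k post[m, k] * panel[k, m]."""
    untyped = np.asarray(untyped)
    if untyped.size and (untyped.min() < 0 or untyped.max() >= panel.n_markers):
        raise IndexError("untyped site index out of range")
    return np.array(
        [float(post[m] @ panel.haplotypes[:, m]) for m in untyped]
    )


def _batched_site_posteriors(
    targets: np.ndarray,
    panel: HaplotypePanel,
    params: HMMParams,
    sites: np.ndarray,
    chunk: int = 64,
) -> np.ndarray:
    """Allele-1 posteriors at ``sites`` for many target haplotypes at once.

    Runs the same scaled forward–backward as :func:`forward_backward` but
    keeps state only at the requested sites, chunking target haplotypes to
    bound memory.  Returns an (n_targets, n_sites) matrix of P(allele=1).
    """
    targets = np.asarray(targets)
    K, M = panel.n_haplotypes, panel.n_markers
    H = panel.haplotypes.astype(np.float64)
    rho = params.rho_vector(M - 1) if M > 1 else np.empty(0)
    theta = params.theta
    sites = np.asarray(sites)
    site_set = {int(s): i for i, s in enumerate(sites)}
    n_t = targets.shape[0]
    out = np.empty((n_t, sites.size))

    for start in range(0, n_t, chunk):
        T = targets[start : start + chunk]  # h x M
        h = T.shape[0]

        def emis(m: int) -> np.ndarray:
            col = H[:, m]
            alle = T[:, m][:, None]  # h x 1
            e = np.where(alle == col[None, :], 1.0 - theta, theta)
            e[alle[:, 0] == MISSING] = 1.0
            return e  # h x K

        f = np.full((h, K), 1.0 / K) * emis(0)
        f /= f.sum(axis=1, keepdims=True)
        f_saved = {}
        if 0 in site_set:
            f_saved[0] = f.copy()
        for m in range(1, M):
            f = (1.0 - rho[m - 1]) * f + rho[m - 1] / K
            f *= emis(m)
            f /= f.sum(axis=1, keepdims=True)
            if m in site_set:
                f_saved[m] = f.copy()

        b = np.ones((h, K))
        if (M - 1) in site_set:
            row = f_saved[M - 1]
            out[start : start + h, site_set[M - 1]] = row @ H[:, M - 1]
        for m in range(M - 2, -1, -1):
            be = b * emis(m + 1)
            b = (1.0 - rho[m]) * be + rho[m] * be.mean(axis=1, keepdims=True)
            b /= b.sum(axis=1, keepdims=True)
            if m in site_set:
                row = f_saved[m] * b
                row /= row.sum(axis=1, keepdims=True)
                out[start : start + h, site_set[m]] = row @ H[:, m]
    return out


def phase_target_naive(
    genotypes: np.ndarray, panel: HaplotypePanel, params: HMMParams
) -> tuple[np.ndarray, np.ndarray]:
    """Heuristic phasing of one unphased target against the panel.

    The first haplotype follows the Viterbi copying path constrained to the
    genotype: homozygous sites force the allele, heterozygous sites take the
    allele of the copied reference haplotype.  The second haplotype is the
    complement, so the pair always sums to the genotype.
    """
    genotypes = np.asarray(genotypes)
    K, M = panel.n_haplotypes, panel.n_markers
    if genotypes.shape != (M,):
        raise ValueError("genotype length does not match panel markers")
    rho = params.rho_vector(M - 1) if M > 1 else np.empty(0)
    theta = params.theta
    H = panel.haplotypes

    def site_emission(m: int) -> np.ndarray:
        g = genotypes[m]
        if g == MISSING or g == 1:
            return np.ones(K)
        forced = g // 2
        return np.where(H[:, m] == forced, 1.0 - theta, theta)

    # max-product Viterbi in log space with uniform-switch transitions
    logd = np.log(site_emission(0) / K)
    back = np.zeros((M, K), dtype=np.int32)
    for m in range(1, M):
        stay = np.log(1.0 - rho[m - 1] + rho[m - 1] / K) + logd
        jump = np.log(rho[m - 1] / K) + logd.max()
        argmax_prev = int(np.argmax(logd))
        new = np.maximum(stay, jump)
        back[m] = np.where(stay >= jump, np.arange(K), argmax_prev)
        logd = new + np.log(site_emission(m))
        logd -= logd.max()
    path = np.empty(M, dtype=np.int32)
    path[M - 1] = int(np.argmax(logd))
    for m in range(M - 1, 0, -1):
        path[m - 1] = back[m, path[m]]

    hap1 = np.empty(M, dtype=np.int8)
    for m in range(M):
        g = genotypes[m]
        if g == MISSING:
            hap1[m] = H[path[m], m]
        elif g == 1:
            hap1[m] = H[path[m], m]
        else:
            hap1[m] = g // 2
    g_filled = np.where(genotypes == MISSING, hap1 * 2, genotypes)
    hap2 = (g_filled - hap1).astype(np.int8)
    return hap1, hap2


def _cn_posterior(p_del: np.ndarray, p_dup: np.ndarray) -> dict[int, float]:
    """CN class distribution from two haplotypes' DEL/DUP allele posteriors.

    Each haplotype contributes −1 (DEL), +1 (DUP) or 0 to CN = 2 + sum,
    treating the two haplotypes as independent and DEL/DUP as mutually
    exclusive on one haplotype.
    """
    dists = []
    for pd_, pu_ in zip(p_del, p_dup, strict=True):
        pd_, pu_ = float(np.clip(pd_, 0, 1)), float(np.clip(pu_, 0, 1))
        total = pd_ + pu_
        if total > 1.0:  # renormalize: one haplotype cannot carry both
            pd_, pu_ = pd_ / total, pu_ / total
        dists.append({-1: pd_, +1: pu_, 0: max(0.0, 1.0 - pd_ - pu_)})
    post: dict[int, float] = {}
    for c1, w1 in dists[0].items():
        for c2, w2 in dists[1].items():
            cn = 2 + c1 + c2
            post[cn] = post.get(cn, 0.0) + w1 * w2
    total = sum(post.values())
    return {cn: w / total for cn, w in sorted(post.items()) if w > 0 or cn == 2}


def impute_cnv_cohort(
    target_haps: np.ndarray,
    target_samples: list[str],
    panel: HaplotypePanel,
    params: HMMParams | None = None,
) -> tuple[list[CopyNumberCall], pd.DataFrame]:
    """Impute CYP2D6 DEL/DUP pseudo-markers into pre-phased target samples.

    ``target_haps`` is a (2·n_samples) × M' matrix over the panel's
    non-pseudo markers, haplotype pairs adjacent, with :data:`MISSING`
    allowed.  Returns best-guess copy-number calls (decoded via the
    dosage rule, posterior over CN classes attached) and a per-sample
    dosage table.
    """
    if params is None:
        params = HMMParams(
            rho=float(compute_switch_probs(1, panel.n_haplotypes,
                                           default_scale(panel.n_haplotypes))[0]),
            theta=0.01,
        )
    try:
        del_idx = panel.marker_index(PSEUDO_DEL_ID)
        dup_idx = panel.marker_index(PSEUDO_DUP_ID)
    except KeyError as exc:
        raise ValueError(
            f"panel lacks pseudo-marker {exc.args[0]}: merge copy-number "
            "calls into the panel before imputing"
        ) from exc

    target_haps = np.asarray(target_haps)
    if target_haps.shape[0] != 2 * len(target_samples):
        raise ValueError("need exactly two haplotypes per target sample")
    non_pseudo = np.flatnonzero(~panel.markers["is_pseudo"].to_numpy(bool))
    if target_haps.shape[1] == panel.n_markers:
        raise ValueError("target haplotypes must not include the pseudo-markers")
    if target_haps.shape[1] != non_pseudo.size:
        raise ValueError(
            f"target width {target_haps.shape[1]} != panel non-pseudo markers "
            f"({non_pseudo.size})"
        )
    # lift targets onto the full marker grid with pseudo sites untyped
    full = np.full((target_haps.shape[0], panel.n_markers), MISSING, dtype=np.int16)
    full[:, non_pseudo] = target_haps
    sites = np.array([del_idx, dup_idx])
    p_alt = _batched_site_posteriors(full, panel, params, sites)  # (2n, 2)

    calls, rows = [], []
    for i, sid in enumerate(target_samples):
        p_del = p_alt[2 * i : 2 * i + 2, 0]
        p_dup = p_alt[2 * i : 2 * i + 2, 1]
        del_dose = float(np.clip(p_del.sum(), 0, 2))
        dup_dose = float(np.clip(p_dup.sum(), 0, 2))
        post = _cn_posterior(p_del, p_dup)
        call = decode_copy_number(del_dose, dup_dose, sample_id=sid, posterior=post)
        calls.append(call)
        rows.append(
            {
                "sample_id": sid,
                "del_dosage": del_dose,
                "dup_dosage": dup_dose,
                "expected_cn": call.expected_cn,
                "best_guess_cn": call.cn,
                **{f"p_cn{k}": v for k, v in post.items()},
            }
        )
    return calls, pd.DataFrame(rows)


def genotype_matrix_to_unphased(g: GenotypeMatrix) -> np.ndarray:
    """Genotype matrix rows as integer allele counts with MISSING for nan."""
    out = np.where(np.isnan(g.geno), MISSING, g.geno).astype(np.int16)
    return out


def phase_cohort(
    targets: GenotypeMatrix, panel: HaplotypePanel, params: HMMParams
) -> np.ndarray:
    """Naively phase every target sample; returns (2n, M) haplotypes."""
    geno = genotype_matrix_to_unphased(targets)
    haps = np.empty((2 * targets.n_samples, targets.n_markers), dtype=np.int8)
    for i in range(targets.n_samples):
        h1, h2 = phase_target_naive(geno[i], panel, params)
        haps[2 * i] = h1
        haps[2 * i + 1] = h2
    return haps
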