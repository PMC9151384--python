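"""Synthetic phased panels and target cohorts with CNV pseudo-alleles on tag haplotypes.

No individual-level data from the cohorts this method was developed on is
distributable, so every downstream stage is exercised against simulated
data shaped like them: a reference panel of ~900 diploids (1804 phased
haplotypes) over a few thousand markers around the CYP2D6 locus, with a
whole-gene deletion allele at haplotype frequency ~1.35% and a duplication
allele at ~4.4% — giving diploid carrier fractions near 2.7% and 8.5% — and
a larger chip-genotyped target cohort whose CNV status is masked.

Haplotypes are mosaics of a founder pool (copying with per-interval switch
probability), which produces block-like linkage disequilibrium.  The DEL
and DUP pseudo-alleles are planted preferentially on haplotypes sharing a
local core haplotype and then a tag site is repaired so the realized
maximum r² with each CNV allele reaches a requested floor — the
co-occurrence of CNVs with nearby SNPs that makes them imputable at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from starimpute.hmm import HaplotypePanel
from starimpute.panel import (
    PSEUDO_CHROM,
    PSEUDO_DEL_ID,
    PSEUDO_DEL_POS,
    PSEUDO_DUP_ID,
    PSEUDO_DUP_POS,
    make_marker_table,
)

LOCUS_START = 42_300_000  # GRCh37 window around CYP2D6 (22q13.2)
LOCUS_END = 42_740_000
CORE_WINDOW = 10  # sites in the core haplotype used for CNV placement


@dataclass
class SimConfig:
    """Study-scale simulation parameters.

    Defaults describe the emulated study: 902 reference diploids (1804
    haplotypes), desk-scale 2000 markers, DEL/DUP haplotype frequencies
    0.0135/0.044 so diploid carrier fractions track ≈2.7% and ≈8.5%.
    """

    n_panel_haplotypes: int = 1804
    n_target_samples: int = 100
    n_sites: int = 2000
    founder_count: int = 40
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    switch_rate: float = 0.01
    del_hap_freq: float = 0.0135
    dup_hap_freq: float = 0.044
    tag_strength: float = 1.0
    genotype_error: float = 0.002
    seed: int = 0
    copy_targets_verbatim: bool = False

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("need at least 3 sites")
        if self.del_hap_freq + self.dup_hap_freq >= 1:
            raise ValueError("DEL + DUP haplotype frequencies must sum below 1")
        for name in ("switch_rate", "del_hap_freq", "dup_hap_freq",
                     "tag_strength", "genotype_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must satisfy 0 < lo <= hi < 1")


@dataclass
class TruthSet:
    """Ground truth emitted alongside simulated data.

    ``hap_cnv`` holds one of ``NONE | DEL | DUP`` per panel haplotype;
    ``sample_cn`` the true diploid copy number per target sample
    (always 2 − #DEL + #DUP); ``site_r2`` the realized squared allelic
    correlation between every SNP site and each CNV allele, recomputed from
    the emitted haplotype matrix.
    """

    hap_cnv: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    sample_cn: pd.DataFrame | None = None
    site_r2: pd.DataFrame | None = None


def generate_founder_haplotypes(
    n_founders: int, n_sites: int, freq_range: tuple[float, float], seed: int
) -> np.ndarray:
    """Binary founder haplotypes with per-site allele frequency drawn uniformly."""
    if n_founders < 2 or n_sites < 1:
        raise ValueError("need n_founders >= 2 and n_sites >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = freq_range
    freqs = rng.uniform(lo, hi, size=n_sites)
    return (rng.random((n_founders, n_sites)) < freqs).astype(np.int8)


def recombine_panel(
    founders: np.ndarray, n_out: int, switch_rate: float, seed: int
) -> np.ndarray:
    """Mosaic haplotypes copied from founders with per-interval resampling.

    At each inter-site interval the copied founder is resampled (uniformly,
    possibly to itself) with probability ``switch_rate``; switch_rate=0
    reproduces founders verbatim, switch_rate=1 copies independently per
    site.
    """
    founders = np.asarray(founders)
    if founders.size == 0:
        raise ValueError("founder set is empty")
    if not 0.0 <= switch_rate <= 1.0:
        raise ValueError("switch_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_f, n_sites = founders.shape
    source = np.empty((n_out, n_sites), dtype=np.int64)
    source[:, 0] = rng.integers(0, n_f, size=n_out)
    switch = rng.random((n_out, n_sites - 1)) < switch_rate
    resample = rng.integers(0, n_f, size=(n_out, n_sites - 1))
    for m in range(1, n_sites):
        source[:, m] = np.where(switch[:, m - 1], resample[:, m - 1], source[:, m - 1])
    return founders[source, np.arange(n_sites)[None, :]].astype(np.int8)


def haplotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared allelic correlation between two binary haplotype columns."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return 0.0
    c = ((x - x.mean()) * (y - y.mean())).mean()
    return float(c * c / (vx * vy))


def _tag_r2_after(carriers: np.ndarray, tag: np.ndarray) -> float:
    return haplotype_r2(tag, carriers.astype(float))


def _build_tag_column(
    carriers: np.ndarray, original: np.ndarray, tag_strength: float
) -> np.ndarray:
    """Repair one site so its r² with the carrier indicator is >= tag_strength.

    Carriers are set to allele 1; non-carrier alleles keep their original
    value, then the number of non-carrier 1s is reduced (in index order)
    until the floor is met.  With tag_strength=1 all non-carrier 1s are
    cleared, giving r²=1 exactly.
    """
    tag = original.copy()
    tag[carriers] = 1
    if _tag_r2_after(carriers, tag) >= tag_strength:
        return tag
    noncarrier_ones = np.flatnonzero(~carriers & (tag == 1))
    for idx in noncarrier_ones:
        tag[idx] = 0
        if _tag_r2_after(carriers, tag) >= tag_strength:
            return tag
    return tag  # all cleared: r² = 1 >= any feasible tag_strength


def _place_carriers(
    panel: np.ndarray,
    n_carriers: int,
    window: slice,
    blocked: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pick carrier haplotypes sharing a core haplotype in ``window``.

    Seeds from a random unblocked haplotype's core pattern and greedily
    takes the haplotypes with smallest Hamming distance to it.
    """
    candidates = np.flatnonzero(~blocked)
    seedhap = rng.choice(candidates)
    core = panel[seedhap, window]
    dist = np.abs(panel[:, window] - core[None, :]).sum(axis=1).astype(float)
    dist[blocked] = np.inf
    dist += rng.random(dist.size) * 1e-3  # random tie-break, deterministic by seed
    order = np.argsort(dist)
    carriers = np.zeros(panel.shape[0], dtype=bool)
    carriers[order[:n_carriers]] = True
    return carriers


def plant_cnv(
    panel: np.ndarray,
    del_hap_freq: float,
    dup_hap_freq: float,
    tag_strength: float,
    seed: int,
    positions: np.ndarray | None = None,
) -> tuple[HaplotypePanel, TruthSet]:
    """Append DEL/DUP pseudo-marker columns on tagged haplotype backgrounds.

    Each CNV allele is assigned to the requested number of haplotypes that
    share a core haplotype in a window adjacent to the pseudo-marker
    coordinates, then one window site per allele is repaired so the realized
    max per-site r² with the CNV allele reaches ``tag_strength``.  No
    haplotype carries both alleles.  Raises when a requested nonzero
    frequency yields an expected carrier count below one.
    """
    panel = np.asarray(panel).copy()
    K, n_snp = panel.shape
    rng = np.random.default_rng(seed)
    n_del = int(round(del_hap_freq * K))
    n_dup = int(round(dup_hap_freq * K))
    for name, freq, n in (("DEL", del_hap_freq, n_del), ("DUP", dup_hap_freq, n_dup)):
        if freq > 0 and n < 1:
            raise ValueError(
                f"{name} haplotype frequency {freq} infeasible for {K} haplotypes "
                "(expected carrier count < 1)"
            )
    if not 0.0 <= tag_strength <= 1.0:
        raise ValueError("tag_strength must lie in [0, 1]")

    if positions is None:
        snp_pos = np.linspace(LOCUS_START, LOCUS_END, n_snp).astype(np.int64)
        snp_pos = np.unique(snp_pos)
        assert snp_pos.size == n_snp, "marker grid too dense for locus window"
    else:
        snp_pos = np.asarray(positions, dtype=np.int64)

    # windows flanking the pseudo-marker insertion point
    insert_at = int(np.searchsorted(snp_pos, PSEUDO_DEL_POS))
    w = CORE_WINDOW
    dup_window = slice(max(0, insert_at - w), insert_at)
    del_window = slice(insert_at, min(n_snp, insert_at + w))

    hap_cnv = np.array(["NONE"] * K, dtype=object)
    dup_carriers = np.zeros(K, dtype=bool)
    del_carriers = np.zeros(K, dtype=bool)
    if n_dup > 0:
        dup_carriers = _place_carriers(panel, n_dup, dup_window, np.zeros(K, bool), rng)
        hap_cnv[dup_carriers] = "DUP"
        tag_site = dup_window.stop - 1
        panel[:, tag_site] = _build_tag_column(
            dup_carriers, panel[:, tag_site], tag_strength
        )
    if n_del > 0:
        del_carriers = _place_carriers(panel, n_del, del_window, dup_carriers, rng)
        hap_cnv[del_carriers] = "DEL"
        tag_site = del_window.start
        panel[:, tag_site] = _build_tag_column(
            del_carriers, panel[:, tag_site], tag_strength
        )
    assert not np.any(dup_carriers & del_carriers)

    ids = [f"rs_sim{i}" for i in range(n_snp)]
    markers = make_marker_table(
        ids, [PSEUDO_CHROM] * n_snp, snp_pos, ["A"] * n_snp, ["G"] * n_snp
    )
    pseudo = make_marker_table(
        [PSEUDO_DEL_ID, PSEUDO_DUP_ID],
        [PSEUDO_CHROM, PSEUDO_CHROM],
        [PSEUDO_DEL_POS, PSEUDO_DUP_POS],
        ["A", "A"],
        ["<DEL_PSEUDO>", "<DUP_PSEUDO>"],
        [True, True],
    )
    markers = pd.concat([markers, pseudo], ignore_index=True)
    order = np.argsort(markers["pos"].to_numpy(), kind="stable")
    markers = markers.iloc[order].reset_index(drop=True)
    haps = np.column_stack(
        [panel, del_carriers.astype(np.int8), dup_carriers.astype(np.int8)]
    )[:, order]
    out_panel = HaplotypePanel(haps.astype(np.int8), markers)

    # realized r² recomputed from the emitted matrix, SNP sites only
    snp_cols = np.flatnonzero(~markers["is_pseudo"].to_numpy(bool))
    r2_rows = []
    for label, carriers in (("DEL", del_carriers), ("DUP", dup_carriers)):
        if carriers.any():
            r2 = [haplotype_r2(haps[:, c], carriers.astype(float)) for c in snp_cols]
        else:
            r2 = [0.0] * snp_cols.size
        r2_rows.append(pd.Series(r2, index=markers["id"].iloc[snp_cols], name=label))
    site_r2 = pd.DataFrame(r2_rows).T
    for label, carriers, freq in (
        ("DEL", del_carriers, del_hap_freq),
        ("DUP", dup_carriers, dup_hap_freq),
    ):
        if carriers.any() and site_r2[label].max() < tag_strength - 1e-9:
            raise ValueError(
                f"tag_strength {tag_strength} unattainable for {label} at "
                f"haplotype frequency {freq}"
            )
    return out_panel, TruthSet(hap_cnv=hap_cnv, site_r2=site_r2)


def sample_cohort(
    panel: HaplotypePanel,
    n_target: int,
    genotype_error: float,
    seed: int,
    switch_rate: float = 0.01,
    copy_verbatim: bool = False,
) -> tuple[np.ndarray, np.ndarray, TruthSet]:
    """Draw diploid targets from the panel-generating process and mask CNV sites.

    Each target is two haplotypes produced by the same mosaic-copying
    process over the panel haplotypes (or copied verbatim when
    ``copy_verbatim``).  SNP alleles are flipped at rate ``genotype_error``;
    the pseudo-marker columns are recorded in the truth and removed from the
    emitted haplotypes.

    Returns ``(emitted_haplotypes (2n × M_snp), true_haplotypes, truth)``.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if not 0.0 <= genotype_error <= 1.0:
        raise ValueError("genotype_error must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_haps = 2 * n_target
    if copy_verbatim:
        idx = rng.integers(0, panel.n_haplotypes, size=n_haps)
        true_haps = panel.haplotypes[idx].copy()
    else:
        true_haps = recombine_panel(
            panel.haplotypes, n_haps, switch_rate, int(rng.integers(0, 2**31))
        )

    pseudo_mask = panel.markers["is_pseudo"].to_numpy(bool)
    del_col = panel.marker_index(PSEUDO_DEL_ID)
    dup_col = panel.marker_index(PSEUDO_DUP_ID)
    del_alleles = true_haps[:, del_col].reshape(n_target, 2).sum(axis=1)
    dup_alleles = true_haps[:, dup_col].reshape(n_target, 2).sum(axis=1)
    true_cn = 2 - del_alleles + dup_alleles

    emitted = true_haps[:, ~pseudo_mask].copy()
    if genotype_error > 0:
        flips = rng.random(emitted.shape) < genotype_error
        emitted = np.where(flips, 1 - emitted, emitted).astype(np.int8)

    truth = TruthSet(
        hap_cnv=np.where(
            true_haps[:, del_col] == 1,
            "DEL",
            np.where(true_haps[:, dup_col] == 1, "DUP", "NONE"),
        ).astype(object),
        sample_cn=pd.DataFrame(
            {
                "sample_id": [f"T{i:05d}" for i in range(n_target)],
                "true_cn": true_cn.astype(int),
                "del_alleles": del_alleles.astype(int),
                "dup_alleles": dup_alleles.astype(int),
            }
        ),
    )
    return emitted.astype(np.int8), true_haps, truth


@dataclass
class SimulatedStudy:
    """Bundle returned by :func:`simulate_study`."""

    config: SimConfig
    panel: HaplotypePanel
    panel_truth: TruthSet
    target_haps: np.ndarray  # 2n x M_snp emitted (with genotype error)
    target_true_haps: np.ndarray  # 2n x M including pseudo columns
    target_truth: TruthSet
    target_samples: list[str]
    target_markers: pd.DataFrame


def simulate_study(config: SimConfig | None = None, **overrides) -> SimulatedStudy:
    """Run the full generator: founders → panel mosaic → CNV planting → cohort."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig(**{**config.__dict__, **overrides})
    rng = np.random.default_rng(config.seed)
    s1, s2, s3, s4 = rng.integers(0, 2**31, size=4)
    founders = generate_founder_haplotypes(
        config.founder_count, config.n_sites, config.allele_freq_range, int(s1)
    )
    raw_panel = recombine_panel(
        founders, config.n_panel_haplotypes, config.switch_rate, int(s2)
    )
    panel, panel_truth = plant_cnv(
        raw_panel,
        config.del_hap_freq,
        config.dup_hap_freq,
        config.tag_strength,
        int(s3),
    )
    emitted, true_haps, target_truth = sample_cohort(
        panel,
        config.n_target_samples,
        config.genotype_error,
        int(s4),
        switch_rate=config.switch_rate,
        copy_verbatim=config.copy_targets_verbatim,
    )
    pseudo_mask = panel.markers["is_pseudo"].to_numpy(bool)
    return SimulatedStudy(
        config=config,
        panel=panel,
        panel_truth=panel_truth,
        target_haps=emitted,
        target_true_haps=true_haps,
        target_truth=target_truth,
        target_samples=list(target_truth.sample_cn["sample_id"]),
        target_markers=panel.markers.loc[~pseudo_mask].reset_index(drop=True),
    )
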