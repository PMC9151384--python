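"""Reference-panel construction: genotype QC and copy-number pseudo-markers.

Whole-gene CYP2D6 deletions and duplications measured by real-time PCR are
integer copy numbers per sample (0–4).  To make them imputable with ordinary
haplotype machinery they are re-encoded as two biallelic *pseudo-markers*:

* ``CYP2D6_DEL`` — allele count ``max(0, 2 - CN)``
* ``CYP2D6_DUP`` — allele count ``max(0, CN - 2)``

so CN=2 is the double-reference state, a hemizygous deletion is one DEL
allele, a single duplication one DUP allele, and no haplotype ever carries
both.  The pseudo-markers are merged into a QC-filtered chip-genotype panel
at fixed GRCh37 coordinates inside CYP2D6, after which the merged panel can
be phased and used as an imputation reference like any SNP panel.

QC follows the usual chip pipeline: marker missingness, sample missingness,
minor-allele frequency, an exact Hardy–Weinberg test, heterozygosity
outliers (mean ± k·SD) and relatedness pruning on method-of-moments
pi-hat.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

# Reserved pseudo-marker identity: GRCh37 coordinates inside CYP2D6,
# chosen not to collide with real chip markers.
PSEUDO_DEL_ID = "CYP2D6_DEL"
PSEUDO_DUP_ID = "CYP2D6_DUP"
PSEUDO_CHROM = "22"
PSEUDO_DEL_POS = 42522500
PSEUDO_DUP_POS = 42522501

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "is_pseudo"]


def make_marker_table(
    ids, chroms, positions, refs, alts, is_pseudo=None
) -> pd.DataFrame:
    """Assemble a marker metadata table (one row per marker, position-sorted input expected)."""
    n = len(ids)
    if is_pseudo is None:
        is_pseudo = [False] * n
    df = pd.DataFrame(
        {
            "id": list(ids),
            "chrom": list(chroms),
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": list(refs),
            "alt": list(alts),
            "is_pseudo": list(is_pseudo),
        }
    )
    if (df["pos"] <= 0).any():
        raise ValueError("marker positions must be positive (1-based)")
    return df


@dataclass
class GenotypeMatrix:
    """Samples × markers alternate-allele counts (0/1/2, ``nan`` = missing).

    ``markers`` is a DataFrame with columns ``id, chrom, pos, ref, alt,
    is_pseudo``; rows align with the columns of ``geno``.
    """

    samples: list[str]
    markers: pd.DataFrame
    geno: np.ndarray  # float array, n_samples x n_markers, nan = missing

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=float)
        if self.geno.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.geno.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.geno), axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.geno), axis=1)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.geno, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = np.nanmean(self.geno, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def heterozygosity(self) -> np.ndarray:
        """Fraction of non-missing genotypes that are heterozygous, per sample."""
        het = self.geno == 1
        called = ~np.isnan(self.geno)
        with np.errstate(invalid="ignore"):
            return het.sum(axis=1) / called.sum(axis=1)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        g = self
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            g = GenotypeMatrix(
                g.samples,
                g.markers.iloc[marker_idx].reset_index(drop=True),
                g.geno[:, marker_idx],
            )
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            g = GenotypeMatrix(
                [g.samples[i] for i in sample_idx],
                g.markers,
                g.geno[sample_idx, :],
            )
        return g


@dataclass
class CopyNumberCall:
    """Integer CYP2D6 copy number for one sample.

    ``source`` records provenance (``"PCR"`` for direct real-time PCR
    measurement, ``"imputed"`` for model output).  ``posterior`` maps CN
    class -> probability; PCR calls carry a degenerate posterior.
    ``expected_cn`` is the dosage-scale estimate when imputed.
    """

    sample_id: str
    cn: int
    source: str = "PCR"
    posterior: dict[int, float] | None = None
    expected_cn: float | None = None

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValueError(f"copy number must be >= 0, got {self.cn}")
        if self.source not in ("PCR", "imputed"):
            raise ValueError(f"unknown call source {self.source!r}")
        if self.posterior is None and self.source == "PCR":
            self.posterior = {self.cn: 1.0}
        if self.posterior is not None:
            total = sum(self.posterior.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"posterior sums to {total}, expected 1")


@dataclass
class QCReport:
    """Per-step exclusion bookkeeping for :func:`qc_filter`.

    Conservation holds per axis: markers excluded across steps plus markers
    retained equals markers in; likewise for samples.
    """

    thresholds: dict = field(default_factory=dict)
    n_markers_in: int = 0
    n_samples_in: int = 0
    excluded_markers: dict[str, int] = field(default_factory=dict)
    excluded_samples: dict[str, int] = field(default_factory=dict)
    n_markers_out: int = 0
    n_samples_out: int = 0
    relatedness_pihat: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["relatedness_pihat"] = {
            f"{a}|{b}": v for (a, b), v in self.relatedness_pihat.items()
        }
        return d


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact conditional Hardy–Weinberg test, two-sided.

    Conditions on the observed minor-allele count and sums the probabilities
    of every heterozygote count whose conditional probability does not
    exceed that of the observed configuration (probability-mass ordering,
    the convention of the standard exact HWE test).

    Returns 1.0 for monomorphic input.
    """
    for v in (n_hom_minor, n_het, n_hom_major):
        if v < 0 or v != int(v):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        raise ValueError("at least one genotyped sample required")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:  # symmetric; condition on the rarer allele
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        return 1.0

    # log P(n_het | n, n_minor) for every feasible het count of same parity
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hets = hets[(n_minor - hets) % 2 == 0]
    hets = hets[(n_minor - hets) // 2 + hets <= n]  # feasibility (always true here)
    n_aa = (n_minor - hets) // 2
    n_bb = n - n_aa - hets
    valid = n_bb >= 0
    hets, n_aa, n_bb = hets[valid], n_aa[valid], n_bb[valid]
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(hets + 1)
        - gammaln(n_bb + 1)
        + hets * math.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-12)].sum()))


DEFAULT_QC_THRESHOLDS = {
    "marker_missingness": 0.03,
    "sample_missingness": 0.03,
    "maf": 0.005,
    "hwe_p": 1e-6,
    "het_sd": 3.0,
}


def _hwe_p_per_marker(g: GenotypeMatrix) -> np.ndarray:
    out = np.ones(g.n_markers)
    for j in range(g.n_markers):
        col = g.geno[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        n_alt_hom = int((col == 2).sum())
        n_het = int((col == 1).sum())
        n_ref_hom = int((col == 0).sum())
        out[j] = hwe_exact_test(n_alt_hom, n_het, n_ref_hom)
    return out


def qc_filter(
    g: GenotypeMatrix, thresholds: dict | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply chip QC filters in fixed order.

    Order: marker missingness → sample missingness → MAF → exact HWE →
    heterozygosity outliers (mean ± k·SD over samples surviving earlier
    steps).  Raises if any step empties the matrix, naming the step.
    """
    th = dict(DEFAULT_QC_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    report = QCReport(
        thresholds=dict(th), n_markers_in=g.n_markers, n_samples_in=g.n_samples
    )

    def _check(gm: GenotypeMatrix, step: str) -> None:
        if gm.n_markers == 0 or gm.n_samples == 0:
            raise ValueError(f"QC step {step!r} removed all remaining data")

    keep = g.marker_missingness() <= th["marker_missingness"]
    report.excluded_markers["marker_missingness"] = int((~keep).sum())
    g = g.subset(marker_idx=np.flatnonzero(keep))
    _check(g, "marker_missingness")

    keep = g.sample_missingness() <= th["sample_missingness"]
    report.excluded_samples["sample_missingness"] = int((~keep).sum())
    g = g.subset(sample_idx=np.flatnonzero(keep))
    _check(g, "sample_missingness")

    keep = g.maf() >= th["maf"]
    report.excluded_markers["maf"] = int((~keep).sum())
    g = g.subset(marker_idx=np.flatnonzero(keep))
    _check(g, "maf")

    keep = _hwe_p_per_marker(g) >= th["hwe_p"]
    report.excluded_markers["hwe"] = int((~keep).sum())
    g = g.subset(marker_idx=np.flatnonzero(keep))
    _check(g, "hwe")

    het = g.heterozygosity()
    mu, sd = float(np.mean(het)), float(np.std(het))
    if sd > 0:
        keep = np.abs(het - mu) <= th["het_sd"] * sd
    else:
        keep = np.ones(g.n_samples, dtype=bool)
    report.excluded_samples["heterozygosity"] = int((~keep).sum())
    g = g.subset(sample_idx=np.flatnonzero(keep))
    _check(g, "heterozygosity")

    report.n_markers_out = g.n_markers
    report.n_samples_out = g.n_samples
    return g, report


MIN_RELATEDNESS_MARKERS = 50


def estimate_relatedness(
    g: GenotypeMatrix, cutoff: float = 0.15
) -> tuple[list[str], dict[tuple[str, str], float]]:
    """Method-of-moments IBD sharing (pi-hat) and relatedness pruning.

    For each sample pair, observed identity-by-state counts are converted to
    IBD-state probabilities using panel allele frequencies (the classic
    moments estimator), and ``pi_hat = P(IBD=1)/2 + P(IBD=2)``.  For each
    pair above ``cutoff`` the member with higher genotype missingness is
    excluded (tie → the later sample index).

    Returns (excluded sample ids, pi-hat per flagged pair).
    """
    if g.n_samples < 2:
        raise ValueError("relatedness estimation needs at least two samples")
    freq = np.nanmean(g.geno, axis=0) / 2.0
    informative = (
        (freq > 0) & (freq < 1) & (g.marker_missingness() < 1.0)
    )
    if informative.sum() < MIN_RELATEDNESS_MARKERS:
        raise ValueError(
            f"only {int(informative.sum())} informative markers; at least "
            f"{MIN_RELATEDNESS_MARKERS} are needed — supply more markers"
        )
    sub = g.subset(marker_idx=np.flatnonzero(informative))
    p = np.nanmean(sub.geno, axis=0) / 2.0
    q = 1.0 - p

    # per-marker P(IBS=s | IBD=k) with the finite-sample (sampling without
    # replacement) corrections of the classic chip-data moments estimator;
    # X/Y are observed allele counts, N the total allele count per marker
    called = (~np.isnan(sub.geno)).sum(axis=0)
    N = 2.0 * called
    X = p * N
    Y = q * N
    c3 = (N / (N - 1)) * (N / (N - 2)) * (N / (N - 3))
    c2 = (N / (N - 1)) * (N / (N - 2))
    e_ibs0_ibd0 = 2.0 * p**2 * q**2 * ((X - 1) / X) * ((Y - 1) / Y) * c3
    e_ibs1_ibd0 = (
        4.0 * p**3 * q * ((X - 1) / X) * ((X - 2) / X)
        + 4.0 * p * q**3 * ((Y - 1) / Y) * ((Y - 2) / Y)
    ) * c3
    e_ibs1_ibd1 = (
        2.0 * p**2 * q * ((X - 1) / X) + 2.0 * p * q**2 * ((Y - 1) / Y)
    ) * c2

    miss = sub.sample_missingness()
    flagged: dict[tuple[str, str], float] = {}
    excluded: set[int] = set()
    geno = sub.geno
    for i, j in itertools.combinations(range(sub.n_samples), 2):
        gi, gj = geno[i], geno[j]
        ok = ~np.isnan(gi) & ~np.isnan(gj)
        if ok.sum() < MIN_RELATEDNESS_MARKERS:
            continue
        diff = np.abs(gi[ok] - gj[ok])
        n0 = float((diff == 2).sum())
        n1 = float((diff == 1).sum())
        s0 = e_ibs0_ibd0[ok].sum()
        s1_0 = e_ibs1_ibd0[ok].sum()
        s1_1 = e_ibs1_ibd1[ok].sum()
        p0 = n0 / s0 if s0 > 0 else 0.0
        p1 = (n1 - p0 * s1_0) / s1_1 if s1_1 > 0 else 0.0
        # raw moments estimate: pi-hat = P(IBD=1)/2 + P(IBD=2) with
        # P(IBD=2) = 1 - P0 - P1.  Left unclamped below zero so that the
        # estimator stays unbiased for unrelated pairs (small negative
        # values are sampling noise); capped at 1.
        pihat = min(1.0 - p0 - p1 / 2.0, 1.0)
        if pihat > cutoff:
            flagged[(sub.samples[i], sub.samples[j])] = pihat
            drop = j if (miss[j] > miss[i] or math.isclose(miss[i], miss[j])) else i
            excluded.add(drop)
    return [sub.samples[i] for i in sorted(excluded)], flagged


MAX_ENCODABLE_CN = 4


def encode_copy_number(calls: list[CopyNumberCall]) -> pd.DataFrame:
    """Encode integer copy numbers as DEL/DUP pseudo-marker allele counts.

    CN=2 maps to (0, 0); each missing copy is one DEL allele, each extra
    copy one DUP allele.  CN above 4 is not representable as a biallelic
    dosage and raises.
    """
    rows = []
    for c in calls:
        if c.cn > MAX_ENCODABLE_CN:
            raise ValueError(
                f"sample {c.sample_id}: CN={c.cn} exceeds the biallelic "
                f"pseudo-marker range (max {MAX_ENCODABLE_CN})"
            )
        rows.append(
            {
                "sample_id": c.sample_id,
                "del_count": max(0, 2 - c.cn),
                "dup_count": max(0, c.cn - 2),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "del_count", "dup_count"])


def decode_copy_number(
    del_dosage: float,
    dup_dosage: float,
    sample_id: str = "",
    posterior: dict[int, float] | None = None,
) -> CopyNumberCall:
    """Decode DEL/DUP dosages back to a copy-number call.

    Expected CN = 2 − del_dosage + dup_dosage; the best-guess class is the
    nearest integer, with exact half-way ties resolved toward the reference
    state CN=2 (prior mass on the unrearranged gene).
    """
    for name, d in (("del", del_dosage), ("dup", dup_dosage)):
        if not 0.0 <= d <= 2.0:
            raise ValueError(f"{name} dosage {d} outside [0, 2]")
    expected = 2.0 - del_dosage + dup_dosage
    lo = math.floor(expected)
    frac = expected - lo
    if math.isclose(frac, 0.5, abs_tol=1e-12):
        best = lo if abs(lo - 2) <= abs(lo + 1 - 2) else lo + 1
    else:
        best = int(round(expected))
    best = max(best, 0)
    return CopyNumberCall(
        sample_id=sample_id,
        cn=best,
        source="imputed",
        posterior=posterior if posterior is not None else {best: 1.0},
        expected_cn=expected,
    )


def merge_pseudo_markers(
    panel: GenotypeMatrix,
    pseudo: pd.DataFrame,
    chrom: str = PSEUDO_CHROM,
    del_pos: int = PSEUDO_DEL_POS,
    dup_pos: int = PSEUDO_DUP_POS,
) -> GenotypeMatrix:
    """Insert the encoded DEL/DUP pseudo-markers into a genotype panel.

    ``pseudo`` is the output of :func:`encode_copy_number`.  The sample sets
    must match exactly; the two new markers are inserted in position order
    and must not collide with existing coordinates.
    """
    pseudo = pseudo.set_index("sample_id")
    panel_set, pseudo_set = set(panel.samples), set(pseudo.index)
    if panel_set != pseudo_set:
        only_panel = sorted(panel_set - pseudo_set)
        only_pseudo = sorted(pseudo_set - panel_set)
        raise ValueError(
            "sample sets differ between panel and copy-number calls: "
            f"panel-only={only_panel[:5]} cnv-only={only_pseudo[:5]}"
        )
    same_chrom = panel.markers["chrom"].astype(str) == str(chrom)
    for pos in (del_pos, dup_pos):
        if ((panel.markers["pos"] == pos) & same_chrom).any():
            raise ValueError(f"pseudo-marker position {chrom}:{pos} collides with an existing marker")

    order = pseudo.loc[panel.samples]
    new_markers = make_marker_table(
        [PSEUDO_DEL_ID, PSEUDO_DUP_ID],
        [chrom, chrom],
        [del_pos, dup_pos],
        ["A", "A"],
        ["<DEL_PSEUDO>", "<DUP_PSEUDO>"],
        [True, True],
    )
    markers = pd.concat([panel.markers, new_markers], ignore_index=True)
    geno = np.column_stack(
        [panel.geno, order["del_count"].to_numpy(float), order["dup_count"].to_numpy(float)]
    )
    sort_idx = np.lexsort((markers["pos"].to_numpy(), markers["chrom"].astype(str).to_numpy()))
    markers = markers.iloc[sort_idx].reset_index(drop=True)
    geno = geno[:, sort_idx]
    merged = GenotypeMatrix(list(panel.samples), markers, geno)
    pos_by_chrom = merged.markers.groupby("chrom", sort=False)["pos"]
    if not all(s.is_monotonic_increasing for _, s in pos_by_chrom):
        raise AssertionError("merged marker positions are not sorted")
    return merged


def remove_pseudo_markers(g: GenotypeMatrix) -> GenotypeMatrix:
    """Drop pseudo-marker columns (inverse of :func:`merge_pseudo_markers`)."""
    keep = ~g.markers["is_pseudo"].to_numpy(bool)
    return g.subset(marker_idx=np.flatnonzero(keep))
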