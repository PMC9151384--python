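"""CPIC-style star-allele calling, activity scores and metabolizer phenotypes.

Pharmacogene haplotypes are named *star alleles* (CYP2D6*4, UGT1A1*28, ...),
each defined by a set of variants; the reference allele *1 is assigned when
no defining variant is observed.  A diplotype is a pair of star alleles,
with CYP2D6 copy number folded in: a whole-gene deletion is the *5 allele
(zero copies of the named allele), a duplication multiplies one allele's
copy count.  When a duplication sits on a heterozygous diplotype the data
do not say which allele is duplicated, so the call carries an ambiguity
set and the phenotype both a pessimistic and an optimistic category.

Genes with activity-score (AS) semantics (CYP2D6, CYP2C9, DPYD) sum
per-allele activity × copy count and bin the total; the others map
diplotype function pairs straight to categories.  All alleles, activities,
functions and bins are table-driven configuration, so guideline revisions
change data, not code.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DELETION_ALLELE = "*5"
DEFAULT_ALLELE = "*1"
GENES = (
    "CYP2C9", "CYP2C19", "CYP2D6", "DPYD",
    "NUDT15", "SLCO1B1", "TPMT", "UGT1A1",
)


class AmbiguousHaplotypeError(ValueError):
    """Two maximal star-allele candidates match the same haplotype."""


def _is_deletion(gene: str, allele: str) -> bool:
    # the whole-gene deletion allele exists only for CYP2D6; SLCO1B1*5 is an
    # ordinary SNP-defined allele and must not be treated as zero copies
    return gene == "CYP2D6" and allele == DELETION_ALLELE


@dataclass
class AlleleDefinitionTable:
    """Star-allele definitions for one or more genes.

    Built from a long-format table with columns
    ``gene, star_allele, marker_id, required_allele, activity, function``;
    the default allele (*1) and the deletion allele (*5, CYP2D6 only) have
    empty defining sets and appear with ``marker_id`` blank.
    """

    defs: pd.DataFrame

    _defining: dict = field(init=False, default_factory=dict)
    _activity: dict = field(init=False, default_factory=dict)
    _function: dict = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        d = self.defs
        for (gene, allele), grp in d.groupby(["gene", "star_allele"]):
            sites = {
                row.marker_id: int(row.required_allele)
                for row in grp.itertuples()
                if isinstance(row.marker_id, str) and row.marker_id
            }
            self._defining[(gene, allele)] = sites
            act = grp["activity"].iloc[0]
            self._activity[(gene, allele)] = None if pd.isna(act) else float(act)
            self._function[(gene, allele)] = grp["function"].iloc[0]
        seen: dict[tuple, str] = {}
        for (gene, allele), sites in self._defining.items():
            if not sites:
                continue
            key = (gene, tuple(sorted(sites.items())))
            if key in seen:
                raise ValueError(
                    f"{gene}: alleles {seen[key]} and {allele} share a defining set"
                )
            seen[key] = allele

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self._defining})

    def alleles(self, gene: str) -> list[str]:
        return sorted(a for g, a in self._defining if g == gene)

    def defining_sites(self, gene: str) -> set[str]:
        return {m for (g, _), s in self._defining.items() if g == gene for m in s}

    def defining_set(self, gene: str, allele: str) -> dict[str, int]:
        return self._defining[(gene, allele)]

    def activity(self, gene: str, allele: str) -> float:
        v = self._activity.get((gene, allele))
        if v is None:
            raise ValueError(f"{gene} {allele} has no configured activity value")
        return v

    def function(self, gene: str, allele: str) -> str:
        return self._function[(gene, allele)]

    @classmethod
    def from_csv(cls, path) -> "AlleleDefinitionTable":
        df = pd.read_csv(path, comment="#", dtype={"marker_id": str})
        df["marker_id"] = df["marker_id"].fillna("")
        return cls(df)


def load_default_definitions() -> AlleleDefinitionTable:
    """Reconstructed subset of CPIC allele definitions shipped with the package."""
    ref = importlib.resources.files("starimpute.data").joinpath(
        "cpic_allele_definitions_subset.csv"
    )
    with importlib.resources.as_file(ref) as p:
        return AlleleDefinitionTable.from_csv(p)


def load_default_bins() -> dict:
    ref = importlib.resources.files("starimpute.data").joinpath("phenotype_bins.json")
    return json.loads(ref.read_text())


def match_haplotype(
    alleles_at_defining_sites: dict[str, int],
    table: AlleleDefinitionTable,
    gene: str,
) -> str:
    """Assign the most specific star allele matching one phased haplotype.

    ``alleles_at_defining_sites`` maps marker id → observed allele (0/1) on
    this haplotype; sites absent from the map are treated as unobserved and
    cannot support a match.  Among alleles whose full defining set matches,
    the one with the largest defining set wins (e.g. *4, defined by its own
    variant plus the *10 variant it carries, beats *10).  With no match the
    reference allele *1 is returned — an individual carrying none of the
    genotyped defining variants defaults to normal.
    """
    candidates = []
    for allele in table.alleles(gene):
        sites = table.defining_set(gene, allele)
        if not sites:
            continue
        if all(alleles_at_defining_sites.get(m) == req for m, req in sites.items()):
            candidates.append((len(sites), allele))
    if not candidates:
        return DEFAULT_ALLELE
    best_size = max(size for size, _ in candidates)
    best = [a for size, a in candidates if size == best_size]
    if len(best) > 1:
        raise AmbiguousHaplotypeError(
            f"{gene}: haplotype matches {sorted(best)} equally; cannot resolve"
        )
    return best[0]


@dataclass
class DiplotypeCall:
    """Star-allele pair with copy multiplicities and duplication ambiguity.

    ``branches`` lists every (allele_a, copy_a, allele_b, copy_b) assignment
    consistent with the observed haplotypes and total copy number; the
    first branch is the primary call.
    """

    gene: str
    allele_a: str
    allele_b: str
    copy_a: int
    copy_b: int
    total_cn: int
    ambiguity_set: list[tuple[str, int, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        named_copies = (
            self.copy_a * (not _is_deletion(self.gene, self.allele_a))
            + self.copy_b * (not _is_deletion(self.gene, self.allele_b))
        )
        if named_copies != self.total_cn:
            raise ValueError(
                f"copy counts {self.copy_a}+{self.copy_b} inconsistent with "
                f"total CN {self.total_cn}"
            )

    @property
    def branches(self) -> list[tuple[str, int, str, int]]:
        primary = (self.allele_a, self.copy_a, self.allele_b, self.copy_b)
        return [primary] + [b for b in self.ambiguity_set if b != primary]

    def label(self) -> str:
        def side(allele, copies):
            return f"{allele}x{copies}" if copies > 1 else allele

        return f"{side(self.allele_a, self.copy_a)}/{side(self.allele_b, self.copy_b)}"


def call_diplotype(
    hap_pair: tuple[str, str], cn: int, gene: str = "CYP2D6"
) -> DiplotypeCall:
    """Fold total copy number into a pair of observed star alleles.

    cn=2 keeps the pair; cn=1 is a hemizygote (other allele *5); cn=0 is
    *5/*5; cn=3 with distinct alleles is ambiguous over which allele is
    duplicated; cn=4 enumerates the 3+1 and 2+2 splits.
    """
    a, b = hap_pair
    if cn < 0:
        raise ValueError("copy number must be >= 0")
    if cn == 0:
        return DiplotypeCall(gene, DELETION_ALLELE, DELETION_ALLELE, 1, 1, 0)
    if cn == 1:
        observed = {x for x in (a, b) if x != DELETION_ALLELE}
        if len(observed) > 1:
            raise ValueError(
                f"hemizygote (CN=1) cannot carry two distinct alleles {sorted(observed)}"
            )
        allele = observed.pop() if observed else DEFAULT_ALLELE
        call = DiplotypeCall(gene, allele, DELETION_ALLELE, 1, 1, 1)
        return call
    if cn == 2:
        return DiplotypeCall(gene, a, b, 1, 1, 2)
    if cn == 3:
        if a == b:
            return DiplotypeCall(gene, a, b, 2, 1, 3)
        return DiplotypeCall(
            gene, a, b, 2, 1, 3, ambiguity_set=[(a, 1, b, 2)]
        )
    if cn == 4:
        if a == b:
            return DiplotypeCall(gene, a, b, 2, 2, 4)
        return DiplotypeCall(
            gene, a, b, 2, 2, 4,
            ambiguity_set=[(a, 3, b, 1), (a, 1, b, 3)],
        )
    raise ValueError(f"copy number {cn} not supported (max 4)")


def activity_score(
    call: DiplotypeCall, table: AlleleDefinitionTable
) -> list[float]:
    """Activity score per ambiguity branch: Σ allele activity × copy count.

    The deletion allele *5 contributes 0.  Only meaningful for genes with
    AS semantics (CYP2D6, CYP2C9, DPYD).
    """
    scores = []
    for a, ca, b, cb in call.branches:
        total = 0.0
        for allele, copies in ((a, ca), (b, cb)):
            if _is_deletion(call.gene, allele):
                continue
            total += table.activity(call.gene, allele) * copies
        scores.append(total)
    return scores


@dataclass
class PhenotypePrediction:
    """Metabolizer phenotype with pessimistic/optimistic range over branches."""

    gene: str
    diplotype: str
    category: str
    pessimistic_category: str
    optimistic_category: str
    activity_scores: list[float] | None = None


def _bin_activity(score: float, bins: list[dict], gene: str) -> str:
    for b in bins:
        lo, hi = b["min"], b["max"]
        lo_ok = score > lo if b.get("min_open") else score >= lo
        hi_ok = score < hi if b.get("max_open") else score <= hi
        if lo_ok and hi_ok:
            return b["category"]
    raise ValueError(f"{gene}: activity score {score} outside configured bins")


def _category_for_branch(
    gene: str,
    branch: tuple[str, int, str, int],
    table: AlleleDefinitionTable,
    gene_bins: dict,
) -> tuple[str, float | None]:
    a, ca, b, cb = branch
    if gene_bins["type"] == "activity_score":
        score = 0.0
        for allele, copies in ((a, ca), (b, cb)):
            if not _is_deletion(gene, allele):
                score += table.activity(gene, allele) * copies
        return _bin_activity(score, gene_bins["bins"], gene), score
    # function-pair lookup; copy count beyond 1 upgrades via the
    # "duplicated" function map when configured
    funcs = []
    for allele, copies in ((a, ca), (b, cb)):
        f = table.function(gene, allele)
        if copies > 1 and "duplicated_function" in gene_bins:
            f = gene_bins["duplicated_function"].get(f, f)
        funcs.append(f)
    key = "|".join(sorted(funcs))
    pairs = gene_bins["pairs"]
    if key not in pairs:
        raise ValueError(f"{gene}: no category configured for function pair {key!r}")
    return pairs[key], None


def predict_phenotype(
    call: DiplotypeCall,
    table: AlleleDefinitionTable,
    bins: dict | None = None,
) -> PhenotypePrediction:
    """Category per ambiguity branch, plus the pessimistic/optimistic pair.

    The pessimistic category is the branch lowest on the gene's ordered
    category scale (worst metabolic capacity relative to normal as ordered
    in the bin config), the optimistic the highest.
    """
    if bins is None:
        bins = load_default_bins()
    gene_bins = bins.get(call.gene)
    if gene_bins is None:
        raise ValueError(f"no phenotype bins configured for gene {call.gene}")
    order = gene_bins["order"]  # worst → best
    results = [
        _category_for_branch(call.gene, br, table, gene_bins) for br in call.branches
    ]
    cats = [c for c, _ in results]
    scores = [s for _, s in results]
    ranked = sorted(cats, key=order.index)
    return PhenotypePrediction(
        gene=call.gene,
        diplotype=call.label(),
        category=cats[0],
        pessimistic_category=ranked[0],
        optimistic_category=ranked[-1],
        activity_scores=None if scores[0] is None else scores,
    )


def summarize_phenotypes(predictions: list[PhenotypePrediction]) -> pd.DataFrame:
    """Prevalence table: per gene and category, count and percentage.

    Percentages are of non-missing calls per gene and sum to 100 up to
    rounding; uses the primary (pessimistic-first) category of each call.
    """
    if not predictions:
        raise ValueError("empty prediction list")
    df = pd.DataFrame(
        [
            {"gene": p.gene, "category": p.pessimistic_category}
            for p in predictions
        ]
    )
    rows = []
    for gene, grp in df.groupby("gene"):
        denom = len(grp)
        for cat, n in grp["category"].value_counts().items():
            rows.append(
                {
                    "gene": gene,
                    "category": cat,
                    "n": int(n),
                    "denominator": denom,
                    "pct": 100.0 * n / denom,
                }
            )
    return pd.DataFrame(rows).sort_values(["gene", "category"]).reset_index(drop=True)


def summarize_counts(counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Prevalence table straight from per-gene category counts."""
    rows = []
    for gene, cats in counts.items():
        denom = sum(cats.values())
        for cat, n in cats.items():
            rows.append(
                {
                    "gene": gene,
                    "category": cat,
                    "n": int(n),
                    "denominator": denom,
                    "pct": 100.0 * n / denom,
                }
            )
    return pd.DataFrame(rows)


def call_sample(
    gene: str,
    hap_alleles: tuple[dict[str, int], dict[str, int]],
    cn: int | None,
    table: AlleleDefinitionTable,
    bins: dict | None = None,
) -> PhenotypePrediction:
    """End-to-end call for one sample and gene from phased defining-site alleles."""
    star_a = match_haplotype(hap_alleles[0], table, gene)
    star_b = match_haplotype(hap_alleles[1], table, gene)
    dip = call_diplotype((star_a, star_b), 2 if cn is None else cn, gene=gene)
    return predict_phenotype(dip, table, bins)
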