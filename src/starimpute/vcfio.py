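"""File formats: VCF 4.2 and PLINK text PED/MAP readers/writers, CN tables.

VCF is the canonical interchange format (1-based coordinates throughout);
reading goes through cyvcf2, writing emits minimal VCF 4.2 text.  PED/MAP
is supported for fidelity to the chip-genotyping workflow the panel comes
from; PED files carry no ref/alt designation, so the per-marker majority
allele is taken as reference and the mapping recorded in the returned
marker table.  Every emitted file carries the seed and config hash of the
run that produced it in a header comment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from starimpute.hmm import HaplotypePanel
from starimpute.panel import GenotypeMatrix, make_marker_table


def _header_meta(
    seed: int | None, config_hash: str | None, chroms=()
) -> list[str]:
    meta = ["##source=starimpute"]
    if seed is not None:
        meta.append(f"##starimpute_seed={seed}")
    if config_hash is not None:
        meta.append(f"##starimpute_config_hash={config_hash}")
    meta.extend(f"##contig=<ID={c}>" for c in dict.fromkeys(chroms))
    return meta


def write_phased_vcf(
    panel: HaplotypePanel,
    path,
    sample_ids: list[str] | None = None,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write a phased haplotype panel as VCF 4.2 with '|' separated GTs.

    Haplotype rows are paired into diploid sample columns (2i, 2i+1).
    """
    K = panel.n_haplotypes
    if K % 2 != 0:
        raise ValueError("phased panel must contain an even number of haplotypes")
    n = K // 2
    if sample_ids is None:
        sample_ids = [f"P{i:05d}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in _header_meta(seed, config_hash, panel.markers["chrom"].astype(str)):
            fh.write(line + "\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        H = panel.haplotypes
        for m, rec in enumerate(panel.markers.itertuples()):
            gts = "\t".join(
                f"{H[2 * i, m]}|{H[2 * i + 1, m]}" for i in range(n)
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_genotype_vcf(
    g: GenotypeMatrix,
    path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write an unphased genotype matrix as VCF 4.2 ('/' separated GTs)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in _header_meta(seed, config_hash, g.markers["chrom"].astype(str)):
            fh.write(line + "\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for m, rec in enumerate(g.markers.itertuples()):
            col = g.geno[:, m]
            gts = "\t".join(
                "./." if np.isnan(v) else gt_strings[int(v)] for v in col
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _markers_from_records(records) -> pd.DataFrame:
    ids, chroms, poss, refs, alts, pseudo = [], [], [], [], [], []
    for v in records:
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chroms.append(str(v.CHROM))
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        pseudo.append(v.ALT[0].startswith("<"))
    return make_marker_table(ids, chroms, poss, refs, alts, pseudo)


def read_vcf_phased(path) -> HaplotypePanel:
    """Read a phased VCF into a haplotype panel.

    Every GT must be phased ('|'); the first unphased record is named in
    the error.  Multiallelic records are rejected.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records, columns = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multiallelic record at {v.CHROM}:{v.POS} not supported")
        gts = v.genotypes  # [a0, a1, phased]
        for s, gt in zip(samples, gts):
            if not gt[2]:
                raise ValueError(
                    f"unphased genotype for sample {s} at {v.CHROM}:{v.POS} "
                    f"(id {v.ID}); a reference panel must be fully phased"
                )
            if gt[0] < 0 or gt[1] < 0:
                raise ValueError(
                    f"missing genotype at {v.CHROM}:{v.POS}; panels must be complete"
                )
        records.append(v)
        columns.append([a for gt in gts for a in gt[:2]])
    markers = _markers_from_records(records)
    haps = np.array(columns, dtype=np.int8).T  # K x M
    hap_samples = [s for s in samples for _ in range(2)]
    return HaplotypePanel(haps, markers, hap_samples)


def read_vcf_genotypes(path) -> GenotypeMatrix:
    """Read an (unphased or phased) VCF into a genotype matrix; './.' → missing."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records, columns = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multiallelic record at {v.CHROM}:{v.POS} not supported")
        col = []
        for gt in v.genotypes:
            if gt[0] < 0 or gt[1] < 0:
                col.append(np.nan)
            else:
                col.append(float(gt[0] + gt[1]))
        records.append(v)
        columns.append(col)
    markers = _markers_from_records(records)
    geno = np.array(columns, dtype=float).T
    return GenotypeMatrix(samples, markers, geno)


# ---------------------------------------------------------------- PED/MAP

def write_pedmap(
    g: GenotypeMatrix, ped_path, map_path, ref_letter: str = "A", alt_letter: str = "T"
) -> None:
    """Write a genotype matrix as PLINK text ped/map.

    Reference alleles are written as ``ref_letter``, alternates as
    ``alt_letter`` (pseudo-marker presence alleles map to ``alt_letter``);
    missing genotypes as '0 0'.
    """
    with open(map_path, "w") as fh:
        for rec in g.markers.itertuples():
            fh.write(f"{rec.chrom}\t{rec.id}\t0\t{rec.pos}\n")
    code = {0: f"{ref_letter} {ref_letter}", 1: f"{ref_letter} {alt_letter}",
            2: f"{alt_letter} {alt_letter}"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.samples):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for v in g.geno[i]:
                fields.append("0 0" if np.isnan(v) else code[int(v)])
            fh.write(" ".join(fields) + "\n")


def read_pedmap(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text ped/map into a genotype matrix.

    PED has no ref/alt, so per marker the majority allele letter becomes
    the reference (ties broken alphabetically); the chosen letters are
    recorded in the marker table's ref/alt columns so the encoding is
    reversible.  '0 0' genotypes are missing.
    """
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos"], dtype={"chrom": str},
    )
    n_markers = len(map_df)
    samples, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{(len(parts) - 6) // 2} genotype pairs, map has {n_markers} markers"
                )
            samples.append(parts[1])
            rows.append(parts[6:])
    allele_pairs = np.array(rows, dtype=object).reshape(len(samples), n_markers, 2)

    geno = np.full((len(samples), n_markers), np.nan)
    refs, alts = [], []
    for m in range(n_markers):
        letters = allele_pairs[:, m, :].ravel()
        observed = sorted({a for a in letters if a != "0"})
        if not observed:
            refs.append("N")
            alts.append("N")
            continue
        counts = {a: int((letters == a).sum()) for a in observed}
        ref = max(observed, key=lambda a: (counts[a], a))  # majority, tie → later letter stable
        others = [a for a in observed if a != ref]
        alt = others[0] if others else ("T" if ref != "T" else "A")
        refs.append(ref)
        alts.append(alt)
        for i in range(len(samples)):
            a1, a2 = allele_pairs[i, m]
            if a1 == "0" or a2 == "0":
                continue
            geno[i, m] = (a1 == alt) + (a2 == alt)
    markers = make_marker_table(
        map_df["id"], map_df["chrom"], map_df["pos"], refs, alts
    )
    return GenotypeMatrix(samples, markers, geno)


# ---------------------------------------------------------------- CN tables

def read_cn_tsv(path) -> pd.DataFrame:
    """Read per-sample copy-number calls from TSV.

    Accepts either a plain genotyping table (``sample_id, cn``) or an
    imputation output (``sample_id, best_guess_cn, ...``).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in df.columns or not {"cn", "best_guess_cn"} & set(df.columns):
        raise ValueError("CN table needs columns sample_id and cn (or best_guess_cn)")
    return df


def write_cn_tsv(
    df: pd.DataFrame, path, seed: int | None = None, config_hash: str | None = None
) -> None:
    """Write an imputed-CN table with provenance header comments."""
    with open(path, "w") as fh:
        fh.write("# starimpute copy-number calls\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)
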