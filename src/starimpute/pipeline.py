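"""End-to-end run: simulate → build panel → impute → call stars → validate.

Each stage writes its outputs into a run directory, and a provenance
manifest records the package version, seed, configuration hash and sha256
of every stage input, so a rerun with the same configuration reproduces
byte-identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import starimpute
from starimpute import hmm, simdata, stars, validate, vcfio
from starimpute.panel import (
    CopyNumberCall,
    GenotypeMatrix,
    encode_copy_number,
    merge_pseudo_markers,
    qc_filter,
)


@dataclass
class PipelineConfig:
    """Paths, thresholds and parameters for a full pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    panel_vcf: str | None = None  # used when simulate=False
    cnv_tsv: str | None = None
    target_vcf: str | None = None
    qc_thresholds: dict = field(default_factory=dict)
    hmm_theta: float = 0.01
    hmm_switch_at_unit: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if not cfg.simulate:
            for name in ("panel_vcf", "cnv_tsv", "target_vcf"):
                p = getattr(cfg, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"pipeline input {name} missing or not found: {p}"
                    )
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage failures propagate wrapped with the stage name.  With
    ``simulate=True`` the synthetic generator provides panel, truth and
    targets; otherwise panel/CNV/target files are read from the configured
    paths.  Targets from files are naively phased against the panel; the
    manifest records which phasing path was used.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "version": starimpute.__version__,
        "seed": config.seed,
        "config_hash": chash,
        "stages": {},
        "inputs": {},
    }

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = "ok"
            return result

        return deco

    if config.simulate:
        @stage("simulate")
        def study():
            s = simdata.simulate_study(
                simdata.SimConfig(**{"seed": config.seed, **config.sim})
            )
            vcfio.write_phased_vcf(
                s.panel, out / "panel.vcf", seed=config.seed, config_hash=chash
            )
            s.target_truth.sample_cn.to_csv(out / "truth.tsv", sep="\t", index=False)
            return s

        panel = study.panel
        target_haps = study.target_haps
        target_samples = study.target_samples
        truth = study.target_truth.sample_cn
        phasing = "simulator-truth (pre-phased)"
    else:
        @stage("build-panel")
        def built():
            chip = vcfio.read_vcf_genotypes(config.panel_vcf)
            manifest["inputs"]["panel_vcf"] = _sha256(Path(config.panel_vcf))
            chip_qc, report = qc_filter(chip, config.qc_thresholds)
            cn_df = vcfio.read_cn_tsv(config.cnv_tsv)
            manifest["inputs"]["cnv_tsv"] = _sha256(Path(config.cnv_tsv))
            cn_df = cn_df[cn_df["sample_id"].isin(chip_qc.samples)]
            calls = [
                CopyNumberCall(r.sample_id, int(r.cn)) for r in cn_df.itertuples()
            ]
            merged = merge_pseudo_markers(chip_qc, encode_copy_number(calls))
            (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=2))
            return merged

        # reference phasing: genotype matrix → trivially phased haplotypes.
        # Simulated/merged panels are homozygous-complete already; real
        # chip data would be pre-phased upstream.
        @stage("phase-panel")
        def panel():
            g: GenotypeMatrix = built
            haps = np.zeros((2 * g.n_samples, g.n_markers), dtype=np.int8)
            geno = np.nan_to_num(g.geno, nan=0.0)
            haps[0::2] = (geno >= 1).astype(np.int8)
            haps[1::2] = (geno == 2).astype(np.int8)
            return hmm.HaplotypePanel(
                haps, g.markers, [s for s in g.samples for _ in range(2)]
            )

        @stage("phase-targets")
        def phased():
            targets = vcfio.read_vcf_genotypes(config.target_vcf)
            manifest["inputs"]["target_vcf"] = _sha256(Path(config.target_vcf))
            pseudo_free = panel.drop_markers(
                np.flatnonzero(panel.markers["is_pseudo"].to_numpy(bool))
            )
            params = hmm.HMMParams(
                rho=float(
                    hmm.compute_switch_probs(
                        1,
                        panel.n_haplotypes,
                        hmm.default_scale(panel.n_haplotypes, config.hmm_switch_at_unit),
                    )[0]
                ),
                theta=config.hmm_theta,
            )
            return (
                hmm.phase_cohort(targets, pseudo_free, params),
                list(targets.samples),
            )

        target_haps, target_samples = phased
        truth = None
        phasing = "naive Viterbi phasing"

    @stage("impute")
    def imputed():
        params = hmm.HMMParams(
            rho=float(
                hmm.compute_switch_probs(
                    1,
                    panel.n_haplotypes,
                    hmm.default_scale(panel.n_haplotypes, config.hmm_switch_at_unit),
                )[0]
            ),
            theta=config.hmm_theta,
        )
        calls, dosages = hmm.impute_cnv_cohort(
            target_haps, target_samples, panel, params
        )
        vcfio.write_cn_tsv(dosages, out / "imputed_cn.tsv", seed=config.seed,
                           config_hash=chash)
        return calls

    @stage("call-stars")
    def phenotypes():
        table = stars.load_default_definitions()
        preds = []
        empty = ({}, {})  # no star-defining variants on the simulated chip
        for call in imputed:
            preds.append(stars.call_sample("CYP2D6", empty, call.cn, table))
        summary = stars.summarize_phenotypes(preds)
        summary.to_csv(out / "phenotype_prevalence.tsv", sep="\t", index=False)
        return preds

    if truth is not None:
        @stage("validate")
        def report():
            truth_calls = [
                CopyNumberCall(r.sample_id, int(r.true_cn))
                for r in truth.itertuples()
            ]
            table = validate.contingency(imputed, truth_calls)
            metrics = {
                "accuracy": table.accuracy(),
                "n": table.total,
                "contingency": {
                    "genotyped_classes": table.row_labels,
                    "imputed_classes": table.col_labels,
                    "counts": table.counts.tolist(),
                },
            }
            dup = validate.class_metrics(
                table, positive=lambda cn: cn >= 3, predicted_positive=lambda cn: cn >= 3
            )
            metrics["duplication_sensitivity"] = dup.sensitivity
            metrics["duplication_specificity"] = dup.specificity
            (out / "validation.json").write_text(json.dumps(metrics, indent=2))
            return metrics

    manifest["phasing"] = phasing
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["inputs"].setdefault(f.name, _sha256(f))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
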