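"""End-to-end orchestration: simulate -> expression filter -> EAI -> screen -> integrate.

Each stage logs its input/output row counts and active thresholds; an
identical config (including seed) reproduces identical output files byte
for byte.
"""
from __future__ import annotations

import logging
from pathlib import Path

from . import io, simulate
from .clinical import ClinicalScreen, hematology_correlates
from .config import PipelineConfig, SimConfig
from .eai import EaiAnalysis
from .expression import fold_change_filter, scale_normalize
from .integrate import gene_rollup, intersect, report, write_report

logger = logging.getLogger("thioscreen")


def run_pipeline(config: PipelineConfig, out_dir) -> dict[str, Path]:
    """Run every stage on freshly simulated data; returns output paths.

    Raises on the first stage failure with a stage-named message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim or SimConfig(seed=config.seed)
    paths: dict[str, Path] = {}

    def _stage(name):
        logger.info("stage %s starting", name)

    try:
        _stage("simulate")
        line_geno = simulate.simulate_genotypes(sim, sim.n_lines, "line")
        pat_geno = simulate.simulate_genotypes(sim, sim.n_patients, "patient")
        signals = simulate.simulate_allele_signals(line_geno, sim)
        patients = simulate.simulate_patients(sim, pat_geno)
        probes, _probe_truth = simulate.simulate_probe_signals(sim)
        truth = simulate.truth_set(sim)
        paths["line_genotypes"] = out / "line_genotypes.tsv"
        paths["patient_genotypes"] = out / "patient_genotypes.tsv"
        paths["allele_signals"] = out / "allele_signals.tsv"
        paths["clinical"] = out / "clinical.csv"
        paths["probe_signals"] = out / "probe_signals.tsv"
        paths["truth"] = out / "truth.json"
        io.write_genotypes(line_geno, paths["line_genotypes"])
        io.write_genotypes(pat_geno, paths["patient_genotypes"])
        io.write_allele_signals(signals, paths["allele_signals"])
        io.write_clinical(patients, paths["clinical"])
        io.write_probe_signals(probes, paths["probe_signals"])
        io.write_truth(truth, paths["truth"])
        logger.info(
            "simulate: %d lines, %d patients, %d SNPs, %d signal rows",
            sim.n_lines, sim.n_patients, sim.n_snps, len(signals),
        )
    except Exception as err:
        raise RuntimeError(f"stage simulate failed: {err}") from err

    try:
        _stage("expression-filter")
        norm = scale_normalize(probes, target=config.norm_target)
        fc = fold_change_filter(norm, up_min=config.up_min,
                                down_max=config.down_max)
        paths["expression_ratios"] = out / "expression_ratios.tsv"
        paths["expression_summary"] = out / "expression_summary.json"
        fc.ratios.to_csv(paths["expression_ratios"], sep="\t", index=False)
        io.write_json(fc.summary(), paths["expression_summary"])
        logger.info("expression-filter: %s", fc.summary())
    except Exception as err:
        raise RuntimeError(f"stage expression-filter failed: {err}") from err

    try:
        _stage("eai")
        eai_res = EaiAnalysis(
            signals, line_geno,
            threshold=config.eai_threshold, alpha=config.alpha_eai,
            min_het=config.min_het, fold_min=config.fold_min,
            fold_rule=config.fold_rule,
        ).fit()
        paths["eai_per_line"] = out / "eai_per_line.tsv"
        paths["eai_cohort"] = out / "eai_cohort.tsv"
        paths["eai_summary"] = out / "eai_summary.json"
        io.write_hits(eai_res.per_line, paths["eai_per_line"])
        io.write_hits(eai_res.cohort, paths["eai_cohort"])
        io.write_json(eai_res.summary_counts(), paths["eai_summary"])
        logger.info(
            "eai: %d het pairs, %d responsive SNPs",
            len(eai_res.per_line), int(eai_res.cohort["responsive"].sum()),
        )
    except Exception as err:
        raise RuntimeError(f"stage eai failed: {err}") from err

    try:
        _stage("screen")
        screen_res = ClinicalScreen(
            pat_geno, patients,
            r2_min=config.r2_min, alpha=config.alpha_clinical,
            threshold_on=config.threshold_on, min_dose=config.min_dose,
            min_per_class=config.min_per_class,
        ).fit()
        paths["clinical_hits"] = out / "clinical_hits.tsv"
        paths["exclusion_report"] = out / "exclusion_report.json"
        io.write_hits(screen_res.hits, paths["clinical_hits"])
        io.write_json(
            {
                "excluded_samples": screen_res.excluded_samples,
                "n_retained": screen_res.n_retained,
                "min_dose": config.min_dose,
            },
            paths["exclusion_report"],
        )
        try:
            hema = hematology_correlates(screen_res._records)
        except Exception:
            hema = {}
        paths["hematology"] = out / "hematology.json"
        io.write_json(hema, paths["hematology"])
        logger.info(
            "screen: %d retained patients, %d passing SNPs",
            screen_res.n_retained, int(screen_res.hits["passes_threshold"].sum()),
        )
    except Exception as err:
        raise RuntimeError(f"stage screen failed: {err}") from err

    try:
        _stage("integrate")
        hits = intersect(
            screen_res.hits, eai_res.per_line, eai_res.cohort,
            mode=config.integrate_mode,
        )
        rep = report(hits, config.to_dict())
        rep["truth"] = {
            "eai_snp_ids": sorted(truth.eai_snp_ids),
            "clinical_snp_ids": sorted(truth.clinical_snp_ids),
            "recovered_coincident": sorted(
                set(hits.loc[hits["coincident"], "snp_id"])
                & (truth.eai_snp_ids & truth.clinical_snp_ids)
            ),
        }
        paths["integrated_hits"] = out / "integrated_hits.tsv"
        paths["report"] = out / "report.json"
        paths["gene_rollup"] = out / "gene_rollup.tsv"
        io.write_hits(hits, paths["integrated_hits"])
        gene_rollup(hits).to_csv(paths["gene_rollup"], sep="\t", index=False)
        write_report(rep, paths["report"])
        logger.info(
            "integrate: %d clinical-pass SNPs, %d coincident",
            len(hits), int(hits["coincident"].sum()),
        )
    except Exception as err:
        raise RuntimeError(f"stage integrate failed: {err}") from err

    return paths
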