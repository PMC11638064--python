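"""End-to-end orchestration: simulate → splice-scan → quantify → read analysis → regress.

A run is driven by a :class:`RunConfig` holding either a synthetic-data
specification (the default) or paths to pre-existing inputs. Every stage
reads from and writes plain files in the run directory, so stages can be
re-run individually from intermediates, and the whole run is deterministic
under a fixed seed: one seeded generator is split into stage-scoped
substreams up front.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import coverage_quant as cq
from . import read_analysis as ra
from . import splice_model
from . import synthetic_data as syn
from .gene_model import (
    GeneModel,
    VariantSite,
    build_region_set,
    read_bed,
    read_gtf,
    write_bed,
)
from .stats import ols_dosage

log = logging.getLogger("branchretain")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    synthetic: bool = True
    inputs: Optional[dict] = None  # paths: fasta, gtf, vcf, sam, fastq, genotypes, activity, methylation
    cohort: Optional[syn.CohortSpec] = None
    activity: Optional[syn.ActivityModel] = None
    methylation: Optional[syn.MethylationModel] = None
    short_window_len: Optional[int] = None  # default: the predicted retained segment
    mode: str = "long"
    swap_control_max_reads: int = 50

    def __post_init__(self):
        if self.synthetic and self.inputs:
            raise ValueError("provide either a synthetic spec or input paths, not both")
        if not self.synthetic and not self.inputs:
            raise ValueError("non-synthetic run requires input paths")

    def content_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "synthetic": self.synthetic,
                "inputs": self.inputs,
                "cohort": vars(self.cohort) if self.cohort else None,
                "activity": vars(self.activity) if self.activity else None,
                "methylation": vars(self.methylation) if self.methylation else None,
                "short_window_len": self.short_window_len,
                "mode": self.mode,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
        kwargs["cohort"] = syn.CohortSpec(**kwargs["cohort"])
    if "activity" in kwargs and isinstance(kwargs["activity"], dict):
        kwargs["activity"] = syn.ActivityModel(**kwargs["activity"])
    if "methylation" in kwargs and isinstance(kwargs["methylation"], dict):
        kwargs["methylation"] = syn.MethylationModel(**kwargs["methylation"])
    return RunConfig(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _read_fasta_one(path: str) -> tuple[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(path, rebuild=True)
    name = list(fa.keys())[0]
    return name, str(fa[name][:])


def _read_vcf_variant(path: str) -> tuple[str, VariantSite]:
    import pysam

    with pysam.VariantFile(path) as vf:
        rec = next(iter(vf))
    return rec.chrom, VariantSite(pos=rec.pos - 1, ref=rec.ref, alt=rec.alts[0])


def _model_from_files(gtf: str, vcf: str) -> GeneModel:
    """Reassemble the analysis gene model: the GTF gene containing the variant,
    its focal intron located from the variant position, and any second GTF gene
    attached as the paralog."""
    models = read_gtf(gtf)
    chrom, variant = _read_vcf_variant(vcf)
    target = None
    for m in models:
        lo, hi = m.span
        if m.chrom == chrom and lo <= variant.pos < hi:
            target = m
            break
    if target is None:
        raise ValueError("no GTF gene contains the VCF variant")
    target.variant_site = variant
    for i, (s, e) in enumerate(target.introns):
        if s <= variant.pos < e:
            target.focal_intron_index = i
            break
    else:
        raise ValueError("variant is not intronic in the annotated gene")
    others = [m for m in models if m is not target]
    if others:
        target.paralog = others[0]
    return target


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the JSON-ready summary dict."""
    os.makedirs(config.outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(config.outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {
        "schema_version": 1,
        "seed": config.seed,
        "config_hash": config.content_hash(),
    }
    try:
        # stage seeds: one substream per stochastic stage
        ss = np.random.SeedSequence(config.seed).spawn(3)
        stage_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]

        # ---- stage 1: inputs -------------------------------------------------
        stage = "simulate" if config.synthetic else "load"
        log.info("stage %s", stage)
        if config.synthetic:
            cohort = config.cohort or syn.CohortSpec()
            cohort.seed = stage_seeds[0]
            syn.write_fixture_bundle(
                config.outdir,
                cohort=cohort,
                activity=config.activity,
                methylation=config.methylation,
                ref_seed=0,
                seed=stage_seeds[0],
                short_window_len=config.short_window_len,
                mode=config.mode,
            )
            inputs = {
                k: os.path.join(config.outdir, v)
                for k, v in {
                    "fasta": "reference.fasta", "gtf": "genes.gtf", "vcf": "variant.vcf",
                    "sam": "truth.sam", "fastq": "reads.fastq", "genotypes": "genotypes.tsv",
                    "activity": "activity.tsv", "methylation": "methylation.tsv",
                    "truth": "truth.tsv",
                }.items()
            }
        else:
            inputs = dict(config.inputs)

        # ---- stage 2: splice scan -------------------------------------------
        stage = "splice-scan"
        log.info("stage %s", stage)
        model = _model_from_files(inputs["gtf"], inputs["vcf"])
        _, chrom_seq = _read_fasta_one(inputs["fasta"])
        model.validate_splice_sites(chrom_seq)
        intron = model.focal_intron()
        intron_seq = model.intron_seq(chrom_seq, intron)
        var_off = model.genomic_to_intron_offset(intron, model.variant_site.pos).offset
        ref_t = model.transcript_orientation(model.variant_site.ref)
        alt_t = model.transcript_orientation(model.variant_site.alt)
        call = splice_model.call_splice_disruption(intron_seq, var_off, ref_t, alt_t)
        pd.DataFrame(
            [(c.window_rank, c.offset, c.motif_score) for c in call.candidates],
            columns=["rank", "offset", "motif_score"],
        ).to_csv(os.path.join(config.outdir, "branchpoint_candidates.tsv"), sep="\t", index=False)
        isoforms = splice_model.predict_isoforms(model, call)
        splice_model.write_isoform_gtf(
            model, isoforms, os.path.join(config.outdir, "predicted_isoforms.gtf")
        )
        summary["splice"] = {
            "variant_offset": var_off,
            "branchpoint_offset": call.primary_bp.offset if call.primary_bp else None,
            "disrupted": call.disrupted,
            "cryptic_acceptor_offset": call.cryptic_acceptor,
            "bp_to_acceptor_gap": call.bp_to_acceptor_gap,
            "retained_len": call.retained_len,
            "predicted_isoforms": sorted(call.predicted_isoforms),
        }

        # ---- stage 3: regions + quantify ------------------------------------
        stage = "quantify"
        log.info("stage %s", stage)
        swl = config.short_window_len or call.retained_len or 40
        regions = build_region_set(model, swl)
        write_bed(regions, os.path.join(config.outdir, "regions.bed"))
        genos = pd.read_csv(inputs["genotypes"], sep="\t").set_index("sample")["genotype"].to_dict()
        records = cq.read_sam(inputs["sam"])
        per_sample: dict[str, list] = {s: [] for s in genos}
        for rec in records:
            sample = rec.read_id.split("|")[0]
            per_sample.setdefault(sample, []).append(rec)
        cov = cq.coverage_table(per_sample, regions, genos)
        cov.to_csv(os.path.join(config.outdir, "coverage.tsv"), sep="\t", index=False)

        assoc_rows = []
        summary["association"] = {}
        for rname in ["intron_short_window", "intron_full", "intron_rest", "exon_up", "exon_down"]:
            sub = cov[cov["region"] == rname]
            pairs = list(zip(sub["normalized"], sub["genotype"]))
            try:
                res = cq.coverage_genotype_association(pairs)
                assoc_rows.append((rname, res.grouping, res.slope, res.se, res.p, res.r2_unadjusted, res.n))
                summary["association"][rname] = {
                    "grouping": res.grouping, "slope": res.slope, "se": res.se,
                    "p": res.p, "r2": res.r2_unadjusted, "n": res.n,
                }
            except ValueError as err:
                assoc_rows.append((rname, "none", np.nan, np.nan, np.nan, np.nan, len(pairs)))
                summary["association"][rname] = {"error": str(err)}
        pd.DataFrame(
            assoc_rows, columns=["region", "grouping", "slope", "se", "p", "r2", "n"]
        ).to_csv(os.path.join(config.outdir, "association.tsv"), sep="\t", index=False)

        # ---- stage 4: read analysis -----------------------------------------
        stage = "read-analysis"
        log.info("stage %s", stage)
        risk, nonrisk = syn.RISK_ALLELE, syn.NONRISK_ALLELE
        kept = [r for r in records if cq.RETENTION_PROFILE.passes(r)]
        iso_calls = {r.read_id: ra.classify_isoform(r, regions) for r in kept}
        allele_calls = {
            r.read_id: ra.assign_allele(r, model.variant_site, risk, nonrisk) for r in kept
        }
        pd.DataFrame(
            [
                (rid, iso_calls[rid].klass, allele_calls[rid].allele, allele_calls[rid].base)
                for rid in iso_calls
            ],
            columns=["read_id", "isoform_class", "allele", "base"],
        ).to_csv(os.path.join(config.outdir, "read_calls.tsv"), sep="\t", index=False)

        retention_ids = [
            rid for rid, c in iso_calls.items() if c.klass in (ra.PARTIAL, ra.FULL)
        ]
        purity = ra.haplotype_purity([allele_calls[rid] for rid in retention_ids])
        summary["haplotype_purity"] = {
            "defined": purity.defined,
            "fraction_risk": purity.fraction_risk,
            "n_covered": purity.n_covered,
            "ci": [purity.ci_low, purity.ci_high] if purity.defined else None,
        }

        if model.paralog is not None:
            lo, hi = model.span
            plo, phi = model.paralog.span
            covering = [r for r in kept if r.base_at(model.variant_site.pos) is not None]
            rng = np.random.default_rng(stage_seeds[1])
            if len(covering) > config.swap_control_max_reads:
                idx = rng.choice(len(covering), config.swap_control_max_reads, replace=False)
                covering = [covering[i] for i in sorted(idx)]
            swap = ra.allele_swap_control(
                covering, model.variant_site, chrom_seq[lo:hi], chrom_seq[plo:phi], risk, nonrisk
            )
            swap.per_read.to_csv(
                os.path.join(config.outdir, "swap_control.tsv"), sep="\t", index=False
            )
            summary["swap_control"] = {
                "concordance": swap.concordance,
                "n_evaluated": swap.n_evaluated,
                "n_ambiguous": swap.n_ambiguous,
                "warning": swap.warning,
            }

        if inputs.get("fastq"):
            whitelist = syn.make_barcode_whitelist()
            fq_reads = []
            with open(inputs["fastq"]) as fh:
                lines = fh.read().splitlines()
            for i in range(0, len(lines) - 3, 4):
                fq_reads.append((lines[i][1:], lines[i + 1]))
            demux = ra.demux_barcodes(fq_reads, whitelist)
            demux.counts.to_csv(os.path.join(config.outdir, "demux.tsv"), sep="\t", index=False)
            summary["demux"] = {
                "observed_whitelist_ratio": demux.observed_whitelist_ratio,
                "n_unassigned": len(demux.assignments["unassigned"]),
            }

        # ---- stage 5: methylation -------------------------------------------
        if inputs.get("methylation"):
            stage = "methylation"
            log.info("stage %s", stage)
            meth = pd.read_csv(inputs["methylation"], sep="\t")
            contrast = ra.methylation_by_allele(meth, risk, nonrisk)
            summary["methylation"] = {
                "fractions": contrast.fractions,
                "p": contrast.p,
                "odds_ratio": contrast.odds_ratio,
                "defined": contrast.defined,
            }

        # ---- stage 6: activity regression ------------------------------------
        if inputs.get("activity"):
            stage = "regress"
            log.info("stage %s", stage)
            act = pd.read_csv(inputs["activity"], sep="\t")
            res = ols_dosage(act["activity"], act["dosage"])
            summary["gcase_regression"] = {
                "slope": res.slope, "se": res.se, "p": res.p,
                "r2": res.r2_unadjusted, "n": res.n,
            }

        out = os.path.join(config.outdir, "summary.json")
        with open(out, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log.info("wrote %s", out)
        return summary
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001 - annotate with stage context
        raise StageError(stage, str(err)) from err
    finally:
        log.removeHandler(handler)
        handler.close()
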