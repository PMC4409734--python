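"""End-to-end orchestration: QC -> ROH -> F_L -> scans -> reports.

``run_pipeline`` executes every stage on one dataset and writes all per-SNP
tracks, candidate-region tables, an autozygosity/scan cross-tabulation and
(optionally) Manhattan-style plots, together with a run manifest that echoes
every parameter and seed so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ehh_stats as ehh_mod
from . import genotype_io as gio
from . import haplotype_analysis as hap
from . import roh as roh_mod
from . import selection_scan as scan_mod

logger = logging.getLogger("herdsweep")


@dataclass
class RunConfig:
    """All inputs, stage parameters and seeds for one pipeline run."""

    genotypes_vcf: str = ""
    haplotypes_vcf: str = ""
    pedigree_tsv: str = ""
    traits_tsv: str = ""
    ancestral_tsv: str = ""
    outdir: str = "herdsweep_out"
    # QC
    maf_min: float = 0.01
    call_rate_min: float = 0.8
    # ROH
    roh_min_snps: int = 50
    roh_min_length_bp: int = 1_000_000
    roh_missing_policy: str = "break"
    roh_bridge_k: int = 0
    # birth-year scan
    n_perm: int = 1000
    perm_seed: int = 1
    region_min_size_bp: int = 500_000
    region_merge_gap_bp: int = 250_000
    # haplotype windows
    window_snps: int = 50
    window_step: int = 1
    trait_names: list = field(default_factory=lambda: ["milk", "fat", "protein"])
    # iHS / Rsb
    ihs_maf_min: float = 0.03
    rsb_maf_min: float = 0.02
    max_bracket_bp: int = 5_000_000
    truncation_ehh: float = 0.05
    gap_bp: int = 500_000
    n_ancestral_cohort: int = 300
    ancestral_cutoff_year: int = 1991
    contemporary_year_lo: int = 2001
    contemporary_year_hi: int = 2007
    cohort_seed: int = 1
    # cross-tab
    fl_threshold: float = 0.3
    crosstab_min_size_bp: int = 1_000_000
    make_plots: bool = False

    def manifest(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    config: RunConfig
    genotypes: "gio.GenotypeMatrix"
    fl_track: "roh_mod.AutozygosityTrack"
    roh_segments: list
    scan: "scan_mod.LogisticScanResult"
    thresholds: "scan_mod.PermutationThresholds"
    regions: list
    windows: list
    hap_scan: "scan_mod.LogisticScanResult"
    hap_thresholds: "scan_mod.PermutationThresholds"
    trait_results: dict
    ihs: pd.DataFrame
    ihs_regions: list
    rsb: pd.DataFrame
    rsb_regions: list
    crosstab: pd.DataFrame
    outputs: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    cfg: RunConfig,
    pop=None,
) -> PipelineResult:
    """Run every stage; ``pop`` (a SimPopulation) bypasses file inputs.

    Outputs are written under ``cfg.outdir``; the stage order is
    qc -> roh -> F_L -> birth-year scan -> windows -> iHS -> Rsb -> trait GLM
    -> cross-tabulation.  A stage failure aborts with the stage name; files
    written by earlier stages are left in place.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _Ctx()

    with stage("load"):
        if pop is not None:
            genotypes = pop.genotypes
            haplotypes = pop.haplotypes
            pedigree = pop.pedigree
            traits = pop.traits
        else:
            genotypes = gio.read_genotypes(cfg.genotypes_vcf, "vcf")
            haplotypes = gio.read_haplotypes(cfg.haplotypes_vcf)
            pedigree = gio.read_pedigree(cfg.pedigree_tsv)
            traits = gio.read_traits(cfg.traits_tsv)
            if cfg.ancestral_tsv:
                markers = gio.read_ancestral_alleles(cfg.ancestral_tsv, genotypes.markers)
                genotypes.markers = markers
                haplotypes.markers = gio.read_ancestral_alleles(
                    cfg.ancestral_tsv, haplotypes.markers
                )

    with stage("qc"):
        qc = gio.qc_filter(genotypes, cfg.maf_min, cfg.call_rate_min)
        kept = set(qc.markers.snp_id.tolist())
        hap_keep = np.array([s in kept for s in haplotypes.markers.snp_id])
        hp = gio.HaplotypePanel(
            list(haplotypes.animals),
            haplotypes.markers.subset(np.flatnonzero(hap_keep)),
            haplotypes.haps[:, :, hap_keep],
        )

    birth_years = pedigree.birth_years(qc.animals)

    with stage("roh"):
        segments = roh_mod.detect_roh(
            qc,
            cfg.roh_min_snps,
            cfg.roh_min_length_bp,
            cfg.roh_missing_policy,
            cfg.roh_bridge_k,
        )
        outputs["roh"] = outdir / "roh_segments.tsv"
        roh_mod.write_roh(segments, outputs["roh"])

    with stage("autozygosity"):
        track = roh_mod.locus_autozygosity(segments, qc, pedigree)
        outputs["fl"] = outdir / "locus_autozygosity.tsv"
        track.to_frame().to_csv(outputs["fl"], sep="\t", index=False, float_format="%.6g")
        inb = roh_mod.inbreeding_table(segments, qc, pedigree)
        outputs["inbreeding"] = outdir / "inbreeding.tsv"
        inb.to_csv(outputs["inbreeding"], sep="\t", index=False, float_format="%.6g")

    with stage("birthyear_scan"):
        coverage = roh_mod.coverage_matrix(segments, qc)
        scan = scan_mod.scan_genome(coverage, birth_years, qc.markers)
        thresholds = scan_mod.permutation_thresholds(
            coverage, birth_years, cfg.n_perm, cfg.perm_seed
        )
        regions = scan_mod.call_regions(
            scan,
            thresholds.threshold_5pct,
            cfg.region_min_size_bp,
            cfg.region_merge_gap_bp,
        )
        outputs["scan"] = outdir / "birthyear_scan.tsv"
        scan_mod.write_scan(scan, outputs["scan"])
        outputs["scan_thresholds"] = outdir / "birthyear_thresholds.tsv"
        scan_mod.write_thresholds(thresholds, outputs["scan_thresholds"])
        outputs["regions"] = outdir / "birthyear_regions.tsv"
        scan_mod.write_regions(regions, outputs["regions"])

    with stage("hap_windows"):
        windows = hap.enumerate_windows(hp, cfg.window_snps, cfg.window_step)
        outputs["windows"] = outdir / "haplotype_windows.tsv"
        hap.write_windows(windows, outputs["windows"])

    with stage("hap_birthyear"):
        hap_scan, hap_thr = hap.birthyear_haplotype_scan(
            windows, pedigree, hp.animals, cfg.n_perm, cfg.perm_seed
        )
        outputs["hap_scan"] = outdir / "haplotype_birthyear_scan.tsv"
        hap.haplotype_scan_frame(windows, hap_scan).to_csv(
            outputs["hap_scan"], sep="\t", index=False, float_format="%.6g"
        )

    with stage("hap_traits"):
        trait_results = {}
        for trait in cfg.trait_names:
            res, thr = hap.trait_association(
                windows, traits, hp.animals, trait, cfg.n_perm, cfg.perm_seed
            )
            trait_results[trait] = (res, thr)
            outputs[f"trait_{trait}"] = outdir / f"trait_assoc_{trait}.tsv"
            res.to_frame().to_csv(
                outputs[f"trait_{trait}"], sep="\t", index=False, float_format="%.6g"
            )

    with stage("ihs"):
        ihs = ehh_mod.ihs_scan(
            hp,
            cfg.ihs_maf_min,
            max_bracket_bp=cfg.max_bracket_bp,
            truncation_ehh=cfg.truncation_ehh,
            gap_bp=cfg.gap_bp,
        )
        ihs_regions = ehh_mod.ihs_candidates(ihs)
        outputs["ihs"] = outdir / "ihs.tsv"
        ehh_mod.write_table(ihs, outputs["ihs"])
        outputs["ihs_regions"] = outdir / "ihs_regions.tsv"
        scan_mod.write_regions(ihs_regions, outputs["ihs_regions"])

    with stage("rsb"):
        split = ehh_mod.split_cohorts(
            pedigree,
            hp.animals,
            cfg.n_ancestral_cohort,
            cfg.ancestral_cutoff_year,
            (cfg.contemporary_year_lo, cfg.contemporary_year_hi),
            cfg.cohort_seed,
        )
        rsb = ehh_mod.rsb_scan(
            hp,
            split,
            cfg.rsb_maf_min,
            cfg.max_bracket_bp,
            cfg.truncation_ehh,
            cfg.gap_bp,
        )
        rsb_regions = ehh_mod.rsb_candidates(rsb)
        outputs["rsb"] = outdir / "rsb.tsv"
        ehh_mod.write_table(rsb, outputs["rsb"])
        outputs["rsb_regions"] = outdir / "rsb_regions.tsv"
        scan_mod.write_regions(rsb_regions, outputs["rsb_regions"])

    with stage("crosstab"):
        crosstab = crosstab_regions(
            track, ihs, rsb, qc, cfg.fl_threshold, cfg.crosstab_min_size_bp
        )
        outputs["crosstab"] = outdir / "high_fl_crosstab.tsv"
        crosstab.to_csv(outputs["crosstab"], sep="\t", index=False, float_format="%.6g")

    if cfg.make_plots:
        with stage("plots"):
            outputs["fl_plot"] = outdir / "fl_manhattan.png"
            manhattan(
                track.markers, track.fl, outputs["fl_plot"], ylabel="F_L"
            )
            outputs["scan_plot"] = outdir / "birthyear_manhattan.png"
            manhattan(
                qc.markers,
                scan.neg_log10_p,
                outputs["scan_plot"],
                ylabel="-log10 p",
                hlines=[thresholds.threshold_5pct, thresholds.threshold_1pct],
            )

    with stage("manifest"):
        manifest = {
            "config": cfg.manifest(),
            "n_animals": qc.n_animals,
            "n_snps_post_qc": qc.n_snps,
            "n_roh_segments": len(segments),
            "timings_s": timings,
            "outputs": {k: str(v) for k, v in outputs.items()},
        }
        outputs["manifest"] = outdir / "manifest.json"
        with open(outputs["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        config=cfg,
        genotypes=qc,
        fl_track=track,
        roh_segments=segments,
        scan=scan,
        thresholds=thresholds,
        regions=regions,
        windows=windows,
        hap_scan=hap_scan,
        hap_thresholds=hap_thr,
        trait_results=trait_results,
        ihs=ihs,
        ihs_regions=ihs_regions,
        rsb=rsb,
        rsb_regions=rsb_regions,
        crosstab=crosstab,
        outputs=outputs,
    )


def crosstab_regions(
    fl_track: "roh_mod.AutozygosityTrack",
    ihs: pd.DataFrame,
    rsb: pd.DataFrame,
    genotypes: "gio.GenotypeMatrix",
    fl_threshold: float = 0.3,
    min_size_bp: int = 1_000_000,
    report_threshold: float = 2.0,
) -> pd.DataFrame:
    """High-autozygosity regions annotated with their extreme EHH statistics.

    Contiguous runs of SNPs with F_L > ``fl_threshold`` spanning more than
    ``min_size_bp`` are reported with the maximum |iHS| and |Rsb| inside
    (shown only when above ``report_threshold``) and the major allele
    frequency at the iHS peak SNP.
    """
    markers = fl_track.markers
    rows = []
    freq_b = genotypes.allele_b_frequency()
    for chrom in markers.chromosomes():
        sl = markers.chrom_slice(int(chrom))
        high = fl_track.fl[sl] > fl_threshold
        pos = markers.position_bp[sl]
        for s, e in roh_mod._runs_of(high):
            if pos[e] - pos[s] <= min_size_bp:
                continue
            lo, hi = int(pos[s]), int(pos[e])
            sel_i = (
                (ihs["chromosome"] == chrom)
                & (ihs["position_bp"] >= lo)
                & (ihs["position_bp"] <= hi)
                & ihs["ihs"].notna()
            )
            sel_r = (
                (rsb["chromosome"] == chrom)
                & (rsb["position_bp"] >= lo)
                & (rsb["position_bp"] <= hi)
                & rsb["rsb"].notna()
            )
            max_ihs = float(ihs.loc[sel_i, "ihs"].abs().max()) if sel_i.any() else np.nan
            max_rsb = float(rsb.loc[sel_r, "rsb"].abs().max()) if sel_r.any() else np.nan
            maj = np.nan
            if sel_i.any() and not np.isnan(max_ihs):
                peak = ihs.loc[sel_i].iloc[
                    ihs.loc[sel_i, "ihs"].abs().to_numpy().argmax()
                ]
                panel_j = np.flatnonzero(markers.snp_id == peak["snp_id"])
                if panel_j.size:
                    p = freq_b[panel_j[0]]
                    maj = float(max(p, 1 - p))
            rows.append(
                {
                    "chromosome": int(chrom),
                    "start_bp": lo,
                    "end_bp": hi,
                    "size_bp": hi - lo,
                    "max_fl": float(fl_track.fl[sl][s : e + 1].max()),
                    "max_abs_ihs": max_ihs if max_ihs > report_threshold else np.nan,
                    "max_abs_rsb": max_rsb if max_rsb > report_threshold else np.nan,
                    "major_allele_freq_at_ihs_peak": maj,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "start_bp",
            "end_bp",
            "size_bp",
            "max_fl",
            "max_abs_ihs",
            "max_abs_rsb",
            "major_allele_freq_at_ihs_peak",
        ],
    )


def manhattan(
    markers: "gio.MarkerMap",
    values: np.ndarray,
    path: str | Path,
    ylabel: str = "statistic",
    hlines: list[float] | None = None,
) -> None:
    """Simple Manhattan-style plot of a per-SNP track (convenience only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for k, chrom in enumerate(markers.chromosomes()):
        sl = markers.chrom_slice(int(chrom))
        x = markers.position_bp[sl] + offset
        ax.scatter(x, values[sl], s=3, color="C0" if k % 2 == 0 else "C1")
        ticks.append(offset + markers.position_bp[sl].mean())
        labels.append(str(chrom))
        offset += int(markers.position_bp[sl].max()) + 1
    for y in hlines or []:
        ax.axhline(y, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
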