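"""End-to-end orchestration of the synthetic study.

The default configuration emulates a two-genotype (WT, Cfp1-null) x
two-treatment (untreated, doxorubicin) design: promoter-mark ChIP samples
with an input control (two pooled biological replicates each), stranded
RNA-seq with two replicates per condition and low-abundance divergent
antisense transcription, and qPCR validation panels.  Stages:

    simulate -> filter/merge -> coverage/normalize -> strand split (RNA)
    -> window matrices / median profiles / k-means-ordered heatmaps
    -> densities + rank-sum comparisons -> counting -> differential
    expression -> classification -> top-active ranking -> qPCR arithmetic

Identical config and seed give byte-identical outputs; every output file
embeds the config hash and seed on a comment line.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coverage as cov
from . import metagene as mg
from .annotation import GeneAnnotation, write_gtf
from .expression import (
    build_count_table,
    classify_de,
    estimate_size_factors,
    rank_top_active,
    test_differential,
)
from .quantification import spikein_fold_induction
from .simulate import (
    ChipEnrichmentSpec,
    RnaExpressionSpec,
    SimulationConfig,
    simulate_annotation,
    simulate_chip_fragments,
    simulate_qpcr_panel,
    simulate_rna_fragments,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

GENOTYPES = ["WT", "Cfp1_null"]
TREATMENTS = ["untr", "doxo"]


@dataclass
class PipelineConfig:
    out_dir: str = "anchorprof_out"
    seed: int = 0
    # genome / annotation
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    n_genes: int = 200
    gene_length_range: tuple = (2_000, 8_000)
    intergenic_gap_range: tuple = (1_500, 6_000)
    # study design
    n_induced: int = 40  # genes upregulated by treatment
    n_repressed: int = 25
    induction_fold: float = 6.0
    repression_fold: float = 0.2
    # ChIP model
    chip_fragments: int = 100_000  # per replicate
    chip_replicates: int = 2
    chip_background_rate: float = 0.01
    chip_amplitude_active: float = 8.0  # promoter mark at expressed genes, WT
    chip_amplitude_induced: float = 20.0  # after treatment, WT only
    chip_amplitude_null_factor: float = 0.25  # residual mark without Cfp1
    chip_peak_shape: int = 500
    # RNA model
    rna_fragments: int = 120_000  # per replicate
    rna_replicates: int = 2
    rna_expression_mean: float = 100.0
    antisense_fraction_wt: float = 0.02
    antisense_fraction_null: float = 0.06
    antisense_span: int = 1_000
    fragment_length: int = 200
    # metagene parameters
    flank: int = 3_000
    window: int = 100
    slide: int = 20
    k_clusters: int = 5
    # differential expression filters
    alpha: float = 0.05
    min_fc: float = 2.5
    min_base_mean: float = 200.0
    n_top_active: int = 50
    # stage toggles (an empty assay section in a sample sheet skips it)
    include_chip: bool = True
    include_rna: bool = True
    include_qpcr: bool = True
    # qPCR panel
    qpcr_noise_cv: float = 0.05
    qpcr_replicates: int = 4
    spikein_copies: float = 1_000.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.chrom_sizes = dict(cfg.chrom_sizes)
        cfg.gene_length_range = tuple(cfg.gene_length_range)
        cfg.intergenic_gap_range = tuple(cfg.intergenic_gap_range)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["gene_length_range"] = list(d["gene_length_range"])
        d["intergenic_gap_range"] = list(d["intergenic_gap_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output path is excluded,
        so reruns into different directories stay comparable)."""
        d = asdict(self)
        d.pop("out_dir")
        canon = yaml.safe_dump(d, sort_keys=True, default_flow_style=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _provenance(cfg: PipelineConfig) -> str:
    return f"# anchorprof config_hash={cfg.config_hash()} seed={cfg.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def _sub_seed(cfg: PipelineConfig, *tags: str) -> int:
    h = hashlib.sha256((cfg.config_hash() + ":" + ":".join(tags)).encode()).digest()
    return (int.from_bytes(h[:4], "big") ^ cfg.seed) % (2**31)


def _gene_programs(cfg: PipelineConfig, annotation: GeneAnnotation):
    """Deterministically pick induced and repressed gene sets."""
    rng = np.random.default_rng(_sub_seed(cfg, "programs"))
    ids = np.array(annotation.gene_ids)
    picked = rng.choice(len(ids), size=cfg.n_induced + cfg.n_repressed, replace=False)
    induced = sorted(ids[picked[: cfg.n_induced]])
    repressed = sorted(ids[picked[cfg.n_induced :]])
    return induced, repressed


def _chip_amplitudes(cfg: PipelineConfig, annotation: GeneAnnotation,
                     induced: list[str], genotype: str, treatment: str) -> dict[str, float]:
    """Promoter-mark amplitude per gene: active baseline everywhere, boosted
    at induced genes after treatment in WT; globally damped without Cfp1."""
    amps = {}
    damp = 1.0 if genotype == "WT" else cfg.chip_amplitude_null_factor
    for g in annotation:
        a = cfg.chip_amplitude_active
        if treatment == "doxo" and genotype == "WT" and g.gene_id in induced:
            a = cfg.chip_amplitude_induced
        amps[g.gene_id] = a * damp
    return amps


def _rna_spec(cfg: PipelineConfig, induced: list[str], repressed: list[str],
              genotype: str) -> RnaExpressionSpec:
    anti = cfg.antisense_fraction_wt if genotype == "WT" else cfg.antisense_fraction_null
    fold = {g: cfg.induction_fold for g in induced}
    fold.update({g: cfg.repression_fold for g in repressed})
    return RnaExpressionSpec(
        expression=cfg.rna_expression_mean,
        antisense_fraction_tss=anti,
        antisense_fraction_tes=anti,
        antisense_span=cfg.antisense_span,
        fold_changes={"doxo": fold},
        fragment_length=cfg.fragment_length,
    )


def _qpcr_truth(cfg: PipelineConfig) -> pd.DataFrame:
    """Validation-panel ground truth: an induced target, a repressed target
    and a flat control across the four genotype x treatment samples."""
    samples = [f"{g}_{t}" for g in GENOTYPES for t in TREATMENTS]
    truth = pd.DataFrame(index=["induced_target", "repressed_target", "flat_control"],
                         columns=samples, dtype=float)
    for s in samples:
        treated = s.endswith("doxo")
        truth.at["induced_target", s] = 100.0 * (cfg.induction_fold if treated else 1.0)
        truth.at["repressed_target", s] = 400.0 * (cfg.repression_fold if treated else 1.0)
        truth.at["flat_control", s] = 250.0
    return truth


def _run_chip_stages(cfg: PipelineConfig, annotation: GeneAnnotation,
                     induced: list[str], out: Path, report: dict) -> None:
    chip_tracks: dict[str, cov.CoverageTrack] = {}
    for genotype in GENOTYPES:
        for treatment in TREATMENTS:
            name = f"{genotype}_{treatment}"
            amps = _chip_amplitudes(cfg, annotation, induced, genotype, treatment)
            spec = ChipEnrichmentSpec(
                background_rate=cfg.chip_background_rate,
                peak_amplitude=amps,
                peak_shape=cfg.chip_peak_shape,
                fragment_length=cfg.fragment_length,
            )
            reps = [
                simulate_chip_fragments(
                    annotation, spec, cfg.chip_fragments, _sub_seed(cfg, "chip", name, str(r))
                )
                for r in range(cfg.chip_replicates)
            ]
            merged = cov.merge_replicates(reps, annotation.chrom_sizes)
            merged, filt = cov.filter_fragments(merged)
            track = cov.normalize_track(cov.compute_coverage(merged, annotation.chrom_sizes))
            chip_tracks[name] = track
            cov.write_bedgraph(track, out / "tracks" / f"chip_{name}.bedgraph")
    # input control: amplitude 0 everywhere
    input_spec = ChipEnrichmentSpec(
        background_rate=cfg.chip_background_rate,
        peak_amplitude=0.0,
        peak_shape=cfg.chip_peak_shape,
        fragment_length=cfg.fragment_length,
    )
    input_frags = simulate_chip_fragments(
        annotation, input_spec, cfg.chip_fragments, _sub_seed(cfg, "chip", "input")
    )
    input_frags, _ = cov.filter_fragments(input_frags)
    chip_tracks["input"] = cov.normalize_track(
        cov.compute_coverage(input_frags, annotation.chrom_sizes)
    )
    cov.write_bedgraph(chip_tracks["input"], out / "tracks" / "chip_input.bedgraph")

    # metagene: matrices, profiles, heatmap ordering, densities
    anchors_induced = mg.build_anchors(
        GeneAnnotation([annotation[g] for g in induced], annotation.chrom_sizes),
        "TSS", cfg.flank,
    )
    anchors_all = mg.build_anchors(annotation, "TSS", cfg.flank)
    matrices = {
        name: mg.compute_window_matrix(track, anchors_induced, cfg.window, cfg.slide)
        for name, track in chip_tracks.items()
    }
    reference = matrices["WT_untr"]
    k = min(cfg.k_clusters, reference.values.shape[0])
    order = mg.cluster_and_order(reference, k=k, seed=_sub_seed(cfg, "kmeans"))
    profiles = {}
    for name, m in matrices.items():
        ordered = m.reordered(order)
        _write_tsv(ordered.to_frame(), out / "matrices" / f"chip_{name}.tsv", cfg)
        prof = mg.average_profile(m)
        profiles[name] = prof
    _write_tsv(pd.DataFrame(profiles), out / "profiles" / "chip_profiles.tsv", cfg)

    densities = {
        name: mg.region_density(track, anchors_induced, group=name)
        for name, track in chip_tracks.items()
    }
    dens_frame = pd.concat(densities.values(), ignore_index=True)
    _write_tsv(dens_frame, out / "stats" / "chip_density.tsv", cfg, index=False)
    comparisons = []
    for a, b in [("WT_doxo", "WT_untr"), ("WT_doxo", "Cfp1_null_doxo"),
                 ("Cfp1_null_doxo", "Cfp1_null_untr")]:
        res = mg.compare_density_groups(densities[a], densities[b])
        comparisons.append((a, b, res.n1, res.n2, res.statistic, res.p_value, res.method))
    comp = pd.DataFrame(
        comparisons, columns=["group_a", "group_b", "n_a", "n_b", "U", "p_value", "method"]
    )
    _write_tsv(comp, out / "stats" / "chip_density_tests.tsv", cfg, index=False)
    report["stages"]["chip"] = {
        "n_tracks": len(chip_tracks),
        "n_matrix_columns": int(reference.values.shape[1]),
        "density_tests": comp.to_dict("records"),
    }


def _run_rna_stages(cfg: PipelineConfig, annotation: GeneAnnotation,
                    induced: list[str], repressed: list[str], out: Path,
                    report: dict) -> None:
    anchors_induced = mg.build_anchors(
        GeneAnnotation([annotation[g] for g in induced], annotation.chrom_sizes),
        "TSS", cfg.flank,
    )
    rna_frags: dict[str, pd.DataFrame] = {}
    for genotype in GENOTYPES:
        spec = _rna_spec(cfg, induced, repressed, genotype)
        for treatment in TREATMENTS:
            for r in range(1, cfg.rna_replicates + 1):
                name = f"{genotype}_{treatment}_rep{r}"
                frags = simulate_rna_fragments(
                    annotation, spec, treatment, cfg.rna_fragments,
                    _sub_seed(cfg, "rna", name),
                )
                frags, _ = cov.filter_fragments(frags, remove_duplicates=False)
                rna_frags[name] = frags
    wt_samples = {n: f for n, f in rna_frags.items() if n.startswith("WT")}
    counts = build_count_table(wt_samples, annotation)
    _write_tsv(counts, out / "de" / "counts_WT.tsv", cfg)
    labels = ["untr" if "_untr_" in c else "doxo" for c in counts.columns]
    de = test_differential(counts, labels, baseline="untr")
    de = classify_de(de, cfg.alpha, cfg.min_fc, cfg.min_base_mean)
    _write_tsv(de, out / "de" / "de_WT_doxo_vs_untr.tsv", cfg)

    lengths = pd.Series({g.gene_id: g.exon_union_length for g in annotation})
    sf = estimate_size_factors(counts)
    untr_cols = [c for c in counts.columns if "_untr_" in c]
    baseline_mean = (counts[untr_cols] / sf[untr_cols]).mean(axis=1)
    top = rank_top_active(baseline_mean, lengths, min(cfg.n_top_active, len(lengths)))
    with open(out / "de" / "top_active_genes.txt", "w") as fh:
        fh.write(_provenance(cfg))
        fh.write("\n".join(top) + "\n")

    truth_up = set(induced)
    called_up = set(de.index[de["class"] == "up"])
    report["stages"]["de"] = {
        "n_tested": int(len(de)),
        "n_up": int((de["class"] == "up").sum()),
        "n_down": int((de["class"] == "down").sum()),
        "n_low_expression": int((de["class"] == "low_expression").sum()),
        "sensitivity_up": (len(called_up & truth_up) / len(truth_up)) if truth_up else None,
    }

    # antisense transcription at TSS/TES of induced genes
    anti_tests = []
    strand_density = {}
    for genotype in GENOTYPES:
        treated = [f for n, f in rna_frags.items() if n.startswith(f"{genotype}_doxo")]
        merged = cov.merge_replicates(treated, annotation.chrom_sizes)
        plus, minus = cov.split_by_strand(merged, annotation.chrom_sizes)
        lib = len(merged)
        plus, minus = cov.normalize_track(plus, lib), cov.normalize_track(minus, lib)
        cov.write_bedgraph(plus, out / "tracks" / f"rna_{genotype}_doxo_plus.bedgraph")
        cov.write_bedgraph(minus, out / "tracks" / f"rna_{genotype}_doxo_minus.bedgraph")
        strand_density[genotype] = mg.strand_resolved_density(
            plus, minus, anchors_induced, group=genotype
        )
    both = pd.concat(strand_density.values(), ignore_index=True)
    _write_tsv(both, out / "stats" / "rna_strand_density.tsv", cfg, index=False)
    for strandedness in ("sense", "antisense"):
        a = strand_density["WT"].query("strandedness == @strandedness")
        b = strand_density["Cfp1_null"].query("strandedness == @strandedness")
        res = mg.compare_density_groups(a, b)
        anti_tests.append((strandedness, res.n1, res.n2, res.statistic, res.p_value, res.method))
    anti = pd.DataFrame(anti_tests, columns=["strandedness", "n_a", "n_b", "U", "p_value", "method"])
    _write_tsv(anti, out / "stats" / "rna_antisense_tests.tsv", cfg, index=False)
    report["stages"]["antisense"] = anti.to_dict("records")


def _run_qpcr_stage(cfg: PipelineConfig, out: Path, report: dict) -> None:
    truth = _qpcr_truth(cfg)
    panel = simulate_qpcr_panel(
        truth, {"ERCC-00074": cfg.spikein_copies, "ERCC-00130": cfg.spikein_copies / 4},
        noise_cv=cfg.qpcr_noise_cv, seed=_sub_seed(cfg, "qpcr"),
        n_replicates=cfg.qpcr_replicates,
    )
    _write_tsv(panel, out / "stats" / "qpcr_panel.tsv", cfg, index=False)
    inductions = {
        t: spikein_fold_induction(panel, t, baseline_sample="WT_untr")
        for t in truth.index
    }
    ind = pd.DataFrame(inductions)
    _write_tsv(ind, out / "stats" / "qpcr_fold_induction.tsv", cfg)
    report["stages"]["qpcr"] = {
        "fold_induction_WT_doxo": {t: float(ind.at["WT_doxo", t]) for t in truth.index}
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage on the synthetic design; return a report dict.

    Stage toggles in the config skip whole assays (recorded as skipped in
    the report).  A failing stage aborts with the stage name attached.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    for sub in ("tracks", "matrices", "profiles", "stats", "de", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "report" / "config_used.yaml")
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}

    sim = SimulationConfig(
        chrom_sizes=cfg.chrom_sizes,
        n_genes=cfg.n_genes,
        gene_length_range=cfg.gene_length_range,
        intergenic_gap_range=cfg.intergenic_gap_range,
        seed=_sub_seed(cfg, "annotation"),
    )
    annotation = simulate_annotation(sim)
    write_gtf(annotation, out / "annotation.gtf")
    induced, repressed = _gene_programs(cfg, annotation)
    report["stages"]["simulate"] = {
        "n_genes": len(annotation),
        "n_induced": len(induced),
        "n_repressed": len(repressed),
    }

    stages = [
        ("chip", cfg.include_chip,
         lambda: _run_chip_stages(cfg, annotation, induced, out, report)),
        ("rna", cfg.include_rna,
         lambda: _run_rna_stages(cfg, annotation, induced, repressed, out, report)),
        ("qpcr", cfg.include_qpcr, lambda: _run_qpcr_stage(cfg, out, report)),
    ]
    for name, enabled, fn in stages:
        if not enabled:
            logger.info("stage %s skipped by config", name)
            report["stages"][name] = "skipped"
            continue
        logger.info("stage %s starting (%.1fs elapsed)", name, time.time() - t0)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # the JSON report stays deterministic; runtime goes to the log and the
    # returned dict only
    with open(out / "report" / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["runtime_s"] = round(time.time() - t0, 2)
    logger.info("pipeline finished in %.1fs", report["runtime_s"])
    return report
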