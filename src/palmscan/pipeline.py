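"""End-to-end selection-scan demo: simulate -> filter -> windowed stats ->
outlier intersection -> regions -> gene report.

All inter-stage artifacts are plain text (VCF/TSV/BED/GFF3/JSON) so each
stage can be re-run and inspected independently; outputs are deterministic
given the config seeds.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from palmscan import io_core
from palmscan.io_core import ConfigurationError, make_windows
from palmscan import popgen_stats as ps
from palmscan import selection_scan as scan
from palmscan import synthetic_data as sim

logger = logging.getLogger("palmscan")


@dataclass
class RunConfig:
    out_dir: str
    theta: float = 0.001
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 5_000_000})
    n_anc: int = 20
    n_intro: int = 20
    F: float = 0.05
    sweeps: list = field(default_factory=list)  # sim.SweepRegion
    window_size: int = 100_000
    window_step: int = 50_000
    q: float = 0.05
    max_missing_fraction: float = 1.0
    min_maf: float = 0.0
    genes_per_window: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.q < 1:
            raise ConfigurationError("q must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sweeps = [sim.SweepRegion(**s) for s in raw.pop("sweeps", [])]
        return cls(sweeps=sweeps, **raw)


def run_selection_demo(config: RunConfig) -> dict:
    """Run the full scan on simulated data; returns the manifest dict.

    Writes: genotypes.vcf, diversity TSVs per population, fst.tsv,
    pi_ratio.tsv, regions.bed, genes.tsv, annotation.gff3, manifest.json.
    """
    os.makedirs(config.out_dir, exist_ok=True)

    def path(name):
        return os.path.join(config.out_dir, name)

    stage = "simulate"
    try:
        pop_cfg = sim.PopSimConfig(
            theta=config.theta,
            chrom_lengths=config.chrom_lengths,
            n_anc=config.n_anc,
            n_intro=config.n_intro,
            F=config.F,
            sweeps=tuple(config.sweeps),
            seed=config.seed,
        )
        matrix = sim.simulate_two_pop_genotypes(pop_cfg)
        io_core.write_vcf(matrix, path("genotypes.vcf"))

        win_per_chrom = {
            c: L // config.window_size for c, L in config.chrom_lengths.items()
        }
        ann_cfg = sim.AnnotationSimConfig(
            chrom_lengths=config.chrom_lengths,
            profile_window=config.window_size,
            gene_counts={
                c: [config.genes_per_window] * n for c, n in win_per_chrom.items()
            },
            seed=config.seed + 1,
        )
        annotation = sim.simulate_gene_annotation(ann_cfg)
        io_core.write_gff3(annotation.features, path("annotation.gff3"))

        stage = "filter"
        matrix = ps.filter_variants(
            matrix, config.max_missing_fraction, config.min_maf
        )

        stage = "window_stats"
        windows = make_windows(
            config.chrom_lengths, config.window_size, config.window_step
        )
        anc, intro = pop_cfg.pop_names
        div_anc = ps.window_diversity(matrix, windows, anc)
        div_intro = ps.window_diversity(matrix, windows, intro)
        fst = ps.window_fst(matrix, windows, anc, intro)
        ratio = ps.window_pi_ratio(div_anc, div_intro)
        ps.diversity_to_frame(div_anc).to_csv(
            path(f"diversity_{anc}.tsv"), sep="\t", index=False
        )
        ps.diversity_to_frame(div_intro).to_csv(
            path(f"diversity_{intro}.tsv"), sep="\t", index=False
        )
        ps.fst_to_frame(fst).to_csv(path("fst.tsv"), sep="\t", index=False)
        ratio.to_csv(path("pi_ratio.tsv"), sep="\t", index=False)

        stage = "scan"
        regions, summary = scan.run_scan(
            windows,
            [s.fst for s in fst],
            ratio["pi_ratio"].to_numpy(),
            [s.tajima_d for s in div_intro],
            q=config.q,
            features=annotation.features,
        )
        intervals, extras = scan.regions_to_bed_rows(regions)
        io_core.write_bed(intervals, path("regions.bed"), extras)
        with open(path("genes.tsv"), "w") as fh:
            fh.write("chrom\tstart\tend\ttajima_supported\tgene_id\n")
            for r in regions:
                for g in r.gene_ids:
                    fh.write(
                        f"{r.chrom}\t{r.start}\t{r.end}\t"
                        f"{int(r.tajima_supported)}\t{g}\n"
                    )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    from palmscan import __version__

    cfg = asdict(config)
    cfg["sweeps"] = [asdict(s) for s in config.sweeps]
    manifest = {
        "palmscan_version": __version__,
        "config": cfg,
        "n_sites": int(matrix.n_sites),
        "n_windows": len(windows),
        "summary": {
            k: (int(v) if isinstance(v, (np.integer,)) else v)
            for k, v in summary.items()
        },
    }
    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info(
        "scan complete: %d regions, %d bp, %d genes",
        summary["n_regions"],
        summary["total_length"],
        summary["n_genes"],
    )
    return manifest
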