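"""End-to-end orchestration: files in, per-cell-type and joint calls out."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import ReferencePanel, harmonize, read_gwas, read_weights
from .joint_acat import (
    AcatWeights,
    call_genes,
    call_segments,
    combine_segments,
    significance_threshold,
)
from .ld_reference import segment_ld
from .owas_single import CellTypeSegmentStat, segment_stat
from .segmentation import (
    assign_snps,
    build_regulatory_regions,
    map_segments_to_genes,
    read_tss_gtf,
    read_tss_table,
    tile_segments,
    write_segments_bed,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated inputs and knobs of one pipeline run."""

    gwas: Path
    weights: list[Path]
    annotation: Path
    panel_prefix: Path
    outdir: Path
    cell_types: list[str] | None = None
    window: int = 100_000
    segment_mode: str = "by_length"
    segment_value: int = 5000
    min_snps: int = 1
    eta: list[float] | None = None
    alpha: float = 0.05
    r2_threshold: float = 0.99
    gwas_columns: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            gwas=Path(raw["gwas"]),
            weights=[Path(p) for p in raw["weights"]],
            annotation=Path(raw["annotation"]),
            panel_prefix=Path(raw["panel_prefix"]),
            outdir=Path(raw.get("outdir", "owasjoint_out")),
            cell_types=raw.get("cell_types"),
            window=int(raw.get("window", 100_000)),
            segment_mode=raw.get("segment_mode", "by_length"),
            segment_value=int(raw.get("segment_value", 5000)),
            min_snps=int(raw.get("min_snps", 1)),
            eta=raw.get("eta"),
            alpha=float(raw.get("alpha", 0.05)),
            r2_threshold=float(raw.get("r2_threshold", 0.99)),
            gwas_columns=raw.get("gwas_columns", {}),
            seed=int(raw.get("seed", 0)),
        )

    def validate(self) -> None:
        for p in [self.gwas, self.annotation, *self.weights]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for suffix in (".bed", ".bim", ".fam"):
            if not Path(self.panel_prefix).with_suffix(suffix).exists():
                raise FileNotFoundError(f"{self.panel_prefix}{suffix}")
        if self.eta is not None and len(self.eta) != len(self.weights):
            raise ValueError("eta length must equal the number of weight files")


def run_pipeline(config: RunConfig) -> dict:
    """data_io -> segmentation -> LD -> per-cell-type test -> joint call.

    Writes per-cell-type TSVs, the joint TSV, the gene TSV, a BED of
    segments, and a JSON run manifest into ``config.outdir``.  Returns the
    manifest dict.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cell_types = config.cell_types or [Path(p).stem for p in config.weights]
    gwas = read_gwas(config.gwas, config.gwas_columns)
    weights = [read_weights(p, ct) for p, ct in zip(config.weights, cell_types)]
    panel = ReferencePanel.from_plink(config.panel_prefix)
    variants = harmonize(gwas, weights, panel)

    ann = Path(config.annotation)
    genes = read_tss_gtf(ann) if ann.suffix.lower() == ".gtf" else read_tss_table(ann)
    regions = build_regulatory_regions(genes, config.window)
    segments = tile_segments(regions, config.segment_mode, config.segment_value, variants)
    segments = assign_snps(segments, variants, min_snps=config.min_snps)
    write_segments_bed(segments, outdir / "segments.bed")

    z = np.array([v.z for v in variants])
    sd = np.array([v.sd_ref for v in variants])
    w_all = np.array([v.w_by_cell_type for v in variants])  # n_var x L
    logp_priority = np.abs(z)
    seg_meta = []
    per_ct: dict[str, list[CellTypeSegmentStat]] = {ct: [] for ct in cell_types}
    for seg in segments:
        idx = seg.snp_indices
        geno = panel.dosages([variants[i].panel_index for i in idx])
        ld = segment_ld(geno, priority=logp_priority[idx], r2_threshold=config.r2_threshold)
        kept = idx[ld.kept_snp_indices]
        for l, ct in enumerate(cell_types):
            per_ct[ct].append(
                segment_stat(
                    z[kept], w_all[kept, l], sd[kept], ld,
                    segment_id=seg.segment_id, cell_type=ct,
                )
            )
        seg_meta.append((seg.segment_id, seg.chrom, seg.start, seg.end, len(kept)))

    meta = pd.DataFrame(seg_meta, columns=["segment_id", "chrom", "start", "end", "n_snps_used"])
    for ct in cell_types:
        df = meta.copy()
        df["Z"] = [s.Z_s for s in per_ct[ct]]
        df["P"] = [s.p for s in per_ct[ct]]
        df.to_csv(outdir / f"owas_{ct}.tsv", sep="\t", index=False)

    eta = AcatWeights(config.eta) if config.eta else AcatWeights.uniform(len(cell_types))
    joint = combine_segments(per_ct, eta)
    n_testable = sum(r.testable for r in joint)
    threshold = significance_threshold(config.alpha, max(n_testable, 1))
    joint = call_segments(joint, threshold)

    jdf = meta.copy()
    for l, ct in enumerate(cell_types):
        jdf[f"p_{ct}"] = [r.p_by_cell_type[l] for r in joint]
    jdf["T"] = [r.T_s for r in joint]
    jdf["P_JOINT"] = [r.p_joint for r in joint]
    jdf["SIGNIFICANT"] = [r.significant for r in joint]
    jdf.to_csv(outdir / "joint.tsv", sep="\t", index=False)

    gene_map = map_segments_to_genes(segments, genes, config.window)
    gene_df = call_genes(joint, gene_map)
    gene_df.to_csv(outdir / "genes.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "threshold": threshold,
        "eta": list(eta.eta),
        "cell_types": cell_types,
        "counts": {
            "gwas_records": len(gwas),
            "harmonized_variants": len(variants),
            "genes": len(genes),
            "segments_tested": len(segments),
            "segments_testable": n_testable,
            "segments_significant": int(sum(r.significant for r in joint)),
            "genes_significant": int(gene_df["significant"].sum()) if len(gene_df) else 0,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", manifest["counts"])
    return manifest
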