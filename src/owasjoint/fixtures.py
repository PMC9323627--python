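"""Synthetic toy dataset emitter (all inputs the pipeline consumes).

Writes a small, fully synthetic GWAS + weights + TSS + PLINK panel bundle
for smoke tests and examples; every file is derived from the simulation
generator, nothing is sampled from real cohorts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import write_plink
from .simulation import marginal_gwas, simulate_genotype_block, simulate_weights

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "C"), ("T", "G")]  # unambiguous


def make_fixtures(
    outdir: str | Path,
    seed: int = 0,
    n_variants: int = 200,
    n_ref: int = 400,
    n_cohort: int = 2000,
    cell_types: tuple[str, ...] = ("ct1", "ct2", "ct3"),
) -> dict[str, Path]:
    """Emit a toy dataset: GWAS TSV, one weight TSV per cell type, a TSS
    table, a PLINK panel, and a ready-to-run config.yaml.

    The phenotype behind the GWAS z-scores is openness-mediated through
    the first cell type's weights in the first gene's window, so the toy
    run produces real signal.  Returns the paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # two gene TSSs on chr1; variants scattered across both windows
    tss = [150_000, 320_000]
    genes = pd.DataFrame(
        {"chrom": "1", "tss": tss, "strand": ["+", "-"], "gene": ["GENE1", "GENE2"]}
    )
    pos = np.sort(rng.choice(np.arange(60_000, 420_000), size=n_variants, replace=False))
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_variants)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i+1}" for i in range(n_variants)],
            "chrom": "1",
            "pos": pos,
            "a1": a1,
            "a2": a2,
        }
    )

    mafs = rng.uniform(0.1, 0.5, size=n_variants)
    cohort = simulate_genotype_block(n_cohort, n_variants, mafs, ld_rho=0.4, rng=rng)
    panel_geno = simulate_genotype_block(n_ref, n_variants, mafs, ld_rho=0.4, rng=rng)
    W = simulate_weights(n_variants, len(cell_types), sparsity=1.0, cross_ct_rho=0.5, rng=rng)

    causal = (pos > tss[0] - 20_000) & (pos < tss[0] + 20_000)
    g = cohort[:, causal] @ W[0, causal]
    g = (g - g.mean()) / (g.std() + 1e-12)
    y = 0.25 * g + rng.standard_normal(n_cohort)
    z = marginal_gwas(y, cohort)

    paths: dict[str, Path] = {}
    gwas = pd.DataFrame(
        {
            "SNP": variants["variant_id"],
            "CHR": variants["chrom"],
            "BP": variants["pos"],
            "A1": variants["a1"],
            "A2": variants["a2"],
            "Z": np.round(z, 6),
            "N": n_cohort,
        }
    )
    paths["gwas"] = outdir / "gwas.tsv"
    gwas.to_csv(paths["gwas"], sep="\t", index=False)

    for l, ct in enumerate(cell_types):
        wdf = pd.DataFrame(
            {
                "CHR": variants["chrom"],
                "BP": variants["pos"],
                "A1": variants["a1"],
                "A2": variants["a2"],
                "W": np.round(W[l], 6),
            }
        )
        paths[f"weights_{ct}"] = outdir / f"{ct}.tsv"
        wdf.to_csv(paths[f"weights_{ct}"], sep="\t", index=False)

    paths["annotation"] = outdir / "tss.tsv"
    genes.to_csv(paths["annotation"], sep="\t", index=False, header=False)

    paths["panel_prefix"] = outdir / "panel"
    write_plink(paths["panel_prefix"], variants, panel_geno)

    config = {
        "gwas": str(paths["gwas"]),
        "weights": [str(paths[f"weights_{ct}"]) for ct in cell_types],
        "cell_types": list(cell_types),
        "annotation": str(paths["annotation"]),
        "panel_prefix": str(paths["panel_prefix"]),
        "outdir": str(outdir / "results"),
        "window": 100_000,
        "segment_mode": "by_length",
        "segment_value": 5000,
        "seed": seed,
    }
    paths["config"] = outdir / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths
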