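"""Reading and harmonization of GWAS summary statistics, openness weights,
and LD reference genotypes.

All on-disk coordinates are 1-based inclusive (BIM/GWAS convention).  The
harmonized variant table aligns three sources on a shared allele coding:

* GWAS summary statistics give a signed per-SNP z-score ``z_j`` toward an
  effect allele;
* one openness-weight table per cell type gives the predicted effect
  ``w_j`` of that same allele substitution on chromatin accessibility;
* a PLINK reference panel supplies genotype dosages from which per-SNP
  standard deviations and per-segment LD are estimated.

The panel's counted allele (BIM A1) is the master coding: z and every w
are sign-flipped when their effect allele is the panel's other allele,
and variants whose alleles cannot be reconciled (or are strand-ambiguous
A/T, C/G) are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

#: default column names for GWAS summary-statistics files
DEFAULT_GWAS_COLUMNS = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "z": "Z",
    "beta": "BETA",
    "se": "SE",
    "n": "N",
}

#: default column names for openness-weight files
DEFAULT_WEIGHT_COLUMNS = {
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "w": "W",
}


class ConfigurationError(ValueError):
    """A required column or input is missing or malformed."""


class HarmonizationError(ValueError):
    """The inputs share no usable variants."""


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's marginal GWAS result, z signed toward ``effect_allele``."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    z: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: identical alleles")
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: alleles must be in A/C/G/T")
        if not np.isfinite(self.z):
            raise ValueError(f"{self.variant_id}: non-finite z")

    @property
    def is_strand_ambiguous(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in _AMBIGUOUS_PAIRS


@dataclass
class OpennessWeightTable:
    """Per-SNP predicted openness effects (deltaSVM-style) for one cell type.

    Keys are ``(chrom, pos, effect_allele, other_allele)``; the weight is
    signed toward the effect allele.
    """

    cell_type: str
    entries: dict[tuple[str, int, str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, chrom: str, pos: int, a1: str, a2: str) -> float | None:
        """Weight for counted allele ``a1``, flipping sign if the table is
        keyed on the opposite orientation. None if absent."""
        w = self.entries.get((chrom, pos, a1, a2))
        if w is not None:
            return w
        w = self.entries.get((chrom, pos, a2, a1))
        if w is not None:
            return -w
        return None


def read_gwas(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[GwasRecord]:
    """Read a delimited GWAS summary-statistics file.

    Either a z column or beta+se columns must exist; with beta+se,
    z = beta / se.  Rows with unparseable numerics are dropped with a
    warning; a missing mandatory column raises :class:`ConfigurationError`.
    """
    cols = dict(DEFAULT_GWAS_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    for key in ("variant_id", "chrom", "pos", "effect_allele", "other_allele"):
        if cols[key] not in df.columns:
            raise ConfigurationError(f"GWAS file missing column {cols[key]!r} ({key})")
    has_z = cols["z"] in df.columns
    has_beta = cols["beta"] in df.columns and cols["se"] in df.columns
    if not (has_z or has_beta):
        raise ConfigurationError(
            f"GWAS file needs either {cols['z']!r} or {cols['beta']!r}+{cols['se']!r}"
        )

    records: list[GwasRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        try:
            if has_z:  # z column wins over beta/se when both present
                z = float(row[cols["z"]])
            else:
                se = float(row[cols["se"]])
                z = float(row[cols["beta"]]) / se
            n_val: int | None = None
            if cols["n"] in df.columns and not pd.isna(row[cols["n"]]):
                n_val = int(float(row[cols["n"]]))
            rec = GwasRecord(
                variant_id=str(row[cols["variant_id"]]),
                chrom=str(row[cols["chrom"]]),
                pos=int(float(row[cols["pos"]])),
                effect_allele=str(row[cols["effect_allele"]]).upper(),
                other_allele=str(row[cols["other_allele"]]).upper(),
                z=z,
                n=n_val,
            )
        except (ValueError, ZeroDivisionError) as exc:
            n_dropped += 1
            logger.warning("dropping GWAS row: %s", exc)
            continue
        records.append(rec)
    logger.info("read %d GWAS records from %s (%d dropped)", len(records), path, n_dropped)
    return records


def read_weights(
    path: str | Path,
    cell_type: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> OpennessWeightTable:
    """Read one cell type's openness-weight table.

    Duplicate variant keys keep the first occurrence (with a warning);
    an empty file is an error.
    """
    cols = dict(DEFAULT_WEIGHT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if cell_type is None:
        cell_type = Path(path).stem
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.empty:
        raise ConfigurationError(f"empty weight file: {path}")
    for key, col in cols.items():
        if col not in df.columns:
            raise ConfigurationError(f"weight file missing column {col!r} ({key})")
    table = OpennessWeightTable(cell_type=cell_type)
    n_dup = 0
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        key = (
            str(row[cols["chrom"]]),
            int(float(row[cols["pos"]])),
            str(row[cols["effect_allele"]]).upper(),
            str(row[cols["other_allele"]]).upper(),
        )
        if key in table.entries:
            n_dup += 1
            continue
        table.entries[key] = float(row[cols["w"]])
    if n_dup:
        logger.warning("%d duplicate weight keys in %s; kept first", n_dup, path)
    return table


# ---------------------------------------------------------------------------
# PLINK 1 reference panel
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# 2-bit PLINK codes -> dosage of the BIM A1 allele; 1 (=0b01) is missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class ReferencePanel:
    """LD reference genotypes with a variant index and a dosage accessor.

    Dosages count copies of the panel's A1 allele; missing genotypes are
    imputed to the per-variant mean so the covariance stays well defined.
    """

    def __init__(self, variants: pd.DataFrame, dosage_matrix: np.ndarray):
        # variants: columns variant_id, chrom, pos, a1, a2 (row i <-> column i)
        if len(variants) != dosage_matrix.shape[1]:
            raise ValueError("variant table and dosage matrix disagree on m")
        self.variants = variants.reset_index(drop=True)
        self._dosages = np.asarray(dosage_matrix, dtype=float)
        self.n_samples = self._dosages.shape[0]
        # mean-impute missing once, up front
        if np.isnan(self._dosages).any():
            col_mean = np.nanmean(self._dosages, axis=0)
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            idx = np.where(np.isnan(self._dosages))
            self._dosages[idx] = col_mean[idx[1]]
        self._sd = self._dosages.std(axis=0, ddof=1)

    @classmethod
    def from_plink(cls, prefix: str | Path) -> "ReferencePanel":
        """Read a PLINK 1 bed/bim/fam triple (SNP-major .bed)."""
        prefix = Path(prefix)
        bim = pd.read_csv(
            prefix.with_suffix(".bim"),
            sep=r"\s+",
            header=None,
            names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
            dtype={"chrom": str, "variant_id": str, "a1": str, "a2": str},
        )
        fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
        n, m = len(fam), len(bim)
        raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
        if raw[:3].tobytes() != _BED_MAGIC:
            raise ConfigurationError(f"{prefix}.bed is not a SNP-major PLINK 1 file")
        bytes_per_snp = (n + 3) // 4
        body = raw[3:].reshape(m, bytes_per_snp)
        # unpack the four 2-bit genotypes per byte
        codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
        codes = codes.reshape(m, -1)[:, :n]  # trim pad samples
        dosages = _CODE_TO_DOSAGE[codes].T  # n x m
        variants = bim[["variant_id", "chrom", "pos", "a1", "a2"]].copy()
        variants["pos"] = variants["pos"].astype(int)
        return cls(variants, dosages)

    def dosages(self, indices: Sequence[int]) -> np.ndarray:
        """n_ref x m dosage matrix for the given variant rows."""
        return self._dosages[:, np.asarray(indices, dtype=int)]

    def sd(self, indices: Sequence[int]) -> np.ndarray:
        """Sample SD of the dosage columns (sigma_hat_j)."""
        return self._sd[np.asarray(indices, dtype=int)]

    @property
    def monomorphic(self) -> np.ndarray:
        """Boolean flag per variant: zero dosage variance in the panel."""
        return self._sd == 0.0


def write_plink(
    prefix: str | Path,
    variants: pd.DataFrame,
    dosages: np.ndarray,
) -> None:
    """Write integer dosages (count of A1) as a PLINK 1 bed/bim/fam triple.

    Inverse of :meth:`ReferencePanel.from_plink`; used by the fixture
    generator and tests.  NaN encodes a missing genotype.
    """
    prefix = Path(prefix)
    n, m = dosages.shape
    bim = pd.DataFrame(
        {
            "chrom": variants["chrom"],
            "variant_id": variants["variant_id"],
            "cm": 0,
            "pos": variants["pos"],
            "a1": variants["a1"],
            "a2": variants["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    dosage_to_code = {2.0: 0, 1.0: 2, 0.0: 3}
    codes = np.full((m, n), 1, dtype=np.uint8)  # 1 = missing
    for dose, code in dosage_to_code.items():
        codes[(dosages.T == dose)] = code
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    packed = codes[:, 0::4] | (codes[:, 1::4] << 2) | (codes[:, 2::4] << 4) | (codes[:, 3::4] << 6)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonizedVariant:
    """The join of one SNP's z, per-cell-type weights, and panel SD, all
    signed toward the panel's counted allele."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    z: float
    w_by_cell_type: tuple[float, ...]
    sd_ref: float
    panel_index: int
    n: int | None = None


def harmonize(
    gwas: Sequence[GwasRecord],
    weights: Sequence[OpennessWeightTable],
    panel: ReferencePanel,
    drop_ambiguous: bool = True,
) -> list[HarmonizedVariant]:
    """Intersect GWAS, all weight tables, and the panel on a shared coding.

    The output is sorted by (chrom, pos).  z and w are flipped when their
    effect allele is the panel A2; variants with irreconcilable alleles,
    strand-ambiguous pairs (by default), or zero panel variance are dropped.
    Raises :class:`HarmonizationError` on an empty intersection.
    """
    panel_key: dict[tuple[str, int], int] = {
        (str(c), int(p)): i
        for i, (c, p) in enumerate(zip(panel.variants["chrom"], panel.variants["pos"]))
    }
    a1 = panel.variants["a1"].to_numpy()
    a2 = panel.variants["a2"].to_numpy()
    mono = panel.monomorphic

    out: list[HarmonizedVariant] = []
    seen: set[tuple[str, int]] = set()
    counts = {"ambiguous": 0, "no_panel": 0, "allele_mismatch": 0, "no_weight": 0, "monomorphic": 0}
    for rec in gwas:
        key = (rec.chrom, rec.pos)
        if key in seen:
            continue
        if drop_ambiguous and rec.is_strand_ambiguous:
            counts["ambiguous"] += 1
            continue
        idx = panel_key.get(key)
        if idx is None:
            counts["no_panel"] += 1
            continue
        if (rec.effect_allele, rec.other_allele) == (a1[idx], a2[idx]):
            z = rec.z
        elif (rec.effect_allele, rec.other_allele) == (a2[idx], a1[idx]):
            z = -rec.z
        else:
            counts["allele_mismatch"] += 1
            continue
        if mono[idx]:
            counts["monomorphic"] += 1
            continue
        ws = []
        for table in weights:
            w = table.lookup(rec.chrom, rec.pos, a1[idx], a2[idx])
            if w is None:
                break
            ws.append(w)
        if len(ws) < len(weights):
            counts["no_weight"] += 1
            continue
        seen.add(key)
        out.append(
            HarmonizedVariant(
                variant_id=rec.variant_id,
                chrom=rec.chrom,
                pos=rec.pos,
                effect_allele=str(a1[idx]),
                other_allele=str(a2[idx]),
                z=z,
                w_by_cell_type=tuple(ws),
                sd_ref=float(panel.sd([idx])[0]),
                panel_index=idx,
                n=rec.n,
            )
        )
    if not out:
        raise HarmonizationError(
            f"no variants shared by GWAS ({len(gwas)}), weights, and panel "
            f"({panel.variants.shape[0]}); drop counts: {counts}"
        )
    out.sort(key=lambda v: (v.chrom, v.pos))
    logger.info("harmonized %d variants; drop counts: %s", len(out), counts)
    return out


def harmonized_frame(variants: Sequence[HarmonizedVariant], cell_types: Sequence[str]) -> pd.DataFrame:
    """Tabular view of harmonized variants (one w_<cell_type> column each)."""
    df = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "effect_allele": [v.effect_allele for v in variants],
            "other_allele": [v.other_allele for v in variants],
            "z": [v.z for v in variants],
            "sd_ref": [v.sd_ref for v in variants],
            "panel_index": [v.panel_index for v in variants],
        }
    )
    for l, ct in enumerate(cell_types):
        df[f"w_{ct}"] = [v.w_by_cell_type[l] for v in variants]
    return df
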