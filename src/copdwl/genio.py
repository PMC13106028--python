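"""Genotype, gene-mask and results I/O plus per-variant allele statistics.

Dosages are stored as a variants × participants float matrix with ``nan``
marking missing genotypes. Alternate-allele fraction (AAF) and minor-allele
count (MAC) are computed over non-missing genotypes only. Positions follow
the hg38 1-based convention; variant ids are the canonical
``chrom:pos:ref:alt`` join.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int
    ref: str
    alt: str
    multiallelic: bool = False   # split from a multi-ALT record at this position

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def allele_pair(self) -> tuple[str, str]:
        """Unordered allele pair, for orientation-free matching."""
        return tuple(sorted((self.ref, self.alt)))


@dataclass
class GenotypeBlock:
    """Biallelic dosage matrix (variants × participants) with allele stats."""

    variants: list[Variant]
    participants: list[str]
    dosage: np.ndarray               # float, {0,1,2,nan}
    aaf: Optional[np.ndarray] = None
    mac: Optional[np.ndarray] = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.variants), len(self.participants)):
            raise ValueError("dosage shape does not match variants × participants")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def variant_index(self) -> dict[str, int]:
        return {v.id: i for i, v in enumerate(self.variants)}

    def subset_participants(self, idx: Sequence[int]) -> "GenotypeBlock":
        idx = list(idx)
        return GenotypeBlock(
            variants=list(self.variants),
            participants=[self.participants[i] for i in idx],
            dosage=self.dosage[:, idx].copy())

    def subset_variants(self, idx: Sequence[int]) -> "GenotypeBlock":
        idx = list(idx)
        return GenotypeBlock(
            variants=[self.variants[i] for i in idx],
            participants=list(self.participants),
            dosage=self.dosage[idx, :].copy(),
            aaf=None if self.aaf is None else self.aaf[idx].copy(),
            mac=None if self.mac is None else self.mac[idx].copy(),
        )


@dataclass
class GeneMask:
    """Variants assigned to one gene for aggregate rare-variant testing."""

    gene: str
    members: list[str]
    gene_id: Optional[str] = None
    annotation: str = "LoF_plus"     # LoF | LoF_plus
    unmatched: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# allele statistics and filters
# ---------------------------------------------------------------------------

def compute_allele_stats(block: GenotypeBlock) -> GenotypeBlock:
    """Fill per-variant AAF and MAC from the dosage matrix.

    ``aaf = sum(dosage) / (2 * n_nonmissing)``;
    ``mac = min(alt count, 2*n_nonmissing - alt count)``.
    Variants with all genotypes missing get ``aaf = nan`` and ``mac = 0``
    and a warning is emitted.
    """
    d = block.dosage
    nonmiss = ~np.isnan(d)
    n2 = 2 * nonmiss.sum(axis=1).astype(float)
    alt = np.nansum(d, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        aaf = np.where(n2 > 0, alt / n2, np.nan)
    mac = np.where(n2 > 0, np.minimum(alt, n2 - alt), 0.0)
    if np.any(n2 == 0):
        warnings.warn(f"{int((n2 == 0).sum())} variant(s) with all genotypes "
                      "missing: AAF undefined", stacklevel=2)
    block.aaf = aaf
    block.mac = mac
    return block


def filter_by_mac(block: GenotypeBlock, mac_min: float) -> GenotypeBlock:
    """Retain variants with MAC strictly greater than ``mac_min``."""
    if block.mac is None:
        raise ValueError("allele stats not computed; call compute_allele_stats first")
    keep = np.where(block.mac > mac_min)[0]
    return block.subset_variants(keep)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeBlock:
    """Read a VCF 4.x into a GenotypeBlock (GT field only).

    Multiallelic records are split into biallelic variants that keep a
    shared-position flag, consumed downstream by the meta-analysis
    multivalent-removal rule. Genotypes with any missing allele become
    missing dosages.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    participants = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    for idx, rec in enumerate(vcf):
        alts = rec.ALT
        if not alts:
            continue
        multi = len(alts) > 1
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=float)
        missing = np.any(alleles < 0, axis=1)
        for k, alt in enumerate(alts):
            try:
                var = Variant(chrom=str(rec.CHROM), pos=int(rec.POS),
                              ref=str(rec.REF), alt=str(alt), multiallelic=multi)
            except ValueError as exc:
                raise ValueError(f"malformed VCF record #{idx + 1} "
                                 f"({rec.CHROM}:{rec.POS}): {exc}") from exc
            dose = (alleles == (k + 1)).sum(axis=1).astype(float)
            dose[missing] = np.nan
            variants.append(var)
            rows.append(dose)
    vcf.close()
    dosage = (np.vstack(rows) if rows
              else np.empty((0, len(participants))))
    return GenotypeBlock(variants=variants, participants=participants,
                         dosage=dosage)


def write_vcf(block: GenotypeBlock, path: str | Path) -> Path:
    """Write a minimal VCF 4.2 (GT only) readable by standard tooling."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({v.chrom for v in block.variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(block.participants) + "\n")
        order = sorted(range(block.n_variants),
                       key=lambda i: (block.variants[i].chrom, block.variants[i].pos,
                                      block.variants[i].alt))
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i in order:
            v = block.variants[i]
            gts = "\t".join("./." if np.isnan(d) else gt_map[d]
                            for d in block.dosage[i])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")
    return path


# ---------------------------------------------------------------------------
# dosage TSV fallback
# ---------------------------------------------------------------------------

def write_dosage_tsv(block: GenotypeBlock, path: str | Path) -> Path:
    df = pd.DataFrame(block.dosage,
                      index=[v.id for v in block.variants],
                      columns=block.participants)
    df.index.name = "variant_id"
    df.to_csv(path, sep="\t")
    return Path(path)


def read_dosage_tsv(path: str | Path) -> GenotypeBlock:
    df = pd.read_csv(path, sep="\t", index_col=0)
    variants = []
    for vid in df.index:
        chrom, pos, ref, alt = str(vid).split(":")
        variants.append(Variant(chrom=chrom, pos=int(pos), ref=ref, alt=alt))
    return GenotypeBlock(variants=variants, participants=list(df.columns),
                         dosage=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# gene group files
# ---------------------------------------------------------------------------

def read_group_file(path: str | Path,
                    block: Optional[GenotypeBlock] = None) -> list[GeneMask]:
    """Read a gene group file: one gene per line, ``GENE vid1 vid2 ...``.

    Duplicate gene lines raise with the offending line number. When a
    GenotypeBlock is supplied, member ids that do not resolve against it
    are recorded on the mask's ``unmatched`` list.
    """
    masks: list[GeneMask] = []
    seen: dict[str, int] = {}
    index = block.variant_index() if block is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            gene, members = tokens[0], tokens[1:]
            if gene in seen:
                raise ValueError(f"duplicate gene {gene!r} at line {lineno} "
                                 f"(first seen at line {seen[gene]})")
            seen[gene] = lineno
            mask = GeneMask(gene=gene, members=members)
            if index is not None:
                mask.unmatched = [m for m in members if m not in index]
                if mask.unmatched:
                    warnings.warn(f"gene {gene}: {len(mask.unmatched)} member "
                                  "id(s) not found in genotype block",
                                  stacklevel=2)
            masks.append(mask)
    return masks


def write_group_file(masks: Sequence[GeneMask], path: str | Path) -> Path:
    with open(path, "w") as fh:
        for mask in masks:
            fh.write(" ".join([mask.gene, *mask.members]) + "\n")
    return Path(path)
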