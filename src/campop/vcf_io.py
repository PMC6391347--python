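"""VCF ingestion and the panel-level site filters.

Reads multi-sample VCFs (via cyvcf2) into the :class:`GenotypeMatrix` /
:class:`VariantTable` data model and applies the standard post-calling
filters for a GBS diversity panel: strictly biallelic SNPs, a minimum
per-site call rate, and a minimum minor allele frequency.

Call-rate semantics: ``min_call_rate`` is the minimum fraction of
non-missing genotype calls a site must have. The widely used vcftools flag
``--max-missing`` is, despite its name, also a minimum call-rate fraction
(``--max-missing 0.2`` keeps sites with call rate ≥ 0.2, i.e. up to 80%
missing). A stated intent of "at most 20% missing data" therefore
corresponds to ``min_call_rate = 0.8``, which is the default here; either
behavior is reachable by configuration.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, VariantTable
from .divstats import minor_allele_frequency


@dataclass
class FilterReport:
    """Site counts surviving each filtering stage (non-increasing)."""

    n_input: int
    n_after_biallelic: int
    n_after_missing: int
    n_after_maf: int

    def __post_init__(self) -> None:
        stages = (
            self.n_input,
            self.n_after_biallelic,
            self.n_after_missing,
            self.n_after_maf,
        )
        if any(a < b for a, b in zip(stages, stages[1:])):
            raise ValueError("stage counts must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "biallelic_snp", "call_rate", "maf"],
                "n_sites": [
                    self.n_input,
                    self.n_after_biallelic,
                    self.n_after_missing,
                    self.n_after_maf,
                ],
            }
        )


def read_vcf(path: str | os.PathLike) -> tuple[GenotypeMatrix, VariantTable]:
    """Read a multi-sample VCF into dosages and a variant table.

    GT fields are mapped to ALT-allele dosage; half-calls and non-diploid
    genotypes become :data:`MISSING`. Multi-allelic records are retained
    (alt alleles comma-joined) so the biallelic filter can drop them; their
    genotypes involving allele indices above 1 are recorded as missing.
    Phase is ignored.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        reader = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions for bad headers
        raise ValueError(f"malformed VCF {path!r}: {exc}") from exc

    samples = list(reader.samples)
    dosage_cols: list[np.ndarray] = []
    rows = []
    ids = []
    try:
        for rec_no, var in enumerate(reader, start=1):
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for i, gt in enumerate(var.genotypes):
                alleles = [a for a in gt[:-1]]  # last entry is the phase flag
                if len(alleles) != 2 or any(a is None or a < 0 for a in alleles):
                    continue  # half-call or non-diploid -> missing
                if any(a > 1 for a in alleles):
                    continue  # beyond first ALT; only meaningful pre-filter
                col[i] = alleles[0] + alleles[1]
            dosage_cols.append(col)
            alt = ",".join(var.ALT) if var.ALT else "."
            rows.append((var.CHROM, var.POS, var.REF, alt))
            ids.append(var.ID if var.ID not in (None, ".") else f"rec{rec_no}")
    except Exception as exc:
        raise ValueError(
            f"malformed VCF {path!r} at record {len(rows) + 1}: {exc}"
        ) from exc

    if not rows:
        raise ValueError(f"VCF {path!r} contains no variant records")
    dosages = np.column_stack(dosage_cols)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    df.index = pd.Index(ids, name="locus")
    return GenotypeMatrix(dosages, samples, ids), VariantTable(df)


def filter_sites(
    genotypes: GenotypeMatrix,
    variants: VariantTable,
    min_call_rate: float = 0.8,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, VariantTable, FilterReport]:
    """Keep biallelic SNPs passing call-rate and MAF thresholds.

    Stages, in order: (1) strictly biallelic SNPs (single-nucleotide ref and
    alt); (2) call rate ≥ ``min_call_rate``; (3) MAF ≥ ``min_maf``, computed
    from called alleles with the same estimator as
    :func:`campop.divstats.minor_allele_frequency`. Both thresholds are
    inclusive. Site order is preserved; filtering is idempotent.
    """
    if not 0.0 <= min_call_rate <= 1.0:
        raise ValueError("min_call_rate must be in [0, 1]")
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")

    n_input = genotypes.n_loci
    snp_mask = variants.is_snp()
    n_biallelic = int(snp_mask.sum())

    call_rate = genotypes.called.mean(axis=0)
    cr_mask = snp_mask & (call_rate >= min_call_rate)
    n_missing = int(cr_mask.sum())

    maf_mask = cr_mask.copy()
    for j in np.flatnonzero(cr_mask):
        col = genotypes.dosages[:, j]
        if not (col != MISSING).any():
            maf_mask[j] = False
            continue
        maf_mask[j] = minor_allele_frequency(col) >= min_maf
    n_maf = int(maf_mask.sum())

    if n_maf == 0:
        warnings.warn("all sites removed by filtering", stacklevel=2)
    report = FilterReport(n_input, n_biallelic, n_missing, n_maf)
    return genotypes.take_loci(maf_mask), variants.take(maf_mask), report


def write_hapmap(
    genotypes: GenotypeMatrix,
    variants: VariantTable,
    path: str | os.PathLike,
) -> None:
    """Export a biallelic panel in HapMap format (tab-delimited).

    One row per site with an ``alleles`` column (ref/alt) and IUPAC-free
    two-letter genotype codes (``NN`` for missing).
    """
    snp = variants.is_snp()
    if not snp.all():
        raise ValueError("HapMap export requires strictly biallelic SNPs")
    header = [
        "rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
        "protLSID", "assayLSID", "panelLSID", "QCcode",
    ] + genotypes.sample_ids
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for j, (locus, row) in enumerate(variants.df.iterrows()):
            ref, alt = row["ref"], row["alt"]
            code = {0: ref + ref, 1: ref + alt, 2: alt + alt, MISSING: "NN"}
            calls = [code[int(d)] for d in genotypes.dosages[:, j]]
            fields = [
                str(locus), f"{ref}/{alt}", str(row["chrom"]), str(row["pos"]),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ] + calls
            fh.write("\t".join(fields) + "\n")
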