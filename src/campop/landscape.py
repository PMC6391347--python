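"""SNP landscape summaries: genomic distribution and substitution spectrum.

Characterizes a filtered SNP panel by chromosome (counts, spans, marker
density) and by substitution class (the six unordered nucleotide pairs,
transition/transversion totals and their ratio).

The module also ships the published chromosome-level summary and substitution
counts of a 6,192-SNP *Camelina sativa* GBS panel (20 chromosomes, 213 spring
accessions) as reference inputs for arithmetic checks and as default
chromosome lengths for the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import VALID_NUCLEOTIDES, VariantTable

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: The two transition pairs and four transversion pairs, as canonical
#: orientation-independent labels.
TRANSITION_PAIRS = ("A/G", "C/T")
TRANSVERSION_PAIRS = ("A/T", "A/C", "G/T", "G/C")
PAIR_LABELS = TRANSITION_PAIRS + TRANSVERSION_PAIRS

# Published chromosome-level distribution of the 6,192-SNP C. sativa panel:
# SNP count and min/max mapped position (bp) per chromosome.
CAMELINA_CHROM_TABLE = pd.DataFrame(
    {
        "chrom": [str(c) for c in range(1, 21)],
        "n_snps": [227, 194, 337, 297, 346, 258, 388, 348, 361, 152,
                   440, 250, 317, 360, 333, 380, 339, 137, 356, 372],
        "start": [228704, 69846, 12546, 155571, 58645, 363184, 134626,
                  47447, 146807, 89230, 27486, 268164, 536996, 127248,
                  444993, 92846, 534721, 199741, 200572, 36207],
        "end": [23090767, 27568580, 28204286, 29874792, 34822707, 26361393,
                33181162, 27676481, 37664901, 25128064, 49606425, 32316596,
                24023072, 31599899, 30403961, 29000290, 35477318, 20820635,
                26042767, 29870253],
    }
).set_index("chrom")

#: Published substitution-class counts for the same 6,192-SNP panel.
CAMELINA_SPECTRUM_COUNTS = {
    "A/G": 2306,
    "C/T": 2257,
    "A/T": 498,
    "A/C": 431,
    "G/T": 423,
    "G/C": 277,
}

#: Chromosome lengths (bp) of the C. sativa reference assembly, from the
#: published per-chromosome lengths in Mb.
CAMELINA_CHROM_LENGTHS = {
    "1": 22_860_000, "2": 27_500_000, "3": 28_190_000, "4": 29_720_000,
    "5": 34_760_000, "6": 26_000_000, "7": 33_050_000, "8": 27_630_000,
    "9": 37_520_000, "10": 25_040_000, "11": 49_580_000, "12": 32_050_000,
    "13": 23_490_000, "14": 31_470_000, "15": 29_960_000, "16": 28_910_000,
    "17": 34_940_000, "18": 20_620_000, "19": 25_840_000, "20": 29_830_000,
}


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Classify a SNP as transition or transversion.

    Returns ``(kind, label)`` where *kind* is ``"transition"`` (purine↔purine
    or pyrimidine↔pyrimidine: A/G, C/T) or ``"transversion"`` (the four
    remaining pairs) and *label* is the orientation-independent pair label
    (``G→A`` and ``A→G`` are both ``"A/G"``).
    """
    ref, alt = str(ref).upper(), str(alt).upper()
    if ref not in VALID_NUCLEOTIDES or alt not in VALID_NUCLEOTIDES:
        raise ValueError(f"non-nucleotide alleles: {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError(f"identical alleles: {ref!r}")
    a, b = sorted((ref, alt))
    label = f"{a}/{b}"
    if label == "C/G":  # conventional label puts the purine first here
        label = "G/C"
    if {ref, alt} <= PURINES or {ref, alt} <= PYRIMIDINES:
        kind = "transition"
    else:
        kind = "transversion"
    return kind, label


@dataclass
class SubstitutionSpectrum:
    """Counts and shares of the six substitution classes in a panel."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = {lab: int(self.counts.get(lab, 0)) for lab in PAIR_LABELS}

    @property
    def n_sites(self) -> int:
        return sum(self.counts.values())

    @property
    def transition_total(self) -> int:
        return sum(self.counts[lab] for lab in TRANSITION_PAIRS)

    @property
    def transversion_total(self) -> int:
        return sum(self.counts[lab] for lab in TRANSVERSION_PAIRS)

    @property
    def tstv_ratio(self) -> float | None:
        """Transition/transversion ratio; None (undefined) if no transversions."""
        if self.transversion_total == 0:
            return None
        return self.transition_total / self.transversion_total

    def percent(self, label: str) -> float:
        return 100.0 * self.counts[label] / self.n_sites

    @property
    def transition_percent(self) -> float:
        return 100.0 * self.transition_total / self.n_sites

    @property
    def transversion_percent(self) -> float:
        return 100.0 * self.transversion_total / self.n_sites

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab in PAIR_LABELS:
            kind = "transition" if lab in TRANSITION_PAIRS else "transversion"
            rows.append(
                {"pair": lab, "kind": kind, "count": self.counts[lab],
                 "percent": round(self.percent(lab), 2)}
            )
        return pd.DataFrame(rows).set_index("pair")


def spectrum(variants: VariantTable) -> SubstitutionSpectrum:
    """Substitution spectrum of all biallelic SNP records in a variant table."""
    counts: dict[str, int] = {lab: 0 for lab in PAIR_LABELS}
    snp = variants.is_snp()
    for ref, alt in zip(variants.df["ref"][snp], variants.df["alt"][snp]):
        _, label = classify_substitution(ref, alt)
        counts[label] += 1
    return SubstitutionSpectrum(counts)


def spectrum_from_counts(counts: dict[str, int]) -> SubstitutionSpectrum:
    """Spectrum built directly from per-pair counts (e.g. a published table)."""
    unknown = set(counts) - set(PAIR_LABELS)
    if unknown:
        raise ValueError(f"unknown pair labels: {sorted(unknown)}")
    return SubstitutionSpectrum(dict(counts))


def chromosome_summary(variants: VariantTable) -> pd.DataFrame:
    """Per-chromosome SNP distribution summary.

    Columns: ``n_snps``, ``pct_snps`` (percent of the panel), ``start`` and
    ``end`` (min/max mapped position, bp), ``span`` (end − start, bp) and
    ``density_kb`` (span / n_snps in kb; NaN for single-SNP chromosomes).
    """
    df = variants.df
    grouped = df.groupby("chrom", sort=False)["pos"]
    out = pd.DataFrame(
        {
            "n_snps": grouped.size(),
            "start": grouped.min(),
            "end": grouped.max(),
        }
    )
    return _summarize(out)


def chromosome_summary_from_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Summary from a precomputed per-chromosome (n_snps, start, end) table."""
    return _summarize(table[["n_snps", "start", "end"]].copy())


def _summarize(out: pd.DataFrame) -> pd.DataFrame:
    total = out["n_snps"].sum()
    out["pct_snps"] = 100.0 * out["n_snps"] / total
    out["span"] = out["end"] - out["start"]
    density = out["span"] / out["n_snps"] / 1000.0
    out["density_kb"] = density.where(out["n_snps"] >= 2)
    return out


def mean_marker_density(summary: pd.DataFrame) -> float:
    """Average marker density: unweighted mean of per-chromosome densities (kb)."""
    return float(summary["density_kb"].mean())
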