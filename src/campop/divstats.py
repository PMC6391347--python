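"""Per-locus and per-population diversity statistics.

Per locus: gene diversity (expected heterozygosity, H = 1 − Σp²),
polymorphism information content (PIC), minor allele frequency (MAF).
Per population: the classical index suite — mean number of alleles (Na),
effective alleles (Ne), Shannon's information index (I), observed and
expected heterozygosity (Ho, He), unbiased He, fixation index F,
percentage of polymorphic loci (PPL) and private-allele counts.

All frequencies are computed from called alleles only (complete case per
locus); the missing sentinel never enters an allele count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, allele_counts

#: Marker informativeness bands on PIC.
PIC_BANDS = (
    (0.5, "highly informative"),
    (0.25, "moderately informative"),
    (0.0, "slightly informative"),
)


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if (freqs < 0).any():
        raise ValueError("allele frequencies must be non-negative")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies must sum to 1, got {freqs.sum()!r}")
    return freqs


def gene_diversity(freqs) -> float:
    """Gene diversity H = 1 − Σ pᵢ².

    The probability that two alleles drawn at random from the population
    differ; equals the expected heterozygosity under Hardy–Weinberg.
    """
    freqs = _check_freqs(freqs)
    return float(1.0 - np.sum(freqs**2))


def pic(freqs) -> float:
    """Polymorphism information content, PIC = 1 − Σpᵢ² − ΣΣ_{i<j} 2pᵢ²pⱼ².

    Gene diversity minus a term discounting matings of indistinguishable
    heterozygotes; for a biallelic locus the maximum is 0.375 at p = 0.5.
    """
    freqs = _check_freqs(freqs)
    sq = freqs**2
    # sum over i<j of 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    cross = float(np.sum(sq) ** 2 - np.sum(sq**2))
    return float(1.0 - np.sum(sq) - cross)


def pic_band(value: float) -> str:
    """Informativeness band of a PIC value.

    ≥ 0.5 highly informative; 0.25–0.5 moderately informative;
    < 0.25 slightly informative.
    """
    for threshold, label in PIC_BANDS:
        if value >= threshold:
            return label
    return PIC_BANDS[-1][1]


def allele_frequencies(dosages) -> np.ndarray:
    """(ref, alt) allele frequencies of one locus column from called alleles."""
    alt, total = allele_counts(np.asarray(dosages))
    if total[0] == 0:
        raise ValueError("all genotypes missing at locus")
    p_alt = float(alt[0] / total[0])
    return np.array([1.0 - p_alt, p_alt])


def minor_allele_frequency(dosages) -> float:
    """MAF: minor-allele count over total called alleles, min(p, 1 − p)."""
    _, p_alt = allele_frequencies(dosages)
    return float(min(p_alt, 1.0 - p_alt))


def locus_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus MAF, gene diversity, PIC and called-genotype count."""
    alt, total = allele_counts(genotypes.dosages)
    if (total == 0).any():
        bad = [genotypes.locus_ids[i] for i in np.flatnonzero(total == 0)]
        raise ValueError(f"all-missing loci: {bad[:5]}")
    p = alt / total
    maf = np.minimum(p, 1 - p)
    gd = 1.0 - p**2 - (1 - p) ** 2
    sumsq = p**2 + (1 - p) ** 2
    picv = 1.0 - sumsq - 2.0 * p**2 * (1 - p) ** 2
    return pd.DataFrame(
        {
            "maf": maf,
            "gd": gd,
            "pic": picv,
            "n_called": genotypes.called.sum(axis=0),
        },
        index=pd.Index(genotypes.locus_ids, name="locus"),
    )


def population_frequencies(
    genotypes: GenotypeMatrix, pop_labels
) -> pd.DataFrame:
    """ALT-allele frequency per population × locus (called alleles only).

    Loci with no calls in a population get NaN.
    """
    labels = np.asarray(pop_labels)
    if labels.shape[0] != genotypes.n_individuals:
        raise ValueError("one population label per individual required")
    rows = {}
    for pop in pd.unique(labels):
        block = genotypes.dosages[labels == pop]
        alt, total = allele_counts(block)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[pop] = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    return pd.DataFrame(rows, index=genotypes.locus_ids).T


def pop_indices(genotypes: GenotypeMatrix, pop_labels) -> pd.DataFrame:
    """Per-population diversity index table plus an unweighted mean row.

    Per locus within each population (called genotypes only):
    Na = observed distinct alleles; Ne = 1/Σpᵢ²; I = −Σ pᵢ ln pᵢ;
    Ho = fraction heterozygous; He = 1 − Σpᵢ²;
    uHe = 2N/(2N − 1) · He with N the called individuals at that locus;
    F = 1 − Ho/He where He > 0. Table entries are means over loci (loci with
    no calls in a population are excluded from that population's means).
    PPL = percent of loci with Na ≥ 2; n_private counts loci where an allele
    present in this population is absent from every other population.
    """
    labels = np.asarray(pop_labels)
    if labels.shape[0] != genotypes.n_individuals:
        raise ValueError("one population label per individual required")
    pops = list(pd.unique(labels))
    for pop in pops:
        if (labels == pop).sum() < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")

    # presence[pop] = (ref present, alt present) per locus, for private alleles
    presence: dict[object, np.ndarray] = {}
    per_pop: dict[object, dict[str, float]] = {}

    for pop in pops:
        block = genotypes.dosages[labels == pop]
        called = block != MISSING
        n_called = called.sum(axis=0).astype(float)
        ok = n_called > 0
        alt, total = allele_counts(block)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, alt / np.maximum(total, 1), np.nan)
        q = 1.0 - p
        ref_present = ok & (q > 0)
        alt_present = ok & (p > 0)
        presence[pop] = np.stack([ref_present, alt_present])

        na = ref_present.astype(float) + alt_present.astype(float)
        sumsq = p**2 + q**2
        ne = 1.0 / sumsq
        with np.errstate(invalid="ignore", divide="ignore"):
            shannon = -(
                np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
                + np.where(q > 0, q * np.log(np.where(q > 0, q, 1.0)), 0.0)
            )
        he = 1.0 - sumsq
        ho = np.where(ok, (block == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
        uhe = np.where(
            ok, (2 * n_called) / np.maximum(2 * n_called - 1, 1) * he, np.nan
        )
        poly = he > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            fix = np.where(poly, 1.0 - ho / np.where(poly, he, 1.0), np.nan)

        per_pop[pop] = {
            "N": float(np.nanmean(np.where(ok, n_called, np.nan))),
            "Na": float(np.nanmean(np.where(ok, na, np.nan))),
            "Ne": float(np.nanmean(np.where(ok, ne, np.nan))),
            "I": float(np.nanmean(np.where(ok, shannon, np.nan))),
            "Ho": float(np.nanmean(ho)),
            "He": float(np.nanmean(np.where(ok, he, np.nan))),
            "uHe": float(np.nanmean(uhe)),
            "F": float(np.nanmean(fix)),
            "PPL": float(100.0 * poly[ok].mean()),
        }

    for pop in pops:
        others = [presence[q_] for q_ in pops if q_ != pop]
        other_present = np.logical_or.reduce(others) if others else np.zeros_like(presence[pop])
        private = presence[pop] & ~other_present
        per_pop[pop]["n_private"] = int(private.any(axis=0).sum())

    table = pd.DataFrame(per_pop).T
    table.index.name = "population"
    table.loc["Mean"] = table.mean(axis=0)
    return table


def unbiased_he(he: float, n_called: int) -> float:
    """Unbiased expected heterozygosity, 2N/(2N − 1) · He."""
    if n_called < 1:
        raise ValueError("need at least one called individual")
    return 2 * n_called / (2 * n_called - 1) * he


def histogram_bins(values, bin_width: float) -> pd.Series:
    """Right-open fixed-width bins starting at 0; counts sum to len(values)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        return pd.Series(dtype=int)
    idx = np.floor(values / bin_width).astype(int)
    counts = pd.Series(idx).value_counts().sort_index()
    counts.index = [
        f"[{i * bin_width:g}, {(i + 1) * bin_width:g})" for i in counts.index
    ]
    return counts
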