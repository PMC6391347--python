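"""Core data model shared by every pipeline stage.

The central object is a :class:`GenotypeMatrix`: an individuals × loci matrix
of minor/ALT-allele dosages for diploid biallelic SNP genotypes, with a
reserved integer sentinel for missing calls. Per-locus positional metadata
lives in a :class:`VariantTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved sentinel for a missing diploid genotype call. Distinct from all
#: valid dosages {0, 1, 2}.
MISSING: int = -1

VALID_NUCLEOTIDES = frozenset("ACGT")


def _check_unique(labels, what: str) -> None:
    if len(set(labels)) != len(labels):
        raise ValueError(f"{what} must be unique")


@dataclass
class GenotypeMatrix:
    """Individuals × loci ALT-allele dosages with a missing sentinel.

    Parameters
    ----------
    dosages
        Integer array of shape ``(n_individuals, n_loci)`` with entries in
        ``{0, 1, 2, MISSING}``.
    sample_ids
        Ordered, unique individual labels (rows).
    locus_ids
        Ordered, unique locus labels (columns), matching a
        :class:`VariantTable` index.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if m != len(self.locus_ids):
            raise ValueError(
                f"{len(self.locus_ids)} locus ids for {m} dosage columns"
            )
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.locus_ids, "locus_ids")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values: {bad.tolist()}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return self.dosages != MISSING

    def take_loci(self, index) -> "GenotypeMatrix":
        """Column subset preserving order, by integer or boolean index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.sample_ids,
            [self.locus_ids[i] for i in index],
        )

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            [self.sample_ids[i] for i in index],
            self.locus_ids,
        )


@dataclass
class VariantTable:
    """Per-locus chromosome, 1-based position and ref/alt alleles.

    Wraps a DataFrame indexed by locus id with columns ``chrom``, ``pos``,
    ``ref`` and ``alt``. Multi-allelic records are representable (``alt`` as a
    comma-joined string) so that the biallelic filter can see and drop them,
    but all downstream statistics require single-nucleotide ref and alt.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref", "alt"}
        missing_cols = required - set(self.df.columns)
        if missing_cols:
            raise ValueError(f"variant table missing columns: {sorted(missing_cols)}")
        if (self.df["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        if (self.df["ref"] == self.df["alt"]).any():
            raise ValueError("ref and alt alleles must differ")
        _check_unique(list(self.df.index), "locus ids")

    @property
    def locus_ids(self) -> list[str]:
        return [str(i) for i in self.df.index]

    def __len__(self) -> int:
        return len(self.df)

    def take(self, index) -> "VariantTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return VariantTable(self.df.iloc[index].copy())

    def is_snp(self) -> np.ndarray:
        """Strictly biallelic SNP mask: single-nucleotide ref and alt."""
        ref_ok = self.df["ref"].isin(list(VALID_NUCLEOTIDES))
        alt_ok = self.df["alt"].isin(list(VALID_NUCLEOTIDES))
        return (ref_ok & alt_ok).to_numpy()


def allele_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (ALT allele count, called allele total) from a dosage block.

    Missing entries contribute nothing; only called genotypes are counted
    (complete-case per locus). ``dosages`` may be 1-D (one locus) or 2-D
    (individuals × loci); the reduction is over individuals.
    """
    d = np.asarray(dosages)
    if d.ndim == 1:  # a single locus column
        d = d.reshape(-1, 1)
    called = d != MISSING
    alt = np.where(called, d, 0).sum(axis=0).astype(float)
    total = 2.0 * called.sum(axis=0)
    return alt, total
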