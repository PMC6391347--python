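"""Synthetic diploid SNP panel generator.

Generates genotype panels with the statistical structure a GBS diversity
study assumes: K subpopulations diverged to a target Fst under the
Balding–Nichols model (population allele frequencies Beta-distributed around
an ancestral frequency), Dirichlet-distributed individual admixture,
missing-completely-at-random genotype calls, and a realistic
transition/transversion substitution spectrum over 20 chromosomes. Panels are
written as plain-text VCF 4.2 plus a sample-metadata table, and every draw is
reproducible from a single seed.

Defaults emulate a 213-accession spring *Camelina sativa* panel: two weakly
differentiated subpopulations (Fst ≈ 0.04) of 105 and 108 individuals,
6,192 post-filter SNPs, Ts/Tv ≈ 2.80.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, VariantTable
from .landscape import CAMELINA_CHROM_LENGTHS, TRANSVERSION_PAIRS


@dataclass
class SimConfig:
    """Parameters of a synthetic panel.

    Attributes
    ----------
    n_pops
        Number of generating subpopulations K (≥ 1).
    pop_sizes
        Individuals per subpopulation; their sum is the panel size N.
    n_loci
        Number of SNP loci.
    fst_target
        Balding–Nichols divergence parameter F in [0, 1). F = 0 collapses all
        population frequencies onto the ancestral frequency.
    admix_alpha
        Dirichlet concentration for off-home clusters; ``None`` gives
        unadmixed individuals (q is one-hot on the generating population).
        An individual from population j draws q ~ Dirichlet(c) with c_j = 1
        and c_k = admix_alpha elsewhere.
    missing_rate
        Per-genotype missing probability (MCAR) in [0, 1).
    tstv_target
        Target transition:transversion ratio (> 0, or 0 for all
        transversions).
    chrom_lengths
        Mapping chromosome label → length in bp; positions are drawn
        uniformly, proportionally to length.
    ancestral_maf_range
        Ancestral minor-allele frequencies are drawn uniformly from this
        interval within (0, 0.5].
    seed
        Master seed; identical configs produce byte-identical panels.
    """

    n_pops: int = 2
    pop_sizes: tuple[int, ...] = (105, 108)
    n_loci: int = 6192
    fst_target: float = 0.04
    admix_alpha: float | None = 0.2
    missing_rate: float = 0.10
    tstv_target: float = 2.80
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(CAMELINA_CHROM_LENGTHS)
    )
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes must have one entry per population")
        if any(s < 1 for s in self.pop_sizes):
            raise ValueError("all population sizes must be >= 1")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        if self.admix_alpha is not None and self.admix_alpha <= 0:
            raise ValueError("admix_alpha must be positive or None")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.tstv_target < 0:
            raise ValueError("tstv_target must be >= 0")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("all chromosome lengths must be positive")

    @property
    def n_individuals(self) -> int:
        return int(sum(self.pop_sizes))


@dataclass
class TruthRecord:
    """Generating parameters of a panel, for parameter-recovery checks."""

    ancestral_freqs: np.ndarray  # (L,)
    pop_freqs: np.ndarray  # (K, L)
    q_true: np.ndarray  # (N, K)
    pop_labels: np.ndarray  # (N,) generating population index

    def __post_init__(self) -> None:
        for arr in (self.ancestral_freqs, self.pop_freqs, self.q_true):
            if ((np.asarray(arr) < 0) | (np.asarray(arr) > 1)).any():
                raise ValueError("frequencies/proportions must lie in [0, 1]")
        if np.abs(self.q_true.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("q_true rows must sum to 1")


def simulate_pop_freqs(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-population minor-allele frequencies.

    Balding–Nichols: with ancestral frequency p and divergence F, each
    population's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F), so that its
    expectation is p and its variance F·p(1−p). F = 0 degenerates to the
    ancestral frequency exactly.

    Returns ``(ancestral (L,), pop_freqs (K, L))``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.n_loci < 1:
        raise ValueError("empty locus set")
    lo, hi = config.ancestral_maf_range
    p = rng.uniform(lo, hi, size=config.n_loci)
    F = config.fst_target
    if F == 0.0:
        pop = np.tile(p, (config.n_pops, 1))
    else:
        scale = (1.0 - F) / F
        pop = rng.beta(p * scale, (1.0 - p) * scale, size=(config.n_pops, config.n_loci))
    return p, pop


def simulate_q(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Admixture proportions and generating-population labels.

    Returns ``(q (N, K), pop_labels (N,))``. Unadmixed configs yield one-hot
    rows.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = np.repeat(np.arange(config.n_pops), config.pop_sizes)
    n = labels.shape[0]
    if config.admix_alpha is None or config.n_pops == 1:
        q = np.zeros((n, config.n_pops))
        q[np.arange(n), labels] = 1.0
    else:
        conc = np.full((n, config.n_pops), config.admix_alpha)
        conc[np.arange(n), labels] = 1.0
        gam = rng.gamma(conc)
        q = gam / gam.sum(axis=1, keepdims=True)
    return q, labels


def simulate_genotypes(
    pop_freqs: np.ndarray,
    q_matrix: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    pop_labels: np.ndarray | None = None,
    ancestral_freqs: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Draw diploid dosages given population frequencies and admixture.

    Each of an individual's two allele copies picks an origin population from
    its q row, then is the minor allele with that population's frequency.
    Missing entries are set completely at random at ``missing_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop_freqs = np.asarray(pop_freqs, dtype=float)
    q_matrix = np.asarray(q_matrix, dtype=float)
    K, L = pop_freqs.shape
    if q_matrix.ndim != 2 or q_matrix.shape[1] != K:
        raise ValueError(
            f"q_matrix has {q_matrix.shape[1] if q_matrix.ndim == 2 else '?'} "
            f"columns but pop_freqs has {K} populations"
        )
    if np.abs(q_matrix.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("q_matrix rows must sum to 1")
    n = q_matrix.shape[0]

    dosage = np.zeros((n, L), dtype=np.int8)
    cdf = np.cumsum(q_matrix, axis=1)
    for copy in range(2):
        u = rng.random((n, L))
        origin = (u[:, :, None] > cdf[:, None, :]).sum(axis=2)
        origin = np.minimum(origin, K - 1)
        p_copy = pop_freqs[origin, np.arange(L)[None, :]]
        dosage += (rng.random((n, L)) < p_copy).astype(np.int8)

    if config.missing_rate > 0:
        miss = rng.random((n, L)) < config.missing_rate
        dosage[miss] = MISSING

    sample_ids = [f"acc{i + 1:04d}" for i in range(n)]
    locus_ids = [f"snp{j + 1:05d}" for j in range(L)]
    gm = GenotypeMatrix(dosage, sample_ids, locus_ids)
    if pop_labels is None:
        pop_labels = np.argmax(q_matrix, axis=1)
    if ancestral_freqs is None:
        ancestral_freqs = pop_freqs.mean(axis=0)
    truth = TruthRecord(
        ancestral_freqs=np.asarray(ancestral_freqs, dtype=float),
        pop_freqs=pop_freqs,
        q_true=q_matrix,
        pop_labels=np.asarray(pop_labels),
    )
    return gm, truth


_TRANSITION_BY_REF = {"A": "G", "G": "A", "C": "T", "T": "C"}


def assign_variant_contexts(
    config: SimConfig, rng: np.random.Generator | None = None
) -> VariantTable:
    """Chromosomes, positions and ref/alt nucleotides for ``n_loci`` sites.

    Sites are spread over chromosomes proportionally to length, at unique
    uniform 1-based positions, sorted by (chrom, pos). Each site is a
    transition with probability t/(1 + t) for target ratio t (A↔G or C↔T);
    otherwise one of the four transversion pairs, uniformly. REF carries the
    major allele by generation-time convention; downstream statistics never
    rely on this and recompute MAF.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    if config.n_loci > lengths.sum():
        raise ValueError("more loci requested than positions available")
    counts = rng.multinomial(config.n_loci, lengths / lengths.sum())
    # repair any chromosome drawn above its capacity (pathological configs)
    while (counts > lengths).any():
        over = int(np.argmax(counts - lengths))
        spare = np.flatnonzero(counts < lengths)
        counts[over] -= 1
        counts[spare[0]] += 1

    rows = []
    t = config.tstv_target
    p_transition = t / (1.0 + t) if t > 0 else 0.0
    for chrom, length, k in zip(chroms, lengths.astype(int), counts):
        if k == 0:
            continue
        # draw-and-deduplicate keeps memory flat for long chromosomes
        pos = np.unique(rng.integers(1, length + 1, size=2 * k + 16))
        while pos.size < k:
            extra = rng.integers(1, length + 1, size=2 * k + 16)
            pos = np.unique(np.concatenate([pos, extra]))
        if pos.size > k:
            pos = np.sort(rng.choice(pos, size=k, replace=False))
        is_ts = rng.random(k) < p_transition
        for p_i, ts in zip(pos, is_ts):
            if ts:
                ref = rng.choice(list("ACGT"))
                alt = _TRANSITION_BY_REF[ref]
            else:
                pair = TRANSVERSION_PAIRS[rng.integers(4)]
                a, b = pair.split("/")
                ref, alt = (a, b) if rng.random() < 0.5 else (b, a)
            rows.append((chrom, int(p_i), ref, alt))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    df.index = pd.Index([f"snp{j + 1:05d}" for j in range(len(df))], name="locus")
    return VariantTable(df)


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypeMatrix, VariantTable, TruthRecord, pd.DataFrame]:
    """Full panel draw: genotypes, variant contexts, truth and metadata.

    All randomness derives from ``config.seed``; identical configs give
    identical panels. Origin labels in the metadata equal the generating
    population (``POP1``, ``POP2``, ...).
    """
    rng = np.random.default_rng(config.seed)
    anc, pop_freqs = simulate_pop_freqs(config, rng)
    q, labels = simulate_q(config, rng)
    gm, truth = simulate_genotypes(
        pop_freqs, q, config, rng, pop_labels=labels, ancestral_freqs=anc
    )
    variants = assign_variant_contexts(config, rng)
    meta = pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "origin_code": [f"POP{l + 1}" for l in labels],
            "true_pop": [f"POP{l + 1}" for l in labels],
        }
    )
    return gm, variants, truth, meta


def write_panel(
    genotypes: GenotypeMatrix,
    variants: VariantTable,
    metadata: pd.DataFrame,
    vcf_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
) -> None:
    """Write a panel as plain-text VCF 4.2 (GT-only) plus metadata TSV.

    Dosages are encoded on the ALT allele (0 → ``0/0``, 1 → ``0/1``,
    2 → ``1/1``, missing → ``./.``), unphased. Round-tripping through
    :func:`campop.vcf_io.read_vcf` reproduces the dosage matrix exactly.
    """
    if genotypes.n_individuals == 0:
        raise ValueError("cannot write a panel with 0 individuals")
    if genotypes.n_loci != len(variants):
        raise ValueError("genotypes and variants disagree on locus count")
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=campop.syndata\n")
        for chrom in dict.fromkeys(variants.df["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j, (locus, row) in enumerate(variants.df.iterrows()):
            calls = "\t".join(
                gt_code[int(d)] for d in genotypes.dosages[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{locus}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )
    metadata.to_csv(metadata_path, sep="\t", index=False)
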