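"""Three-level codominant AMOVA with Φ(Fst), Nm and a permutation test.

The hierarchy partitions squared genetic distances among allele copies into
among-population, among-individual-within-population and within-individual
components. Each diploid individual is expanded to two allele rows (per-locus
minor/ALT-allele indicators); sums of squares are ratios of pairwise squared
distances, and variance components are solved from expected mean squares with
the unequal-sample-size coefficient n₀. Φ over the total variance is the
fixation index Fst, and the island-model migrant number is
Nm = [(1/Fst) − 1]/4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .distances import pairwise_squared_dosage

#: Fst above this is conventionally read as significant population
#: differentiation.
FST_SIGNIFICANT = 0.15


def nm_from_fst(fst: float) -> float:
    """Haploid migrant number under the island model, Nm = [(1/Fst) − 1]/4.

    Undefined (NaN) for Fst ≤ 0.
    """
    if not np.isfinite(fst) or fst <= 0:
        return float("nan")
    return ((1.0 / fst) - 1.0) / 4.0


def differentiation_label(fst: float) -> str:
    """Qualitative reading of an Fst value (> 0.15 ⇒ significant)."""
    if not np.isfinite(fst):
        return "undefined"
    return "significant" if fst > FST_SIGNIFICANT else "low"


@dataclass
class AmovaResult:
    """AMOVA table, fixation index, migrant number and permutation p-value."""

    strata: pd.DataFrame  # df, SS, MS, est_var, pct per level + total
    fst: float
    nm: float
    p_value: float
    n_permutations: int
    negative_components: bool = False

    def __str__(self) -> str:  # pragma: no cover - convenience only
        lines = [self.strata.to_string(float_format=lambda v: f"{v:.3f}")]
        lines.append(f"Fst = {self.fst:.4f}  Nm = {self.nm:.3f}")
        if self.n_permutations:
            lines.append(
                f"P(perm Fst >= obs) = {self.p_value:.4f} "
                f"({self.n_permutations} permutations)"
            )
        return "\n".join(lines)


def allele_expansion(genotypes: GenotypeMatrix) -> np.ndarray:
    """Expand diploids to 2N allele-indicator rows (with missing sentinel).

    Row 2i and 2i+1 carry individual i's two allele copies as ALT-allele
    indicators; within heterozygotes the copies are written (1, 0) in fixed
    arbitrary order — every distance used downstream is invariant to that
    order.
    """
    d = genotypes.dosages
    n, L = d.shape
    rows = np.full((2 * n, L), MISSING, dtype=np.int8)
    called = d != MISSING
    first = np.where(d >= 1, 1, 0)
    second = np.where(d == 2, 1, 0)
    rows[0::2][called] = first[called]
    rows[1::2][called] = second[called]
    return rows


def _ss_within_groups(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    """Σ over groups of (sum of pairwise squared distances)/(group size)."""
    total = 0.0
    for idx in groups:
        block = d2[np.ix_(idx, idx)]
        total += block.sum() / 2.0 / idx.size
    return total


def _components_from_ss(
    ss_ap: float, ss_ai: float, ss_wi: float, pop_sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """df, MS and variance components for the three levels."""
    k = pop_sizes.size
    n = int(pop_sizes.sum())
    df = np.array([k - 1, n - k, n], dtype=float)
    ms = np.array([ss_ap, ss_ai, ss_wi]) / df
    sigma_wi = ms[2]
    sigma_ai = (ms[1] - ms[2]) / 2.0
    n0 = (n - (pop_sizes**2).sum() / n) / (k - 1)
    sigma_ap = (ms[0] - ms[1]) / (2.0 * n0)
    return df, ms, np.array([sigma_ap, sigma_ai, sigma_wi])


def _fst(components: np.ndarray) -> float:
    total = components.sum()
    if total <= 0:
        return float("nan")
    return float(components[0] / total)


def amova_three_level(
    genotypes: GenotypeMatrix,
    pop_labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Three-level AMOVA over K ≥ 2 populations of diploid individuals.

    SS_total is the sum of pairwise squared distances among all 2N allele
    rows divided by 2N; within-group SS are computed analogously inside each
    grouping (populations; individuals). The partition is
    total = among-pops + among-individuals-within-pops + within-individuals
    with df (K−1, N−K, N). Distances between allele rows rescale by shared
    called loci exactly as individual distances do. The permutation test
    shuffles whole individuals (both allele rows) among populations and
    reports the plain fraction of permutations with Fst ≥ the observed value.
    """
    labels = np.asarray(pop_labels)
    if labels.shape[0] != genotypes.n_individuals:
        raise ValueError("one population label per individual required")
    pops = list(pd.unique(labels))
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    sizes = np.array([(labels == p).sum() for p in pops], dtype=float)
    if (sizes < 2).any():
        small = [p for p, s in zip(pops, sizes) if s < 2]
        raise ValueError(f"singleton populations not allowed: {small}")
    n = genotypes.n_individuals

    rows = allele_expansion(genotypes)
    d2 = pairwise_squared_dosage(rows, rescale_to=genotypes.n_loci)

    ss_total = d2.sum() / 2.0 / (2 * n)
    indiv_groups = [np.array([2 * i, 2 * i + 1]) for i in range(n)]
    ss_wi = _ss_within_groups(d2, indiv_groups)

    def pop_groups(lab: np.ndarray) -> list[np.ndarray]:
        out = []
        for p in pops:
            members = np.flatnonzero(lab == p)
            out.append(np.concatenate([[2 * i, 2 * i + 1] for i in members]))
        return out

    ss_wp = _ss_within_groups(d2, pop_groups(labels))
    ss_ap = ss_total - ss_wp
    ss_ai = ss_wp - ss_wi

    df, ms, comp = _components_from_ss(ss_ap, ss_ai, ss_wi, sizes)
    fst = _fst(comp)
    negative = bool((comp < 0).any())
    comp_floor = np.maximum(comp, 0.0)
    total_var = comp_floor.sum()
    pct = 100.0 * comp_floor / total_var if total_var > 0 else np.zeros(3)

    strata = pd.DataFrame(
        {
            "df": np.append(df, df.sum()),
            "SS": [ss_ap, ss_ai, ss_wi, ss_total],
            "MS": np.append(ms, np.nan),
            "est_var": np.append(comp, comp.sum()),
            "pct": np.append(pct, pct.sum()),
        },
        index=[
            "among_pops",
            "among_individuals",
            "within_individuals",
            "total",
        ],
    )

    p_value = float("nan")
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            ss_wp_p = _ss_within_groups(d2, pop_groups(perm))
            ss_ap_p = ss_total - ss_wp_p
            ss_ai_p = ss_wp_p - ss_wi
            _, _, comp_p = _components_from_ss(ss_ap_p, ss_ai_p, ss_wi, sizes)
            fst_p = _fst(comp_p)
            if np.isfinite(fst_p) and np.isfinite(fst) and fst_p >= fst:
                hits += 1
        p_value = hits / n_permutations

    return AmovaResult(
        strata=strata,
        fst=fst,
        nm=nm_from_fst(fst),
        p_value=p_value,
        n_permutations=n_permutations,
        negative_components=negative,
    )
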