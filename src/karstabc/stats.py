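"""Descriptive population-genetic statistics.

Sequence side: haplotype and nucleotide diversity with Nei (1987)
standard deviations, segregating sites, mean pairwise differences,
Kimura two-parameter distances (plain and net between groups), AMOVA
Phi_ST and haplotype-identity F_ST with permutation tests.

Microsatellite side: observed/unbiased expected heterozygosity, allelic
richness by hypergeometric rarefaction, Weir & Cockerham (1984) F_IS and
two-population F_ST (theta), Slatkin-type R_ST from allele-size variance
components, Hardy-Weinberg and genic-differentiation exact tests
(enumeration or Monte-Carlo under the Levene / fixed-margins conditional
distributions), and a Mantel test of isolation by distance on linearised
F_ST versus log great-circle distance.

All permutation/Monte-Carlo p-values use the (b+1)/(B+1) convention and
are bit-reproducible for a fixed ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .io import MISSING_ALLELE, MicrosatGenotypes, SequenceAlignment

__all__ = [
    "DiversityStats",
    "DifferentiationResult",
    "MicrosatDiversity",
    "SaturationError",
    "haplotype_diversity",
    "nucleotide_diversity",
    "seq_summary",
    "k2p_distance",
    "net_k2p_between_groups",
    "phist_pairwise",
    "fst_haplotype_pairwise",
    "microsat_summary",
    "allelic_richness",
    "fis_wc",
    "wc_fst_two_pops",
    "hwe_exact_mc",
    "genic_diff_exact_mc",
    "fisher_combine",
    "fst_microsat_pairwise",
    "rst_pairwise",
    "mantel_ibd",
    "great_circle_km",
    "pairwise_difference_matrix",
    "amova_two_groups",
]


class SaturationError(ValueError):
    """K2P distance undefined: substitution saturation (log argument <= 0)."""


@dataclass
class DiversityStats:
    n: int
    k: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    S: int
    W: float


@dataclass
class DifferentiationResult:
    statistic_kind: str
    value: float
    permutation_p: float
    n_permutations: int


@dataclass
class MicrosatDiversity:
    group: str
    n: int
    Ho: float
    Ho_sd: float
    He: float
    He_sd: float
    AR: float
    Fis: float
    hwe_p_per_locus: dict[str, float]
    hwe_p_global: float


# ---------------------------------------------------------------------------
# sequence diversity


def haplotype_diversity(counts: Sequence[int]) -> tuple[float, float]:
    """Unbiased gene diversity h = n/(n-1)(1 - sum p_i^2) and its SD.

    The variance is Nei (1987, eq. 8.12):
    V(h) = 2/(n(n-1)) * [2(n-2)(sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2].
    """
    counts = np.asarray(counts, dtype=float)
    if (counts <= 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be positive integers")
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 sequences")
    p = counts / n
    sp2 = float(np.sum(p**2))
    sp3 = float(np.sum(p**3))
    h = n / (n - 1.0) * (1.0 - sp2)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (sp3 - sp2**2) + sp2 - sp2**2)
    return h, math.sqrt(max(var, 0.0))


def _diff_and_valid(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise difference counts and compared-site counts (pairwise deletion)."""
    n = arr.shape[0]
    obs = (arr != b"N") & (arr != b"-")
    diffs = np.zeros((n, n))
    valid = np.zeros((n, n))
    for i in range(n):
        both = obs[i] & obs[i + 1 :]
        d = (arr[i] != arr[i + 1 :]) & both
        diffs[i, i + 1 :] = d.sum(axis=1)
        valid[i, i + 1 :] = both.sum(axis=1)
    diffs += diffs.T
    valid += valid.T
    return diffs, valid


def pairwise_difference_matrix(aln: SequenceAlignment) -> np.ndarray:
    """n x n matrix of pairwise difference counts (missing sites excluded)."""
    return _diff_and_valid(aln.to_array())[0]


def nucleotide_diversity(aln: SequenceAlignment) -> tuple[float, float]:
    """Mean per-site pairwise diversity pi and its total SD.

    pi averages differences/compared-sites over all pairs. The variance is
    the Nei (1987) total variance,
    V(pi) = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2,
    covering both sampling and stochastic components.
    """
    n, L = aln.n, aln.length
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if L == 0:
        raise ValueError("zero-length alignment")
    diffs, valid = _diff_and_valid(aln.to_array())
    iu = np.triu_indices(n, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_pair = np.where(valid[iu] > 0, diffs[iu] / valid[iu], 0.0)
    pi = float(per_pair.mean())
    var = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return pi, math.sqrt(max(var, 0.0))


def seq_summary(aln: SequenceAlignment) -> tuple[int, int, float]:
    """(k distinct haplotypes, segregating sites S, mean pairwise differences W)."""
    if aln.n < 1:
        raise ValueError("empty alignment")
    k = len(set(aln.sequences))
    arr = aln.to_array()
    S = segregating_sites(arr)
    if aln.n < 2:
        return k, S, 0.0
    diffs, _ = _diff_and_valid(arr)
    iu = np.triu_indices(aln.n, 1)
    return k, S, float(diffs[iu].mean())


def segregating_sites(arr: np.ndarray) -> int:
    """Columns with >= 2 observed states, missing (N/-) excluded."""
    S = 0
    for j in range(arr.shape[1]):
        col = arr[:, j]
        states = set(col[(col != b"N") & (col != b"-")].tolist())
        if len(states) >= 2:
            S += 1
    return S


# ---------------------------------------------------------------------------
# K2P

_PURINES = (b"A", b"G")
_PYRIMIDINES = (b"C", b"T")


def k2p_distance(seq1: str, seq2: str) -> float:
    """Kimura two-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q))."""
    a = np.frombuffer(seq1.upper().encode(), dtype="S1")
    b = np.frombuffer(seq2.upper().encode(), dtype="S1")
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    obs = np.isin(a, [b"A", b"C", b"G", b"T"]) & np.isin(b, [b"A", b"C", b"G", b"T"])
    m = int(obs.sum())
    if m == 0:
        raise ValueError("no jointly observed sites")
    a, b = a[obs], b[obs]
    diff = a != b
    pur_a, pur_b = np.isin(a, _PURINES), np.isin(b, _PURINES)
    transitions = int((diff & (pur_a == pur_b)).sum())
    transversions = int((diff & (pur_a != pur_b)).sum())
    P, Q = transitions / m, transversions / m
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError(f"saturated pair (P={P:.4g}, Q={Q:.4g})")
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


def net_k2p_between_groups(
    aln: SequenceAlignment,
    partition: dict[str, str],
    group_a: str,
    group_b: str,
) -> float:
    """Net divergence dA = dXY - (dX + dY)/2 on mean K2P distances."""
    ids_a = [s for s in aln.sample_ids if partition.get(s) == group_a]
    ids_b = [s for s in aln.sample_ids if partition.get(s) == group_b]
    if not ids_a or not ids_b:
        raise ValueError("both groups need at least one sequence")
    seq = dict(zip(aln.sample_ids, aln.sequences))

    def mean_within(ids: list[str]) -> float:
        if len(ids) < 2:
            return 0.0
        return float(
            np.mean([k2p_distance(seq[x], seq[y]) for x, y in combinations(ids, 2)])
        )

    d_xy = float(np.mean([k2p_distance(seq[x], seq[y]) for x in ids_a for y in ids_b]))
    return d_xy - 0.5 * (mean_within(ids_a) + mean_within(ids_b))


# ---------------------------------------------------------------------------
# AMOVA machinery (two groups, arbitrary squared-distance matrix)


def amova_two_groups(d2: np.ndarray, labels: np.ndarray) -> float:
    """Phi_ST from an AMOVA variance decomposition of squared distances.

    ``d2`` is the matrix of squared inter-unit distances; ``labels`` a
    0/1 vector assigning units to the two groups. Returns
    sigma2_a / (sigma2_a + sigma2_w); NaN if the total variance is zero.
    """
    n = len(labels)
    sizes = np.array([(labels == g).sum() for g in (0, 1)], dtype=float)
    if (sizes < 1).any():
        raise ValueError("each group needs at least one unit")
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in (0, 1):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_a, df_w = 1.0, n - 2.0
    if df_w <= 0:
        return math.nan
    sigma_w = ss_within / df_w
    n_prime = (n - (sizes**2).sum() / n) / df_a
    sigma_a = (ss_among / df_a - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    if denom == 0:
        return math.nan
    return float(sigma_a / denom)


def _permutation_p(
    d2: np.ndarray,
    labels: np.ndarray,
    observed: float,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """(b+1)/(B+1) upper-tail p, shuffling units between the two groups."""
    b = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        val = amova_two_groups(d2, lab)
        if not math.isnan(val) and val >= observed - 1e-12:
            b += 1
    return (b + 1) / (n_perm + 1)


def _labels_for(ids: Iterable[str], partition: dict[str, str], ga: str, gb: str):
    kept, lab = [], []
    for i, s in enumerate(ids):
        g = partition.get(s)
        if g == ga:
            kept.append(i)
            lab.append(0)
        elif g == gb:
            kept.append(i)
            lab.append(1)
    return np.array(kept), np.array(lab)


def phist_pairwise(
    aln: SequenceAlignment,
    partition: dict[str, str],
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> DifferentiationResult:
    """AMOVA Phi_ST between two groups, inter-haplotype distance = number
    of pairwise differences; p by permutation of individuals."""
    rng = rng or np.random.default_rng()
    kept, labels = _labels_for(aln.sample_ids, partition, group_a, group_b)
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("each group needs at least 2 sequences")
    d2 = pairwise_difference_matrix(aln)[np.ix_(kept, kept)]
    observed = amova_two_groups(d2, labels)
    p = _permutation_p(d2, labels, observed, n_perm, rng)
    return DifferentiationResult("PhiST", observed, p, n_perm)


def fst_haplotype_pairwise(
    alleles: Sequence,
    partition_labels: Sequence[str],
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> DifferentiationResult:
    """Conventional F_ST: the same AMOVA with 0/1 identity distances.

    ``alleles`` is one allele (e.g. a haplotype label) per sample,
    ``partition_labels`` the matching group label per sample.
    """
    rng = rng or np.random.default_rng()
    alleles = list(alleles)
    partition = {i: g for i, g in enumerate(partition_labels)}
    kept, labels = _labels_for(range(len(alleles)), partition, group_a, group_b)
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    sub = [alleles[i] for i in kept]
    _, codes = np.unique(np.asarray(sub, dtype=object), return_inverse=True)
    d2 = (codes[:, None] != codes[None, :]).astype(float)
    observed = amova_two_groups(d2, labels)
    p = _permutation_p(d2, labels, observed, n_perm, rng)
    return DifferentiationResult("FST(haplotype)", observed, p, n_perm)


# ---------------------------------------------------------------------------
# microsatellite diversity


def _locus_counts(geno: np.ndarray) -> dict[int, int]:
    """Allele -> gene-copy count at one locus ((n,2) slice), missing dropped."""
    alleles = geno[geno != MISSING_ALLELE]
    vals, counts = np.unique(alleles, return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


def observed_expected_het(geno: np.ndarray) -> tuple[float, float]:
    """(Ho, unbiased He) at one locus; NaN if no genotyped individual."""
    typed = geno[(geno != MISSING_ALLELE).all(axis=1)]
    if len(typed) == 0:
        return math.nan, math.nan
    ho = float((typed[:, 0] != typed[:, 1]).mean())
    copies = typed.ravel().astype(float)
    n2 = len(copies)
    _, counts = np.unique(copies, return_counts=True)
    p = counts / n2
    he = n2 / (n2 - 1.0) * (1.0 - float(np.sum(p**2))) if n2 > 1 else math.nan
    return ho, he


def allelic_richness(counts: dict[int, int] | Sequence[int], g: int) -> float:
    """Rarefied allele count for a subsample of ``g`` gene copies.

    AR = sum_i [1 - C(N-N_i, g)/C(N, g)] (hypergeometric rarefaction).
    """
    vals = list(counts.values()) if isinstance(counts, dict) else list(counts)
    N = int(sum(vals))
    if g > N:
        raise ValueError(f"g={g} exceeds available gene copies {N}")
    if g < 1:
        raise ValueError("g must be >= 1")
    log_cn = _log_comb(N, g)
    ar = 0.0
    for ni in vals:
        if N - ni < g:
            ar += 1.0
        else:
            ar += 1.0 - math.exp(_log_comb(N - ni, g) - log_cn)
    return ar


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def _wc_single_pop_components(geno: np.ndarray) -> tuple[float, float]:
    """Sums of Weir-Cockerham b and c components over alleles at one locus."""
    typed = geno[(geno != MISSING_ALLELE).all(axis=1)]
    n = len(typed)
    if n < 2:
        return 0.0, 0.0
    alleles = np.unique(typed)
    b_sum = c_sum = 0.0
    for a in alleles:
        p = float((typed == a).sum()) / (2 * n)
        h = float(((typed[:, 0] == a) != (typed[:, 1] == a)).mean())
        b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1.0) / (4.0 * n) * h)
        c = h / 2.0
        b_sum += b
        c_sum += c
    return b_sum, c_sum


def fis_wc(geno: MicrosatGenotypes) -> float:
    """Multi-locus Weir & Cockerham (1984) f (F_IS) for one population."""
    if geno.n < 2:
        raise ValueError("need at least 2 individuals")
    B = C = 0.0
    for j in range(geno.n_loci):
        b, c = _wc_single_pop_components(geno.genotypes[:, j, :])
        B += b
        C += c
    if B + C == 0:
        raise ValueError("all loci monomorphic: Fis undefined")
    return 1.0 - C / (B + C)


def wc_fst_two_pops(
    geno_a: np.ndarray, geno_b: np.ndarray
) -> tuple[float, float, float]:
    """Summed Weir-Cockerham theta components (a, b, c) across loci.

    Inputs are (n, L, 2) genotype arrays for the two populations.
    theta = a / (a + b + c); the caller sums across loci already done here.
    """
    L = geno_a.shape[1]
    A = B = C = 0.0
    r = 2
    for j in range(L):
        pops = []
        for g in (geno_a[:, j, :], geno_b[:, j, :]):
            typed = g[(g != MISSING_ALLELE).all(axis=1)]
            if len(typed) >= 1:
                pops.append(typed)
        if len(pops) < 2:
            continue
        ns = np.array([len(t) for t in pops], dtype=float)
        nbar = ns.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        alleles = np.unique(np.concatenate([t.ravel() for t in pops]))
        for a in alleles:
            ps = np.array([float((t == a).sum()) / (2 * len(t)) for t in pops])
            hs = np.array(
                [float(((t[:, 0] == a) != (t[:, 1] == a)).mean()) for t in pops]
            )
            pbar = float((ns * ps).sum() / (r * nbar))
            s2 = float((ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar))
            hbar = float((ns * hs).sum() / (r * nbar))
            a_comp = (nbar / nc) * (
                s2
                - 1.0
                / (nbar - 1)
                * (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
            )
            b_comp = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1.0) / r * s2
                - (2 * nbar - 1.0) / (4.0 * nbar) * hbar
            )
            c_comp = hbar / 2.0
            A += a_comp
            B += b_comp
            C += c_comp
    return A, B, C


def _theta_from_geno(genotypes: np.ndarray, labels: np.ndarray) -> float:
    a, b, c = wc_fst_two_pops(genotypes[labels == 0], genotypes[labels == 1])
    denom = a + b + c
    return float(a / denom) if denom != 0 else math.nan


def fst_microsat_pairwise(
    geno: MicrosatGenotypes,
    partition: dict[str, str],
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> DifferentiationResult:
    """Multi-locus Weir-Cockerham theta with permutation of individuals."""
    rng = rng or np.random.default_rng()
    kept, labels = _labels_for(geno.sample_ids, partition, group_a, group_b)
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("each group needs at least 2 individuals")
    sub = geno.genotypes[kept]
    observed = _theta_from_geno(sub, labels)
    b = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        val = _theta_from_geno(sub, lab)
        if not math.isnan(val) and val >= observed - 1e-12:
            b += 1
    return DifferentiationResult("FST(microsat)", observed, (b + 1) / (n_perm + 1), n_perm)


def _rst_components(genotypes: np.ndarray, labels: np.ndarray) -> float:
    """R_ST: AMOVA on squared allele-size differences of gene copies,
    variance components summed across loci."""
    L = genotypes.shape[1]
    sig_a_sum = sig_w_sum = 0.0
    for j in range(L):
        copies, copy_labels = [], []
        for g in (0, 1):
            sub = genotypes[labels == g, j, :]
            typed = sub[(sub != MISSING_ALLELE).all(axis=1)]
            copies.append(typed.ravel().astype(float))
            copy_labels.append(np.full(typed.size, g))
        x = np.concatenate(copies)
        lab = np.concatenate(copy_labels)
        if len(x) < 3 or (lab == 0).sum() < 1 or (lab == 1).sum() < 1:
            continue
        d2 = (x[:, None] - x[None, :]) ** 2
        n = len(x)
        sizes = np.array([(lab == 0).sum(), (lab == 1).sum()], dtype=float)
        iu = np.triu_indices(n, 1)
        ss_total = d2[iu].sum() / n
        ss_within = 0.0
        for g in (0, 1):
            idx = np.flatnonzero(lab == g)
            if len(idx) > 1:
                subm = d2[np.ix_(idx, idx)]
                ss_within += subm[np.triu_indices(len(idx), 1)].sum() / len(idx)
        df_w = n - 2.0
        if df_w <= 0:
            continue
        sigma_w = ss_within / df_w
        n_prime = n - (sizes**2).sum() / n
        sigma_a = ((ss_total - ss_within) - sigma_w) / n_prime
        sig_a_sum += sigma_a
        sig_w_sum += sigma_w
    denom = sig_a_sum + sig_w_sum
    return float(sig_a_sum / denom) if denom != 0 else math.nan


def rst_pairwise(
    geno: MicrosatGenotypes,
    partition: dict[str, str],
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> DifferentiationResult:
    """Slatkin-type R_ST using allele-size variance components."""
    rng = rng or np.random.default_rng()
    kept, labels = _labels_for(geno.sample_ids, partition, group_a, group_b)
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("each group needs at least 2 individuals")
    sub = geno.genotypes[kept]
    observed = _rst_components(sub, labels)
    b = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        val = _rst_components(sub, lab)
        if not math.isnan(val) and val >= observed - 1e-12:
            b += 1
    return DifferentiationResult("RST", observed, (b + 1) / (n_perm + 1), n_perm)


def microsat_summary(
    geno: MicrosatGenotypes,
    partition: dict[str, str],
    rarefaction_g: int = 2,
    mc_reps: int = 10000,
    rng: np.random.Generator | None = None,
) -> list[MicrosatDiversity]:
    """Per-group Ho/He (locus mean +- sd), rarefied AR, multilocus Fis and
    HWE exact-test p-values (per locus and Fisher-combined)."""
    rng = rng or np.random.default_rng()
    groups: dict[str, list[str]] = {}
    for sid in geno.sample_ids:
        g = partition.get(sid)
        if g is not None:
            groups.setdefault(g, []).append(sid)
    out = []
    for g, ids in groups.items():
        sub = geno.subset(ids)
        hos, hes, ars, hwe_ps = [], [], [], {}
        for j, locus in enumerate(sub.locus_names):
            ho, he = observed_expected_het(sub.genotypes[:, j, :])
            counts = _locus_counts(sub.genotypes[:, j, :])
            if not counts:
                warnings.warn(f"locus {locus} untyped in group {g}; excluded")
                continue
            hos.append(ho)
            hes.append(he)
            N = sum(counts.values())
            ars.append(allelic_richness(counts, min(rarefaction_g, N)))
            hwe_ps[locus] = hwe_exact_mc(sub.genotypes[:, j, :], mc_reps, rng)
        try:
            fis = fis_wc(sub)
        except ValueError:
            fis = math.nan
        poly_ps = [p for p in hwe_ps.values() if not math.isnan(p)]
        global_p = fisher_combine(poly_ps) if poly_ps else math.nan
        out.append(
            MicrosatDiversity(
                group=g,
                n=sub.n,
                Ho=float(np.nanmean(hos)),
                Ho_sd=float(np.nanstd(hos)),
                He=float(np.nanmean(hes)),
                He_sd=float(np.nanstd(hes)),
                AR=float(np.nanmean(ars)),
                Fis=fis,
                hwe_p_per_locus=hwe_ps,
                hwe_p_global=global_p,
            )
        )
    return out


# ---------------------------------------------------------------------------
# exact tests


def _levene_log_prob(table: dict[tuple[int, int], int], m: dict[int, int]) -> float:
    """log P of a genotype-count table under the Levene conditional."""
    n = sum(table.values())
    het = sum(v for (a, b), v in table.items() if a != b)
    lp = gammaln(n + 1) + het * math.log(2.0)
    for cnt in table.values():
        lp -= gammaln(cnt + 1)
    for mi in m.values():
        lp += gammaln(mi + 1)
    lp -= gammaln(2 * n + 1)
    return float(lp)


def _genotype_table(geno: np.ndarray) -> dict[tuple[int, int], int]:
    typed = geno[(geno != MISSING_ALLELE).all(axis=1)]
    table: dict[tuple[int, int], int] = {}
    for a1, a2 in typed:
        key = (int(min(a1, a2)), int(max(a1, a2)))
        table[key] = table.get(key, 0) + 1
    return table


def _enumerate_hwe(
    alleles: list[int], m: dict[int, int], n: int
) -> list[tuple[dict[tuple[int, int], int], float]]:
    """All genotype tables with the given allele counts, with log probs."""
    pairs = [(alleles[i], alleles[j]) for i in range(len(alleles)) for j in range(i, len(alleles))]
    results: list[tuple[dict, float]] = []
    table: dict[tuple[int, int], int] = {}

    def rec(idx: int, remaining: dict[int, int]) -> None:
        if idx == len(pairs):
            if all(v == 0 for v in remaining.values()):
                results.append((dict(table), _levene_log_prob(table, m)))
            return
        a, b = pairs[idx]
        if a == b:
            max_c = remaining[a] // 2
        else:
            max_c = min(remaining[a], remaining[b])
        for c in range(max_c + 1):
            if c:
                table[(a, b)] = c
                remaining[a] -= c if a == b else c
                if a == b:
                    remaining[a] -= c
                else:
                    remaining[b] -= c
            rec(idx + 1, remaining)
            if c:
                remaining[a] += 2 * c if a == b else c
                if a != b:
                    remaining[b] += c
                del table[(a, b)]

    rec(0, dict(m))
    return results


def _hwe_config_count(m: dict[int, int]) -> float:
    """Loose upper bound on the number of genotype tables."""
    k = len(m)
    npairs = k * (k + 1) // 2
    n = sum(m.values()) // 2
    return math.comb(n + npairs - 1, npairs - 1)


def hwe_exact_mc(
    geno: np.ndarray,
    mc_reps: int = 10000,
    rng: np.random.Generator | None = None,
    enumerate_limit: int = 100000,
) -> float:
    """Hardy-Weinberg exact test p (probability-ordering criterion).

    Complete enumeration of the Levene conditional distribution when the
    configuration count is small, otherwise Monte-Carlo by random pairing
    of gene copies (which samples that distribution exactly), with the
    (b+1)/(B+1) estimator. Monomorphic data give p = 1.
    """
    rng = rng or np.random.default_rng()
    table = _genotype_table(geno)
    n = sum(table.values())
    if n < 2:
        raise ValueError("need at least 2 genotyped individuals")
    m: dict[int, int] = {}
    for (a, b), cnt in table.items():
        m[a] = m.get(a, 0) + cnt * (2 if a == b else 1)
        if a != b:
            m[b] = m.get(b, 0) + cnt
    if len(m) < 2:
        return 1.0
    obs_lp = _levene_log_prob(table, m)
    if _hwe_config_count(m) <= enumerate_limit:
        configs = _enumerate_hwe(sorted(m), m, n)
        total = sum(math.exp(lp) for _, lp in configs)
        p = sum(math.exp(lp) for _, lp in configs if lp <= obs_lp + 1e-9)
        return min(p / total, 1.0)
    copies = np.concatenate([[a] * c for a, c in m.items()]).astype(int)
    b_hits = 0
    for _ in range(mc_reps):
        rng.shuffle(copies)
        sim = copies.reshape(n, 2)
        sim_table = _genotype_table(sim)
        if _levene_log_prob(sim_table, m) <= obs_lp + 1e-9:
            b_hits += 1
    return (b_hits + 1) / (mc_reps + 1)


def _table_log_prob(table: np.ndarray, row_sums, col_sums, n) -> float:
    """Fixed-margins (multivariate hypergeometric) log probability."""
    lp = sum(gammaln(r + 1) for r in row_sums) + sum(gammaln(c + 1) for c in col_sums)
    lp -= gammaln(n + 1)
    lp -= gammaln(table + 1).sum()
    return float(lp)


def genic_diff_exact_mc(
    table: np.ndarray,
    mc_reps: int = 10000,
    rng: np.random.Generator | None = None,
    enumerate_limit: int = 100000,
) -> float:
    """Probability test of genic differentiation on a 2 x k allele-count table.

    p = total probability (margins fixed) of tables no more probable than
    the observed one; exact enumeration for small tables, otherwise
    Monte-Carlo permutation of gene copies with (b+1)/(B+1).
    """
    rng = rng or np.random.default_rng()
    table = np.asarray(table, dtype=int)
    if table.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise ValueError("degenerate margins")
    n = int(table.sum())
    obs_lp = _table_log_prob(table, row_sums, col_sums, n)
    k = table.shape[1]
    n_configs = float(np.prod([min(row_sums[0], c) + 1 for c in col_sums]))
    if n_configs <= enumerate_limit:
        total = p = 0.0
        first_rows = _enumerate_first_rows(row_sums[0], col_sums)
        for r0 in first_rows:
            t = np.vstack([r0, col_sums - r0])
            lp = _table_log_prob(t, row_sums, col_sums, n)
            pr = math.exp(lp)
            total += pr
            if lp <= obs_lp + 1e-9:
                p += pr
        return min(p / total, 1.0)
    copies = np.concatenate([[j] * c for j, c in enumerate(col_sums)]).astype(int)
    b_hits = 0
    for _ in range(mc_reps):
        rng.shuffle(copies)
        r0 = np.bincount(copies[: row_sums[0]], minlength=k)
        t = np.vstack([r0, col_sums - r0])
        if _table_log_prob(t, row_sums, col_sums, n) <= obs_lp + 1e-9:
            b_hits += 1
    return (b_hits + 1) / (mc_reps + 1)


def _enumerate_first_rows(r0_total: int, col_sums: np.ndarray) -> list[np.ndarray]:
    rows: list[np.ndarray] = []
    k = len(col_sums)
    cur = np.zeros(k, dtype=int)

    def rec(j: int, remaining: int) -> None:
        if j == k - 1:
            if remaining <= col_sums[j]:
                cur[j] = remaining
                rows.append(cur.copy())
            return
        for v in range(min(remaining, col_sums[j]) + 1):
            cur[j] = v
            rec(j + 1, remaining - v)

    rec(0, int(r0_total))
    return rows


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method across independent tests (e.g. loci)."""
    from scipy.stats import chi2

    ps = np.clip(np.asarray(p_values, dtype=float), 1e-300, 1.0)
    stat = -2.0 * np.log(ps).sum()
    return float(chi2.sf(stat, 2 * len(ps)))


# ---------------------------------------------------------------------------
# isolation by distance


def great_circle_km(
    lat1: float, lon1: float, lat2: float, lon2: float, radius_km: float = 6371.0
) -> float:
    """Haversine great-circle distance on a sphere of radius 6371 km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * radius_km * math.asin(min(1.0, math.sqrt(a)))


def mantel_ibd(
    diff: np.ndarray,
    geo_km: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mantel test of F_ST/(1-F_ST) against ln(great-circle km).

    ``diff`` holds pairwise differentiation values (F_ST-like, clamped to
    0 from below for the linearisation); pairs with diff == 1 are
    excluded with a warning (infinite linearised value). Returns
    (r_squared, upper-tail permutation p on r).
    """
    rng = rng or np.random.default_rng()
    diff = np.asarray(diff, dtype=float)
    geo_km = np.asarray(geo_km, dtype=float)
    if diff.shape != geo_km.shape or diff.shape[0] != diff.shape[1]:
        raise ValueError("matrices must be square and matched")
    n = diff.shape[0]
    if n < 3:
        raise ValueError("need at least 3 units")
    if np.any(np.isclose(diff, 1.0)):
        warnings.warn("differentiation of 1 found; those pairs are excluded")
    lin = np.clip(diff, 0.0, None) / (1.0 - np.clip(diff, 0.0, None))
    with np.errstate(divide="ignore"):
        log_geo = np.log(geo_km)
    iu = np.triu_indices(n, 1)
    ok = np.isfinite(lin[iu]) & np.isfinite(log_geo[iu])

    def corr(perm: np.ndarray) -> float:
        lp = lin[np.ix_(perm, perm)][iu][ok]
        gp = log_geo[iu][ok]
        if lp.std() == 0 or gp.std() == 0:
            return 0.0
        return float(np.corrcoef(lp, gp)[0, 1])

    observed = corr(np.arange(n))
    b = 0
    perm = np.arange(n)
    for _ in range(n_perm):
        rng.shuffle(perm)
        if corr(perm) >= observed - 1e-12:
            b += 1
    return observed**2, (b + 1) / (n_perm + 1)
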