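"""Approximate Bayesian Computation: scenario families, priors, summary
statistics, reference tables, rejection, logistic-regression model choice
and local-linear posterior estimation.

The analysis tests the origin of one focal population group against ten
competing histories over four extant groups plus an unsampled ancestral
population (AP): direct divergence from AP; origin from each of the three
other current groups; admixture between AP and each current group; and
admixture between each pair of current groups. The non-focal backbone
(each other group diverging from the AP lineage at its own time) is
identical across the ten scenarios, so the comparison isolates the focal
group's origin.

Workflow: draw parameters from the priors, simulate a multilocus dataset
per draw, reduce it to a fixed vector of summary statistics, keep the 1%
of simulations closest to the observed vector in normalised Euclidean
distance, fit a ridge-penalised multinomial logistic regression of
scenario on statistics over the accepted set, and read posterior scenario
probabilities (with asymptotic confidence intervals) at the observed
point. Parameters are then estimated from the best scenario's accepted
rows by Beaumont-style local-linear regression adjustment.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .io import ReferenceTable
from .sim import (
    Admixture,
    DemographicScenario,
    Divergence,
    MutationModel,
    SyntheticDataset,
    _genealogies,
    hky_mutated_ts,
    mutate_microsats_gsm,
    validate_scenario,
)

__all__ = [
    "DEFAULT_GROUPS",
    "PriorSpec",
    "PriorSet",
    "default_priors",
    "ScenarioTemplate",
    "build_scenario_family",
    "sample_priors",
    "SummaryVector",
    "summary_stat_names",
    "summarize_dataset",
    "simulate_summary",
    "build_reference_table",
    "PcaPriorCheck",
    "pca_prior_check",
    "reject_closest",
    "ModelChoiceResult",
    "model_choice_logistic",
    "PosteriorEstimate",
    "prior_bounds",
    "estimate_parameters_loclinear",
]

DEFAULT_GROUPS = ["W", "C", "N", "NE"]


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorSpec:
    """One marginal prior: uniform, log-uniform (uniform on log10 scale),
    gridded uniform (``step``) or a point mass (``fixed``)."""

    kind: str  # uniform | loguniform | fixed
    lo: float
    hi: float
    step: float | None = None

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return self.lo
        if self.kind == "uniform":
            x = rng.uniform(self.lo, self.hi)
        elif self.kind == "loguniform":
            x = 10 ** rng.uniform(math.log10(self.lo), math.log10(self.hi))
        else:
            raise ValueError(f"unknown prior kind {self.kind}")
        if self.step:
            x = round(x / self.step) * self.step
            x = min(max(x, self.lo), self.hi)
        return float(x)


@dataclass
class PriorSet:
    """Marginal priors for sizes, event times, admixture rate and the
    mutation-model means, plus strict ordering constraints "a < b"."""

    size: PriorSpec = field(default_factory=lambda: PriorSpec("uniform", 10, 50000, step=1))
    time: PriorSpec = field(default_factory=lambda: PriorSpec("loguniform", 10, 5e6))
    admixture: PriorSpec = field(
        default_factory=lambda: PriorSpec("uniform", 0.001, 0.999, step=0.001)
    )
    ms_mean_rate: PriorSpec = field(default_factory=lambda: PriorSpec("uniform", 1e-4, 1e-3))
    ms_mean_p: PriorSpec = field(default_factory=lambda: PriorSpec("uniform", 0.1, 0.3))
    sni_rate: PriorSpec = field(default_factory=lambda: PriorSpec("fixed", 0.0, 0.0))
    mt_rate: PriorSpec = field(default_factory=lambda: PriorSpec("uniform", 1e-8, 1e-7))
    kappa: PriorSpec = field(default_factory=lambda: PriorSpec("uniform", 0.05, 20.0))


def default_priors() -> PriorSet:
    """The default prior set used throughout (sizes uniform [10, 5e4],
    times log-uniform [10, 5e6] generations, ra uniform on the 0.001 grid,
    microsatellite mean rate uniform [1e-4, 1e-3] with geometric
    coefficient uniform [0.1, 0.3], mtDNA mean rate uniform [1e-8, 1e-7]
    with kappa uniform [0.05, 20])."""
    return PriorSet()


# ---------------------------------------------------------------------------
# scenario family


@dataclass
class ScenarioTemplate:
    """A parameter-free description of one competing history.

    ``kind`` is one of ``from_ap`` (direct divergence from the ancestral
    population), ``from_group`` (origin from one current group),
    ``admix_ap`` (admixture between AP and one current group) and
    ``admix_pair`` (admixture between two current groups).
    ``constraints`` are strict "a < b" orderings among time parameters.
    """

    scenario_id: str
    label: str
    focal: str
    others: list[str]  # backbone order, oldest first
    kind: str
    partners: tuple[str, ...]
    sample_config: dict[str, tuple[int, int]]
    constraints: list[tuple[str, str]]

    @property
    def groups(self) -> list[str]:
        return self.others + [self.focal]

    @property
    def time_param(self) -> str:
        if self.kind == "from_ap":
            return f"T_{self.focal}"
        return "T_" + "".join(self.partners) + self.focal

    @property
    def param_names(self) -> list[str]:
        names = [f"N_{p}" for p in ["AP"] + self.groups]
        names += [f"T_{o}" for o in self.others]
        names.append(self.time_param)
        if self.kind.startswith("admix"):
            names.append("ra")
        names += ["mt_rate", "kappa", "ms_mean_rate", "ms_mean_p"]
        return names

    def instantiate(self, params: dict[str, float]) -> DemographicScenario:
        sizes = {p: params[f"N_{p}"] for p in ["AP"] + self.groups}
        events: list[Divergence | Admixture] = [
            Divergence(params[f"T_{o}"], o, "AP") for o in self.others
        ]
        t = params[self.time_param]
        if self.kind == "from_ap":
            events.append(Divergence(t, self.focal, "AP"))
        elif self.kind == "from_group":
            events.append(Divergence(t, self.focal, self.partners[0]))
        else:
            s1, s2 = self.partners
            events.append(Admixture(t, self.focal, s1, s2, params["ra"]))
        return validate_scenario(
            DemographicScenario(
                self.scenario_id,
                ["AP"] + self.groups,
                sizes,
                events,
                dict(self.sample_config),
            )
        )

    def mutation_model(self, params: dict[str, float], **kwargs) -> MutationModel:
        return MutationModel(
            mt_rate=params["mt_rate"],
            kappa=params["kappa"],
            ms_mean_rate=params["ms_mean_rate"],
            ms_mean_p=params["ms_mean_p"],
            **kwargs,
        )


def build_scenario_family(
    focal: str,
    group_set: Sequence[str] = DEFAULT_GROUPS,
    sample_config: dict[str, tuple[int, int]] | None = None,
    backbone_order: Sequence[str] = DEFAULT_GROUPS,
) -> list[ScenarioTemplate]:
    """The ten competing scenarios for the origin of ``focal``.

    Scenario 1: focal diverges directly from AP. Scenarios 2-4: focal
    originates from each other current group, at a time constrained to be
    younger than that group's own divergence. Scenarios 5-7: admixture
    between AP and each current group. Scenarios 8-10: admixture between
    each pair of current groups (constrained younger than both partners'
    divergences). The non-focal backbone (others diverging from AP, with
    the given age order, oldest first) is identical across all ten.
    """
    if focal not in group_set:
        raise ValueError(f"focal group {focal} not in {list(group_set)}")
    others = [g for g in backbone_order if g in group_set and g != focal]
    if len(others) != len(group_set) - 1:
        raise ValueError("backbone_order must cover the non-focal groups")
    sample_config = sample_config or {g: (10, 10) for g in group_set}
    backbone = [(f"T_{b}", f"T_{a}") for a, b in zip(others, others[1:])]

    def make(idx: int, kind: str, partners: tuple[str, ...], label: str, extra):
        return ScenarioTemplate(
            scenario_id=f"{focal}.{idx}",
            label=label,
            focal=focal,
            others=others,
            kind=kind,
            partners=partners,
            sample_config=sample_config,
            constraints=backbone + extra,
        )

    fam = [make(1, "from_ap", (), "Only from AP", [])]
    idx = 2
    # origin from each current group, youngest backbone group first
    for src in reversed(others):
        t = f"T_{src}{focal}"
        fam.append(make(idx, "from_group", (src,), f"Only from {src}", [(t, f"T_{src}")]))
        idx += 1
    for src in reversed(others):
        t = f"T_AP{src}{focal}"
        fam.append(make(idx, "admix_ap", ("AP", src), f"Mix AP+{src}", [(t, f"T_{src}")]))
        idx += 1
    for s1, s2 in itertools.combinations(list(reversed(others)), 2):
        t = f"T_{s1}{s2}{focal}"
        fam.append(
            make(
                idx,
                "admix_pair",
                (s1, s2),
                f"Mix {s1}+{s2}",
                [(t, f"T_{s1}"), (t, f"T_{s2}")],
            )
        )
        idx += 1
    return fam


def sample_priors(
    prior_set: PriorSet,
    template: ScenarioTemplate,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> dict[str, float]:
    """Independent draws for every parameter of the template's scenario;
    ordering constraints are enforced by resampling only the offending
    time parameters. Raises after ``max_tries`` consecutive rejections."""
    params: dict[str, float] = {}
    for name in template.param_names:
        if name.startswith("N_"):
            params[name] = prior_set.size.draw(rng)
        elif name.startswith("T_"):
            params[name] = prior_set.time.draw(rng)
        elif name == "ra":
            params[name] = prior_set.admixture.draw(rng)
        else:
            params[name] = getattr(prior_set, name).draw(rng)
    for _ in range(max_tries):
        bad: set[str] = set()
        for small, big in template.constraints:
            if not params[small] < params[big]:
                bad.update((small, big))
        if not bad:
            return params
        # deterministic order: set iteration depends on the hash seed
        for name in sorted(bad):
            params[name] = prior_set.time.draw(rng)
    raise RuntimeError(
        f"{template.scenario_id}: constraints unsatisfiable after {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# summary statistics


def summary_stat_names(groups: Sequence[str]) -> list[str]:
    """Fixed ordering of the summary-statistic vector for these groups."""
    names = []
    for g in groups:
        names += [
            f"mt_nhap_{g}",
            f"mt_segsites_{g}",
            f"mt_pwdiff_mean_{g}",
            f"mt_pwdiff_var_{g}",
            f"mt_privsites_{g}",
            f"ms_nalleles_{g}",
            f"ms_he_{g}",
            f"ms_sizevar_{g}",
            f"ms_gw_{g}",
        ]
    for a, b in itertools.combinations(groups, 2):
        names += [
            f"mt_fst_{a}_{b}",
            f"mt_pwdiff_{a}_{b}",
            f"ms_fst_{a}_{b}",
            f"ms_lik_{a}_{b}",
        ]
    return names


@dataclass
class SummaryVector:
    names: list[str]
    values: np.ndarray
    n_imputed: int = 0

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


# heavy-tailed count/variance statistics enter the vector on the log1p
# scale: their prior-predictive distributions span orders of magnitude,
# and a variance-stabilised scale keeps the normalised Euclidean
# distance and the local regressions from being dominated by the tails
_LOG_STAT_PREFIXES = ("mt_pwdiff", "mt_segsites", "mt_privsites", "ms_sizevar")


def _log_stat_mask(names: Sequence[str]) -> np.ndarray:
    return np.array([n.startswith(_LOG_STAT_PREFIXES) for n in names])


def _identity_fst_from_counts(ca: np.ndarray, cb: np.ndarray) -> float:
    """Haplotype-identity AMOVA F_ST between two groups given counts of
    shared haplotype classes. NaN when undefined (no variation)."""
    na, nb = ca.sum(), cb.sum()
    n = na + nb
    if na < 2 or nb < 2:
        return math.nan

    def ss(c: np.ndarray, tot: float) -> float:
        # sum over pairs of identity distance = (tot^2 - sum c^2) / 2
        return (tot**2 - float((c.astype(float) ** 2).sum())) / 2.0

    ct = ca + cb
    ss_total = ss(ct, n) / n
    ss_within = ss(ca, na) / na + ss(cb, nb) / nb
    df_w = n - 2.0
    sigma_w = ss_within / df_w
    n_prime = n - (na**2 + nb**2) / n
    sigma_a = ((ss_total - ss_within) - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    return float(sigma_a / denom) if denom != 0 else math.nan


def _wc_theta_sums(na, ca, ha, nb, cb, hb, mask) -> tuple[float, float, float]:
    """Weir-Cockerham variance components summed over loci and alleles.

    ``ca/ha`` etc. are padded (n_loci, max_alleles) allele-copy and
    heterozygote counts; ``na/nb`` scalar individual counts; ``mask``
    marks real allele slots.
    """
    if min(na, nb) < 1:
        return 0.0, 0.0, 0.0
    r = 2
    ns = np.array([na, nb], dtype=float)
    nbar = ns.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    pa, pb = ca / (2.0 * na), cb / (2.0 * nb)
    hfa, hfb = ha / na, hb / nb
    pbar = (na * pa + nb * pb) / (r * nbar)
    s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (na * hfa + nb * hfb) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return float(a[mask].sum()), float(b[mask].sum()), float(c[mask].sum())


def _summaries_from_matrices(
    mt: np.ndarray,
    mt_group_sizes: Sequence[int],
    ms_genotypes: np.ndarray,
    ms_group_sizes: Sequence[int],
    groups: Sequence[str],
) -> SummaryVector:
    """Core summary computation.

    ``mt``: (n_seq, n_sites) comparable codes (only equality is used);
    ``ms_genotypes``: (n_ind, n_loci, 2) allele sizes; group blocks are
    contiguous in the given order. Degenerate statistics (monomorphic
    comparisons) are imputed as 0 and counted.
    """
    imputed = 0
    values: list[float] = []
    G = len(groups)
    mt_bounds = np.concatenate([[0], np.cumsum(mt_group_sizes)])
    ms_bounds = np.concatenate([[0], np.cumsum(ms_group_sizes)])

    # collapse to unique haplotypes once
    _, hap_codes = np.unique(mt, axis=0, return_inverse=True)
    K = int(hap_codes.max()) + 1
    uniq_rows = np.empty((K, mt.shape[1]), dtype=mt.dtype)
    uniq_rows[hap_codes] = mt
    D = (uniq_rows[:, None, :] != uniq_rows[None, :, :]).sum(axis=2).astype(float)

    var_mask = []
    counts = []
    for g in range(G):
        rows = mt[mt_bounds[g] : mt_bounds[g + 1]]
        var_mask.append((rows != rows[:1]).any(axis=0))
        c = np.bincount(hap_codes[mt_bounds[g] : mt_bounds[g + 1]], minlength=K)
        counts.append(c.astype(float))
    var_any = np.vstack(var_mask)

    # per-locus microsat tallies on a padded (n_loci, max_alleles) grid
    n_loci = ms_genotypes.shape[1]
    locus_alleles = [np.unique(ms_genotypes[:, j, :]) for j in range(n_loci)]
    A_max = max(len(a) for a in locus_alleles)
    alleles_pad = np.zeros((n_loci, A_max))
    amask = np.zeros((n_loci, A_max), dtype=bool)
    idx0 = np.empty((ms_genotypes.shape[0], n_loci), dtype=int)
    idx1 = np.empty_like(idx0)
    for j, alleles in enumerate(locus_alleles):
        alleles_pad[j, : len(alleles)] = alleles
        amask[j, : len(alleles)] = True
        idx0[:, j] = np.searchsorted(alleles, ms_genotypes[:, j, 0])
        idx1[:, j] = np.searchsorted(alleles, ms_genotypes[:, j, 1])
    cnt = np.zeros((G, n_loci, A_max))  # gene-copy counts
    het = np.zeros((G, n_loci, A_max))  # heterozygote counts per allele
    jj = np.broadcast_to(np.arange(n_loci), idx0.shape)
    for g in range(G):
        sl = slice(ms_bounds[g], ms_bounds[g + 1])
        np.add.at(cnt[g], (jj[sl], idx0[sl]), 1.0)
        np.add.at(cnt[g], (jj[sl], idx1[sl]), 1.0)
        het_mask = (idx0[sl] != idx1[sl]).astype(float)
        np.add.at(het[g], (jj[sl], idx0[sl]), het_mask)
        np.add.at(het[g], (jj[sl], idx1[sl]), het_mask)

    def impute(x: float) -> float:
        nonlocal imputed
        if not math.isfinite(x):
            imputed += 1
            return 0.0
        return x

    for g in range(G):
        n_mt = mt_group_sizes[g]
        c = counts[g]
        nhap = float((c > 0).sum())
        S_g = float(var_mask[g].sum())
        others_var = var_any[np.arange(G) != g].any(axis=0)
        priv = float((var_mask[g] & ~others_var).sum())
        pairs = n_mt * (n_mt - 1) / 2.0
        if pairs > 0:
            mean_d = float(c @ D @ c) / 2.0 / pairs
            var_d = max(float(c @ (D**2) @ c) / 2.0 / pairs - mean_d**2, 0.0)
        else:
            mean_d = var_d = 0.0
        # microsats: per-locus values then mean over loci
        tot = cnt[g].sum(axis=1)  # (n_loci,)
        ok = tot >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            k_here = (cnt[g] > 0).sum(axis=1).astype(float)
            p = cnt[g] / np.clip(tot[:, None], 1.0, None)
            he_l = tot / (tot - 1.0) * (1.0 - (p**2).sum(axis=1))
            mean_sz = (alleles_pad * cnt[g]).sum(axis=1) / np.clip(tot, 1.0, None)
            var_l = (cnt[g] * (alleles_pad - mean_sz[:, None]) ** 2).sum(axis=1) / (
                tot - 1.0
            )
            lo_sz = np.where(amask & (cnt[g] > 0), alleles_pad, np.inf).min(axis=1)
            hi_sz = np.where(amask & (cnt[g] > 0), alleles_pad, -np.inf).max(axis=1)
            gw_l = k_here / (hi_sz - lo_sz + 1.0)
        values += [
            nhap,
            S_g,
            mean_d,
            var_d,
            priv,
            impute(float(k_here[ok].mean()) if ok.any() else math.nan),
            impute(float(he_l[ok].mean()) if ok.any() else math.nan),
            impute(float(var_l[ok].mean()) if ok.any() else math.nan),
            impute(float(gw_l[ok].mean()) if ok.any() else math.nan),
        ]

    log2 = math.log(2.0)
    for a, b in itertools.combinations(range(G), 2):
        values.append(impute(_identity_fst_from_counts(counts[a], counts[b])))
        na, nb = mt_group_sizes[a], mt_group_sizes[b]
        cross = float(counts[a] @ D @ counts[b]) / (na * nb) if na * nb else 0.0
        values.append(impute(cross))
        n_a, n_b = ms_group_sizes[a], ms_group_sizes[b]
        wa, wb, wc_ = _wc_theta_sums(n_a, cnt[a], het[a], n_b, cnt[b], het[b], amask)
        denom = wa + wb + wc_
        values.append(impute(wa / denom if denom != 0 else math.nan))
        # classification index: mean assignment log-likelihood, symmetrised
        k_tot = amask.sum(axis=1).astype(float)  # alleles per locus overall
        ci_dirs = []
        for i, j in ((a, b), (b, a)):
            n_i = ms_group_sizes[i]
            if n_i == 0:
                ci_dirs.append(math.nan)
                continue
            with np.errstate(divide="ignore"):
                pj = (cnt[j] + 1.0 / k_tot[:, None]) / (
                    cnt[j].sum(axis=1)[:, None] + 1.0
                )
                logp = np.log(pj)
            sl = slice(ms_bounds[i], ms_bounds[i + 1])
            ll = logp[jj[sl], idx0[sl]] + logp[jj[sl], idx1[sl]]
            ll = ll + np.where(idx0[sl] != idx1[sl], log2, 0.0)
            ci_dirs.append(float(ll.sum()) / n_i)
        values.append(impute(0.5 * (ci_dirs[0] + ci_dirs[1])))

    names = summary_stat_names(groups)
    out = np.array(values, dtype=float)
    mask = _log_stat_mask(names)
    out[mask] = np.log1p(np.clip(out[mask], 0.0, None))
    return SummaryVector(names, out, imputed)


def summarize_dataset(
    dataset: SyntheticDataset,
    groups: Sequence[str] | None = None,
) -> SummaryVector:
    """Summary-statistic vector of one dataset (observed or simulated).

    Group blocks are taken from the dataset's sample table; ``groups``
    fixes the group ordering (defaults to order of first appearance).
    Count/variance-type entries are log1p-scaled (see
    ``_LOG_STAT_PREFIXES``); bounded statistics stay on their natural
    scale.
    """
    table = dataset.sample_table
    groups = list(groups) if groups else table.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    group_of = table.group_of()

    aln = dataset.alignment
    mt_ids = [s for g in groups for s in aln.sample_ids if group_of.get(s) == g]
    aln_sorted = aln.subset(mt_ids)
    mt_sizes = [sum(1 for s in mt_ids if group_of[s] == g) for g in groups]
    if min(mt_sizes) == 0:
        raise ValueError("a group has no sequences")

    geno = dataset.genotypes
    ind_ids = [s for g in groups for s in geno.sample_ids if group_of.get(s) == g]
    geno_sorted = geno.subset(ind_ids)
    ms_sizes = [sum(1 for s in ind_ids if group_of[s] == g) for g in groups]

    return _summaries_from_matrices(
        aln_sorted.to_array(), mt_sizes, geno_sorted.genotypes, ms_sizes, groups
    )


def simulate_summary(
    template: ScenarioTemplate,
    params: dict[str, float],
    rng: np.random.Generator,
    mut_kwargs: dict | None = None,
) -> SummaryVector:
    """Simulate one dataset under the template and reduce it directly to
    summary statistics (no FASTA/GENEPOP materialisation).

    Follows the same simulation calls as
    :func:`karstabc.sim.simulate_dataset`; only the extraction differs.
    """
    scenario = template.instantiate(params)
    mut = template.mutation_model(params, **(mut_kwargs or {}))
    groups = template.groups
    mt_sizes = [scenario.sample_config[g][0] for g in groups]
    ms_sizes = [scenario.sample_config[g][1] for g in groups]

    # the sample-set order in sim follows scenario.populations = [AP] + groups
    ts_mt = _genealogies(scenario, "mtDNA", rng, sequence_length=mut.seq_length)
    mts = hky_mutated_ts(ts_mt, mut, rng)
    Gmat = mts.genotype_matrix().T  # (n_seq, S); equality-comparable codes
    if Gmat.shape[1] == 0:
        Gmat = np.zeros((sum(mt_sizes), 1), dtype=np.int8)

    rates, ps = mut.draw_locus_params(rng)
    n_ind = sum(ms_sizes)
    geno = np.zeros((n_ind, mut.n_loci, 2), dtype=int)
    replicates = _genealogies(scenario, "autosomal", rng, 1, num_replicates=mut.n_loci)
    for j, ts in enumerate(replicates):
        sizes = mutate_microsats_gsm(
            ts, rates[j], ps[j], rng, n_states=mut.n_states, root_state=mut.root_state
        )
        geno[:, j, :] = sizes.reshape(n_ind, 2)
    return _summaries_from_matrices(Gmat, mt_sizes, geno, ms_sizes, groups)


# ---------------------------------------------------------------------------
# reference table


def _reference_rows(
    template: ScenarioTemplate,
    s_idx: int,
    rows: range,
    prior_set: PriorSet,
    seed: int,
    param_names: list[str],
    mut_kwargs: dict | None,
) -> tuple[list[list[float]], list[np.ndarray]]:
    params_rows, stats_rows = [], []
    for row in rows:
        rng = np.random.default_rng([seed, s_idx, row])
        params = sample_priors(prior_set, template, rng)
        sv = simulate_summary(template, params, rng, mut_kwargs)
        params_rows.append([params.get(p, math.nan) for p in param_names])
        stats_rows.append(sv.values)
    return params_rows, stats_rows


def build_reference_table(
    templates: Sequence[ScenarioTemplate],
    prior_set: PriorSet,
    n_per_scenario: int,
    seed: int,
    mut_kwargs: dict | None = None,
    progress: Callable[[int, int], None] | None = None,
    threads: int = 1,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` rows per scenario.

    Every row runs on an independent RNG substream keyed by
    (seed, scenario index, row index), so any row can be regenerated in
    isolation and chunks can be produced in parallel (``threads`` > 1
    farms row chunks out with joblib) and concatenated deterministically.
    """
    if not templates:
        raise ValueError("no scenarios")
    param_names = sorted({p for t in templates for p in t.param_names})
    stat_names = summary_stat_names(templates[0].groups)
    total = len(templates) * n_per_scenario
    scen_ids, params_rows, stats_rows = [], [], []
    if threads > 1:
        from joblib import Parallel, delayed

        chunk = max(50, n_per_scenario // (4 * threads))
        jobs = [
            (t, s_idx, range(lo, min(lo + chunk, n_per_scenario)))
            for s_idx, t in enumerate(templates)
            for lo in range(0, n_per_scenario, chunk)
        ]
        results = Parallel(n_jobs=threads)(
            delayed(_reference_rows)(t, s_idx, rows, prior_set, seed,
                                     param_names, mut_kwargs)
            for t, s_idx, rows in jobs
        )
        for (t, _, rows), (p_rows, s_rows) in zip(jobs, results):
            scen_ids += [t.scenario_id] * len(rows)
            params_rows += p_rows
            stats_rows += s_rows
    else:
        done = 0
        for s_idx, template in enumerate(templates):
            p_rows, s_rows = [], []
            for row in range(n_per_scenario):
                rng = np.random.default_rng([seed, s_idx, row])
                params = sample_priors(prior_set, template, rng)
                sv = simulate_summary(template, params, rng, mut_kwargs)
                p_rows.append([params.get(p, math.nan) for p in param_names])
                s_rows.append(sv.values)
                done += 1
                if progress and done % 200 == 0:
                    progress(done, total)
            scen_ids += [template.scenario_id] * n_per_scenario
            params_rows += p_rows
            stats_rows += s_rows
    return ReferenceTable(
        np.array(scen_ids, dtype=object),
        param_names,
        np.array(params_rows, dtype=float),
        stat_names,
        np.vstack(stats_rows),
    )


# ---------------------------------------------------------------------------
# rejection and model choice


@dataclass
class PcaPriorCheck:
    inside: bool
    within_ranges: bool
    mahalanobis: float
    mahalanobis_q99: float
    dropped_stats: list[str]


def pca_prior_check(
    table: ReferenceTable, observed: SummaryVector, n_rows: int = 10_000
) -> PcaPriorCheck:
    """Do the priors generate data like the observed data?

    PCA on the first ``n_rows`` normalised simulated statistic vectors;
    the observed vector must fall inside every statistic's simulated
    range and within the 99th percentile of Mahalanobis distance in the
    first-two-PC plane.
    """
    from sklearn.decomposition import PCA

    X = table.stats[:n_rows]
    keep = X.std(axis=0) > 0
    dropped = [n for n, k in zip(table.stat_names, keep) if not k]
    if dropped:
        warnings.warn(f"zero-variance statistics dropped: {dropped}")
    Xk = (X[:, keep] - X[:, keep].mean(axis=0)) / X[:, keep].std(axis=0)
    obs = observed.values[keep]
    within = bool(
        np.all(obs >= X[:, keep].min(axis=0)) and np.all(obs <= X[:, keep].max(axis=0))
    )
    obs_n = (obs - X[:, keep].mean(axis=0)) / X[:, keep].std(axis=0)
    pca = PCA(n_components=min(2, Xk.shape[1]))
    P = pca.fit_transform(Xk)
    obs_p = pca.transform(obs_n[None, :])[0]
    cov = np.cov(P.T) if P.shape[1] > 1 else np.atleast_2d(np.var(P[:, 0]))
    icov = np.linalg.pinv(np.atleast_2d(cov))
    diffs = P - P.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", diffs, icov, diffs)
    od = obs_p - P.mean(axis=0)
    obs_d2 = float(od @ icov @ od)
    q99 = float(np.quantile(d2, 0.99))
    return PcaPriorCheck(within and obs_d2 <= q99, within, obs_d2, q99, dropped)


def reject_closest(
    table: ReferenceTable, observed: SummaryVector, tolerance: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the closest ``tolerance`` fraction of rows.

    Distance is Euclidean over statistics centred on the observed vector
    and scaled by the table's stored normalisation constants. Ties are
    broken by row order.
    """
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must be in (0, 1]")
    z = (table.stats - observed.values[None, :]) / table.norm[None, :]
    d = np.sqrt((z**2).sum(axis=1))
    n_keep = math.ceil(tolerance * table.n_rows)
    order = np.argsort(d, kind="stable")[:n_keep]
    return order, d[order]


@dataclass
class ModelChoiceResult:
    probabilities: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    accepted_counts: dict[str, int]
    degenerate: bool = False

    @property
    def best(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)


def _fit_multinomial_ridge(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    ridge: float,
    sample_weight: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference-class multinomial logistic with L2 penalty.

    Returns (W, H) where W is ((k-1), d) coefficients (class 0 is the
    reference) and H the penalised Hessian of the negative log-likelihood
    at the optimum (for asymptotic covariances). The intercept column
    (assumed first) is not penalised.
    """
    m, d = X.shape
    Y = np.zeros((m, k))
    Y[np.arange(m), y] = 1.0
    sw = np.ones(m) if sample_weight is None else np.asarray(sample_weight, float)
    pen = np.ones(d)
    pen[0] = 0.0  # intercept unpenalised

    def unpack(w):
        return w.reshape(k - 1, d)

    def probs(W):
        eta = np.hstack([np.zeros((m, 1)), X @ W.T])
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def nll_grad(w):
        W = unpack(w)
        P = probs(W)
        ll = float(sw @ np.sum(Y * np.log(np.clip(P, 1e-300, None)), axis=1))
        nll = -ll + 0.5 * ridge * float(((W**2) * pen).sum())
        G = ((P[:, 1:] - Y[:, 1:]) * sw[:, None]).T @ X + ridge * W * pen
        return nll, G.ravel()

    w0 = np.zeros((k - 1) * d)
    res = minimize(nll_grad, w0, jac=True, method="L-BFGS-B", options={"maxiter": 500})
    W = unpack(res.x)
    P = probs(W)
    H = np.zeros(((k - 1) * d, (k - 1) * d))
    for a in range(1, k):
        for b in range(1, k):
            w_ab = sw * P[:, a] * ((a == b) - P[:, b])
            block = (X * w_ab[:, None]).T @ X
            H[(a - 1) * d : a * d, (b - 1) * d : b * d] = block + ridge * np.diag(pen) * (
                a == b
            )
    return W, H


def model_choice_logistic(
    table: ReferenceTable,
    accepted: np.ndarray,
    observed: SummaryVector,
    scenario_ids: Sequence[str] | None = None,
    ridge: float = 1.0,
    distances: np.ndarray | None = None,
) -> ModelChoiceResult:
    """Posterior scenario probabilities at the observed statistics.

    Multinomial logistic regression of the scenario indicator on the
    normalised, observed-centred summary statistics over the accepted
    rows; evaluated at the observed point (the regression intercept).
    95% confidence intervals come from the asymptotic covariance of the
    linear predictors mapped through the softmax (delta method). A small
    ridge penalty keeps the fit defined under complete separation.
    """
    scenario_ids = list(scenario_ids) if scenario_ids else sorted(set(table.scenario_ids))
    labels = table.scenario_ids[accepted]
    counts = {s: int((labels == s).sum()) for s in scenario_ids}
    present = [s for s in scenario_ids if counts[s] > 0]
    if len(present) < 2:
        probs = {s: 1.0 if s in present else 0.0 for s in scenario_ids}
        cis = {s: (p, p) for s, p in probs.items()}
        return ModelChoiceResult(probs, cis, counts, degenerate=True)

    z = (table.stats[accepted] - observed.values[None, :]) / table.norm[None, :]
    X = np.hstack([np.ones((len(accepted), 1)), z])
    class_of = {s: i for i, s in enumerate(present)}
    y = np.array([class_of[s] for s in labels])
    k, d = len(present), X.shape[1]
    sw = None
    if distances is not None:
        dmax = distances.max()
        sw = 1.0 - (distances / dmax) ** 2 if dmax > 0 else None
        if sw is not None:
            sw = np.clip(sw, 1e-6, None)
    W, H = _fit_multinomial_ridge(X, y, k, ridge, sample_weight=sw)
    cov = np.linalg.pinv(H)

    # at the observed point x0 = (1, 0, ..., 0): eta_a = W[a-1, 0]
    eta = np.concatenate([[0.0], W[:, 0]])
    e = np.exp(eta - eta.max())
    p = e / e.sum()
    # covariance of (eta_2..eta_k) at x0: intercept block of cov
    idx = [(a - 1) * d for a in range(1, k)]
    V_eta = cov[np.ix_(idx, idx)]
    # delta method: dp/d eta_b (b = 2..k)
    J = np.zeros((k, k - 1))
    for a in range(k):
        for b in range(1, k):
            J[a, b - 1] = p[a] * ((a == b) - p[b])
    V_p = J @ V_eta @ J.T
    se = np.sqrt(np.clip(np.diag(V_p), 0.0, None))
    probs = {s: 0.0 for s in scenario_ids}
    cis = {s: (0.0, 0.0) for s in scenario_ids}
    for s, i in class_of.items():
        probs[s] = float(p[i])
        lo = max(0.0, p[i] - 1.96 * se[i])
        hi = min(1.0, p[i] + 1.96 * se[i])
        cis[s] = (float(lo), float(hi))
    return ModelChoiceResult(probs, cis, counts)


# ---------------------------------------------------------------------------
# parameter estimation


@dataclass
class PosteriorEstimate:
    param_names: list[str]
    median: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    adjusted: bool

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            n: {"median": float(m), "q2.5": float(lo), "q97.5": float(hi)}
            for n, m, lo, hi in zip(self.param_names, self.median, self.q025, self.q975)
        }


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    return float(np.interp(q, cw, x[order]))


def prior_bounds(
    template: ScenarioTemplate, prior_set: PriorSet
) -> tuple[dict[str, tuple[float, float]], set[str]]:
    """(bounds, log-scale names) for every parameter of a template."""
    bounds: dict[str, tuple[float, float]] = {}
    logs: set[str] = set()
    for name in template.param_names:
        if name.startswith("N_"):
            spec = prior_set.size
        elif name.startswith("T_"):
            spec = prior_set.time
        elif name == "ra":
            spec = prior_set.admixture
        else:
            spec = getattr(prior_set, name)
        bounds[name] = (spec.lo, spec.hi)
        if spec.kind == "loguniform":
            logs.add(name)
    return bounds, logs


def estimate_parameters_loclinear(
    table: ReferenceTable,
    accepted: np.ndarray,
    distances: np.ndarray,
    observed: SummaryVector,
    param_bounds: dict[str, tuple[float, float]],
    param_names: Sequence[str] | None = None,
    log_params: set[str] | None = None,
) -> PosteriorEstimate:
    """Beaumont local-linear regression adjustment of accepted parameters.

    Parameters are logit-transformed to their prior bounds, regressed on
    the normalised statistics with Epanechnikov weights on distance, the
    fitted trend is removed at the observed point, and quantiles are read
    from the weighted adjusted sample. Falls back to unadjusted weighted
    quantiles (flagged) when the accepted set is smaller than the number
    of statistics + 2.
    """
    names = [n for n in (param_names or table.param_names) if n in param_bounds]
    log_params = log_params or set()
    cols = [table.param_names.index(n) for n in names]
    theta = table.params[np.ix_(accepted, cols)].astype(float)
    if np.isnan(theta).any():
        raise ValueError("accepted rows must come from a single scenario (NaN params)")
    dmax = distances.max()
    w = 1.0 - (distances / dmax) ** 2 if dmax > 0 else np.ones_like(distances)
    w = np.clip(w, 1e-12, None)
    z = (table.stats[accepted] - observed.values[None, :]) / table.norm[None, :]

    lo = np.array([param_bounds[n][0] for n in names])
    hi = np.array([param_bounds[n][1] for n in names])
    is_log = np.array([n in log_params for n in names])
    lo[is_log] = np.log10(lo[is_log])
    hi[is_log] = np.log10(hi[is_log])
    theta[:, is_log] = np.log10(theta[:, is_log])
    span = hi - lo
    frac = np.clip((theta - lo) / span, 1e-9, 1 - 1e-9)
    zt = np.log(frac / (1 - frac))

    m = len(accepted)
    adjusted = m >= z.shape[1] + 2
    if adjusted:
        X = np.hstack([np.ones((m, 1)), z])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], zt * sw[:, None], rcond=None)
        zt_adj = zt - z @ beta[1:, :]
    else:
        warnings.warn("too few accepted rows for regression; unadjusted quantiles")
        zt_adj = zt

    back = lo + span / (1.0 + np.exp(-zt_adj))
    back[:, is_log] = 10 ** back[:, is_log]
    med = np.array([_weighted_quantile(back[:, j], w, 0.5) for j in range(len(names))])
    q025 = np.array([_weighted_quantile(back[:, j], w, 0.025) for j in range(len(names))])
    q975 = np.array([_weighted_quantile(back[:, j], w, 0.975) for j in range(len(names))])
    return PosteriorEstimate(names, med, q025, q975, adjusted)
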