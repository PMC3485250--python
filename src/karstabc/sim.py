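"""Backward-time simulation of multilocus data under divergence/admixture
demographies.

A demographic scenario is a list of backward-time events over a set of
named populations (an unsampled ancestral population plus the extant
groups): *divergence* merges a child lineage into its parent, and
*admixture* sends each lineage of a target population to one of two
sources with probability ``ra`` / ``1 - ra``. Genealogies are drawn from
the continuous-time coalescent (via msprime), with population sizes in
diploid individuals: autosomal loci coalesce at rate 1/(2N) per lineage
pair, the maternally inherited mitochondrial locus at 1/(N/2).

Mutations: the mitochondrial locus evolves under a finite-sites HKY
process (transition/transversion parameter kappa); microsatellites
under a generalized stepwise model (GSM) where each mutation moves the
repeat number up or down by a geometrically distributed step with mean
1/(1-p), reflecting at the bounds of a contiguous allele range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import msprime
import numpy as np

from .io import MicrosatGenotypes, SampleTable, SequenceAlignment

__all__ = [
    "Divergence",
    "Admixture",
    "DemographicScenario",
    "MutationModel",
    "SyntheticDataset",
    "ScenarioError",
    "validate_scenario",
    "sample_genealogy",
    "hky_mutated_ts",
    "mutate_sequences_hky",
    "mutate_microsats_gsm",
    "gsm_transition_matrix",
    "simulate_dataset",
]

_BASES = np.array([b"A", b"C", b"G", b"T"])


class ScenarioError(ValueError):
    """Raised when a demographic scenario is structurally invalid."""


@dataclass(frozen=True)
class Divergence:
    """Backward in time at ``time``, the child population merges into parent."""

    time: float
    child: str
    parent: str


@dataclass(frozen=True)
class Admixture:
    """Backward in time at ``time``, each lineage of ``target`` moves to
    ``source1`` with probability ``ra``, else to ``source2``."""

    time: float
    target: str
    source1: str
    source2: str
    ra: float


@dataclass
class DemographicScenario:
    """Named populations, per-population diploid sizes, backward-time events
    and per-population sample counts (mtDNA sequences, diploid individuals)."""

    scenario_id: str
    populations: list[str]
    effective_sizes: dict[str, float]
    events: list[Divergence | Admixture]
    sample_config: dict[str, tuple[int, int]] = field(default_factory=dict)


def validate_scenario(scenario: DemographicScenario) -> DemographicScenario:
    """Time-sort events and verify the event graph reaches a single root.

    Checks: all sizes >= 1; event times positive and strictly increasing;
    admixture rates in (0, 1); every event references populations that
    are still active at its time (this is what enforces conditions such
    as "an origin time must be younger than its source's own divergence");
    exactly one population remains at the oldest event.
    """
    for pop in scenario.populations:
        size = scenario.effective_sizes.get(pop)
        if size is None or size < 1:
            raise ScenarioError(f"population {pop} needs effective size >= 1")
    events = sorted(scenario.events, key=lambda e: e.time)
    times = [e.time for e in events]
    if any(t <= 0 for t in times):
        raise ScenarioError("event times must be positive")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ScenarioError("event times must be strictly increasing")
    active = set(scenario.populations)
    for ev in events:
        if isinstance(ev, Divergence):
            if ev.child not in active:
                raise ScenarioError(
                    f"{scenario.scenario_id}: {ev.child} already merged before "
                    f"t={ev.time} (ordering constraint violated)"
                )
            if ev.parent not in active:
                raise ScenarioError(
                    f"{scenario.scenario_id}: parent {ev.parent} inactive at "
                    f"t={ev.time} (ordering constraint violated)"
                )
            active.remove(ev.child)
        else:
            if not (0 < ev.ra < 1):
                raise ScenarioError(f"admixture rate {ev.ra} outside (0,1)")
            for pop in (ev.target, ev.source1, ev.source2):
                if pop not in active:
                    raise ScenarioError(
                        f"{scenario.scenario_id}: {pop} inactive at admixture "
                        f"t={ev.time}"
                    )
            active.remove(ev.target)
    if len(active) != 1:
        raise ScenarioError(
            f"{scenario.scenario_id}: {len(active)} populations remain at the "
            f"root ({sorted(active)}); expected exactly 1"
        )
    return replace(scenario, events=events)


@dataclass
class MutationModel:
    """Mutation parameters for one mitochondrial locus and a battery of
    unlinked microsatellites.

    ``mt_rate`` is the mean per-site per-generation substitution rate,
    ``kappa`` the HKY transition/transversion parameter. ``ms_mean_rate``
    and ``ms_mean_p`` are the across-locus means of the per-locus GSM
    mutation rate and geometric coefficient; per-locus values are drawn
    around them (Gamma with shape 2 for rates, uniform +-0.05 for p).
    The single-nucleotide-indel component of the GSM is disabled
    (``sni_rate`` fixed at 0). Alleles live on ``n_states`` contiguous
    repeat numbers 1..n_states with the root allele at the centre.
    """

    mt_rate: float
    kappa: float
    seq_length: int = 1613
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    ms_mean_rate: float = 5e-4
    ms_mean_p: float = 0.22
    n_loci: int = 12
    n_states: int = 40
    root_state: int = 20  # repeat number; centre of the allowed range
    sni_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mt_rate < 0 or self.ms_mean_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not (0 < self.ms_mean_p < 1):
            raise ValueError("GSM coefficient p must be in (0,1)")
        if self.n_states < 2:
            raise ValueError("allele range needs >= 2 states")

    def draw_locus_params(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (rates, geometric coefficients).

        Rates: Gamma(shape 2) scaled to the mean, truncated to
        [1e-5, 1e-2]; coefficients: uniform within +-0.05 of the mean,
        truncated to (0, 1).
        """
        rates = rng.gamma(2.0, self.ms_mean_rate / 2.0, size=self.n_loci)
        rates = np.clip(rates, 1e-5, 1e-2)
        ps = rng.uniform(self.ms_mean_p - 0.05, self.ms_mean_p + 0.05, size=self.n_loci)
        ps = np.clip(ps, 1e-3, 0.999)
        return rates, ps


@dataclass
class SyntheticDataset:
    """One simulated multilocus dataset plus full provenance."""

    alignment: SequenceAlignment
    genotypes: MicrosatGenotypes
    sample_table: SampleTable
    provenance: dict


# ---------------------------------------------------------------------------
# msprime bridge


def _to_demography(scenario: DemographicScenario, mtdna: bool) -> msprime.Demography:
    demography = msprime.Demography()
    sampled = {p for p, (nm, ni) in scenario.sample_config.items() if nm + ni > 0}
    for pop in scenario.populations:
        size = scenario.effective_sizes[pop]
        demography.add_population(
            name=pop,
            initial_size=size / 2.0 if mtdna else size,
            initially_active=pop in sampled or None,
        )
    for ev in scenario.events:
        if isinstance(ev, Divergence):
            demography.add_population_split(
                time=ev.time, derived=[ev.child], ancestral=ev.parent
            )
        else:
            demography.add_admixture(
                time=ev.time,
                derived=ev.target,
                ancestral=[ev.source1, ev.source2],
                proportions=[ev.ra, 1.0 - ev.ra],
            )
    demography.sort_events()
    return demography


def _genealogies(
    scenario: DemographicScenario,
    locus_kind: str,
    rng: np.random.Generator,
    sequence_length: int = 1,
    num_replicates: int | None = None,
):
    if locus_kind not in ("mtDNA", "autosomal"):
        raise ValueError("locus_kind must be 'mtDNA' or 'autosomal'")
    mtdna = locus_kind == "mtDNA"
    samples = []
    for pop in scenario.populations:
        n_mt, n_ind = scenario.sample_config.get(pop, (0, 0))
        count = n_mt if mtdna else n_ind
        if count > 0:
            samples.append(msprime.SampleSet(count, population=pop, ploidy=1 if mtdna else 2))
    if not samples:
        raise ScenarioError("no samples configured")
    return msprime.sim_ancestry(
        samples=samples,
        demography=_to_demography(scenario, mtdna),
        ploidy=1 if mtdna else 2,
        sequence_length=sequence_length,
        discrete_genome=True,
        num_replicates=num_replicates,
        record_provenance=False,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )


def sample_genealogy(
    scenario: DemographicScenario,
    locus_kind: str,
    rng: np.random.Generator,
    sequence_length: int = 1,
):
    """Draw one coalescent genealogy (a single-tree tskit TreeSequence).

    ``locus_kind`` is ``"mtDNA"`` (haploid, size N/2 copies per diploid
    population of size N) or ``"autosomal"`` (diploid individuals, 2N
    copies). Sample counts come from ``scenario.sample_config``: the
    first entry for mtDNA sequences, the second for diploid individuals.
    """
    return _genealogies(scenario, locus_kind, rng, sequence_length)


def hky_model(kappa: float, base_freqs: Sequence[float]) -> msprime.MatrixMutationModel:
    """HKY mutation-event matrix: target allele drawn proportional to its
    equilibrium frequency, weighted by kappa for transitions; rows are
    normalised exactly (diagonal mass = silent events)."""
    freqs = np.asarray(base_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    M = np.full((4, 4), 1.0)
    M[((0, 1, 2, 3), (2, 3, 0, 1))] = kappa  # A<->G, C<->T
    M *= freqs
    np.fill_diagonal(M, 0.0)
    M /= M.sum(axis=1).max()
    # clip guards the max-sum row, whose diagonal can round to -1 ulp
    np.fill_diagonal(M, np.clip(1.0 - M.sum(axis=1), 0.0, None))
    M /= M.sum(axis=1, keepdims=True)
    return msprime.MatrixMutationModel(
        ["A", "C", "G", "T"], root_distribution=freqs, transition_matrix=M
    )


def hky_mutated_ts(ts, mut: MutationModel, rng: np.random.Generator):
    """Overlay HKY mutations on a genealogy; returns the mutated TreeSequence."""
    return msprime.sim_mutations(
        ts,
        rate=mut.mt_rate,
        model=hky_model(mut.kappa, mut.base_freqs),
        record_provenance=False,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )


def mutate_sequences_hky(
    ts,
    mut: MutationModel,
    rng: np.random.Generator,
    sample_ids: Sequence[str] | None = None,
    locus_name: str = "mtDNA",
) -> SequenceAlignment:
    """Evolve the sequence locus under HKY on the given genealogy.

    The root sequence is drawn from the model's base frequencies; sites
    are independent; the expected number of substitutions per site on a
    branch equals rate x branch length in generations.
    """
    L = int(ts.sequence_length)
    n = ts.num_samples
    mts = hky_mutated_ts(ts, mut, rng)
    ref_idx = rng.choice(4, size=L, p=np.asarray(mut.base_freqs) / np.sum(mut.base_freqs))
    arr = np.tile(_BASES[ref_idx], (n, 1))
    for var in mts.variants():
        site = int(var.site.position)
        alleles = np.array([a.encode() for a in var.alleles if a is not None], dtype="S1")
        arr[:, site] = alleles[var.genotypes]
    flat = arr.tobytes().decode()
    seqs = [flat[i * L : (i + 1) * L] for i in range(n)]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return SequenceAlignment(locus_name, list(sample_ids), seqs)


def gsm_transition_matrix(p: float, n_states: int, tail_tol: float = 1e-12) -> np.ndarray:
    """Single-mutation transition matrix of the reflected GSM.

    Step size k >= 1 is geometric with success probability 1-p (mean
    1/(1-p)); direction up/down equiprobable; targets outside
    [0, n_states-1] are reflected back into range.
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0,1)")
    k_max = max(1, int(math.ceil(math.log(tail_tol) / math.log(p))) if p > 0 else 1)
    k = np.arange(1, k_max + 1)
    pk = (1 - p) * p ** (k - 1)
    pk /= pk.sum()  # renormalise the truncated tail
    period = 2 * (n_states - 1) if n_states > 1 else 1
    states = np.arange(n_states)

    def reflect(x: np.ndarray) -> np.ndarray:
        m = np.mod(x, period)
        return np.where(m >= n_states, period - m, m)

    matrix = np.zeros((n_states, n_states))
    for sign in (+1, -1):
        targets = reflect(states[:, None] + sign * k[None, :])
        np.add.at(matrix, (np.repeat(states, k_max), targets.ravel()), np.tile(pk / 2.0, n_states))
    return matrix


def mutate_microsats_gsm(
    ts,
    rate: float,
    p: float,
    rng: np.random.Generator,
    n_states: int = 40,
    root_state: int = 20,
) -> np.ndarray:
    """Allele sizes (repeat numbers 1..n_states) at the leaves of one locus.

    Mutations fall as a Poisson process on branches; each applies a
    reflected geometric step. Returns one repeat number per sample node
    in sample order.
    """
    alleles = [str(i) for i in range(1, n_states + 1)]
    root = np.zeros(n_states)
    root[root_state - 1] = 1.0
    model = msprime.MatrixMutationModel(
        alleles, root_distribution=root, transition_matrix=gsm_transition_matrix(p, n_states)
    )
    mts = msprime.sim_mutations(
        ts,
        rate=rate,
        model=model,
        record_provenance=False,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    if mts.num_sites == 0:
        return np.full(ts.num_samples, root_state, dtype=int)
    var = next(mts.variants())
    allele_sizes = np.array([int(a) for a in var.alleles if a is not None])
    return allele_sizes[var.genotypes]


def simulate_dataset(
    scenario: DemographicScenario,
    mut: MutationModel,
    rng: np.random.Generator,
    params: dict | None = None,
) -> SyntheticDataset:
    """One complete multilocus dataset under the scenario.

    One non-recombining mitochondrial genealogy plus ``mut.n_loci``
    independent autosomal microsatellite genealogies. Sample identifiers
    are shared between markers where the per-group counts coincide, so a
    preset with equal counts behaves like one panel of individuals typed
    for everything.
    """
    scenario = validate_scenario(scenario)
    groups_mt: list[str] = []
    mt_ids: list[str] = []
    groups_ind: list[str] = []
    ind_ids: list[str] = []
    for pop in scenario.populations:
        n_mt, n_ind = scenario.sample_config.get(pop, (0, 0))
        for i in range(n_mt):
            mt_ids.append(f"{pop}_{i:03d}")
            groups_mt.append(pop)
        for i in range(n_ind):
            ind_ids.append(f"{pop}_{i:03d}")
            groups_ind.append(pop)

    ts_mt = sample_genealogy(scenario, "mtDNA", rng, sequence_length=mut.seq_length)
    alignment = mutate_sequences_hky(ts_mt, mut, rng, sample_ids=mt_ids)

    rates, ps = mut.draw_locus_params(rng)
    n_ind_total = len(ind_ids)
    geno = np.zeros((n_ind_total, mut.n_loci, 2), dtype=int)
    replicates = _genealogies(
        scenario, "autosomal", rng, sequence_length=1, num_replicates=mut.n_loci
    )
    for j, ts in enumerate(replicates):
        sizes = mutate_microsats_gsm(
            ts, rates[j], ps[j], rng, n_states=mut.n_states, root_state=mut.root_state
        )
        geno[:, j, :] = sizes.reshape(n_ind_total, 2)
    genotypes = MicrosatGenotypes(
        ind_ids, [f"locus{j+1:02d}" for j in range(mut.n_loci)], geno, groups_ind
    )

    all_ids: dict[str, str] = {}
    for sid, g in zip(mt_ids + ind_ids, groups_mt + groups_ind):
        all_ids.setdefault(sid, g)
    table = SampleTable(
        sample_ids=list(all_ids),
        locality_ids=[all_ids[s] for s in all_ids],
        group_labels=[all_ids[s] for s in all_ids],
        latitudes=[0.0] * len(all_ids),
        longitudes=[0.0] * len(all_ids),
    )
    provenance = {
        "scenario_id": scenario.scenario_id,
        "params": dict(params or {}),
        "locus_rates": rates.tolist(),
        "locus_ps": ps.tolist(),
    }
    return SyntheticDataset(alignment, genotypes, table, provenance)
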