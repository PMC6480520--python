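"""Coalescent simulation of four-taxon data with a single admixture pulse.

The demography mirrors the classic ms-style four-population history
(((P1,P2),P3),O) with split times ``t12 < t123 <= t123O`` expressed in
units of 4N generations, plus one pulse of gene flow of fraction ``f``
at time ``t_GF`` in one of three directions.  Ancestry is simulated with
msprime; setting haploid populations of size 0.5 makes one msprime
generation equal one 4N-generation coalescent unit, so ms-style times
and the locus-wide recombination parameter rho are used directly.
Mutations are laid down either under HKY with rate ``s`` substitutions
per site per unit branch length (the seq-gen pipeline) or under an
infinite-sites binary model at the same expected density.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import msprime
import numpy as np

from .core_stats import POPULATIONS
from .io import HaplotypeMatrix, polarize, write_ms, write_phylip

__all__ = [
    "SimulationConfig",
    "simulate_locus",
    "simulate_alignment",
    "simulate_grid",
    "simulate_detection_set",
    "simulate_chromosome",
]

DIRECTIONS = ("P3>P2", "P2>P3", "P3>P1")


@dataclass
class SimulationConfig:
    """Four-taxon demography + mutation parameters (times in 4N units).

    Defaults are the baseline study conditions: 8 haplotypes per
    population, splits at 1/2/3 x 4N, pulse of fraction ``f`` at
    ``t_GF = 0.1``, rho = 50 over a 5 kb locus, HKY with branch scale
    s = 0.01 (kappa and base frequencies are nuisance parameters,
    default kappa=2, equal frequencies).
    """

    t12: float = 1.0
    t123: float = 2.0
    t123O: float = 3.0
    f: float = 0.1
    t_gf: float = 0.1
    direction: str = "P3>P2"
    rho: float = 50.0
    L: int = 5000
    s: float = 0.01
    substitution_model: str = "hky"
    kappa: float = 2.0
    samples_per_pop: int = 8
    N12: float = 1.0
    N123: float = 1.0
    seed: int | None = None

    def validate(self):
        if not (0 < self.t_gf < self.t12 <= self.t123 <= self.t123O):
            raise ValueError(
                "need 0 < t_gf < t12 <= t123 <= t123O, got "
                f"{self.t_gf}, {self.t12}, {self.t123}, {self.t123O}")
        if not 0 <= self.f <= 1:
            raise ValueError(f"introgression fraction f={self.f} outside [0, 1]")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.rho < 0 or self.L < 1 or self.samples_per_pop < 2:
            raise ValueError("need rho >= 0, L >= 1, samples_per_pop >= 2")
        if self.substitution_model not in ("hky", "infinite-sites"):
            raise ValueError("substitution_model must be 'hky' or 'infinite-sites'")
        return self

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _demography(cfg: SimulationConfig) -> msprime.Demography:
    d = msprime.Demography()
    for name in POPULATIONS:
        d.add_population(name="O" if name == "O" else name, initial_size=0.5)
    d.add_population(name="A12", initial_size=0.5 * cfg.N12)
    d.add_population(name="A123", initial_size=0.5 * cfg.N123)
    d.add_population(name="A123O", initial_size=0.5)
    if cfg.f > 0:
        # backwards in time: recipient lineages jump into the donor
        recipient, donor = {
            "P3>P2": ("P2", "P3"),
            "P2>P3": ("P3", "P2"),
            "P3>P1": ("P1", "P3"),
        }[cfg.direction]
        d.add_mass_migration(time=cfg.t_gf, source=recipient, dest=donor,
                             proportion=cfg.f)
    d.add_population_split(time=cfg.t12, derived=["P1", "P2"], ancestral="A12")
    d.add_population_split(time=cfg.t123, derived=["A12", "P3"], ancestral="A123")
    d.add_population_split(time=cfg.t123O, derived=["A123", "O"],
                           ancestral="A123O")
    d.sort_events()
    return d


def _child_seeds(seed, n):
    """Deterministic msprime-safe seeds (1 .. 2^31-1) from a master seed."""
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n, dtype=np.uint64) % (2**31 - 2) + 1).astype(np.int64)


def simulate_tree_sequence(config: SimulationConfig, seed=None):
    """Ancestry + mutations for one locus; returns the tskit TreeSequence."""
    cfg = config.validate()
    seed = cfg.seed if seed is None else seed
    anc_seed, mut_seed = _child_seeds(seed, 2)
    r = cfg.rho / (cfg.L - 1) if cfg.L > 1 else 0.0
    ts = msprime.sim_ancestry(
        samples={p: cfg.samples_per_pop for p in POPULATIONS},
        ploidy=1,
        demography=_demography(cfg),
        sequence_length=cfg.L,
        recombination_rate=r,
        random_seed=anc_seed,
    )
    if cfg.substitution_model == "hky":
        model = msprime.HKY(kappa=cfg.kappa)
        discrete = True
    else:
        model = msprime.BinaryMutationModel()
        discrete = False
    return msprime.sim_mutations(ts, rate=cfg.s, model=model,
                                 random_seed=mut_seed,
                                 discrete_genome=discrete)


def _pops_array(cfg):
    return np.asarray(
        [p for p in POPULATIONS for _ in range(cfg.samples_per_pop)],
        dtype=object)


def _site_alleles(ts):
    """Allele list per site in tskit's variant indexing: ancestral state
    first, then derived states in mutation order, deduplicated."""
    out = []
    for site in ts.sites():
        alleles = [site.ancestral_state]
        for mut in site.mutations:
            if mut.derived_state not in alleles:
                alleles.append(mut.derived_state)
        out.append(alleles)
    return out


def _variant_columns(ts, want_bases=False):
    """Biallelic variant columns as (positions, codes (L, H), bases).

    Sites that are invariant or carry >2 alleles among the samples are
    dropped.  ``codes`` are 0/1 with 0 the alphabetically smaller base;
    the character matrix ``bases`` is built only when requested.
    """
    empty = (np.empty(0, dtype=np.int64),
             np.empty((0, ts.num_samples), dtype=np.int8),
             np.empty((0, ts.num_samples), dtype="U1"))
    if ts.num_sites == 0:
        return empty
    G = ts.genotype_matrix()
    rmin, rmax = G.min(axis=1), G.max(axis=1)
    keep = (rmin != rmax) & \
        ((G == rmin[:, None]) | (G == rmax[:, None])).all(axis=1)
    if not keep.any():
        return empty
    alleles = _site_alleles(ts)
    raw_pos = ts.tables.sites.position.astype(np.int64)
    positions, code_rows, base_rows = [], [], []
    last_pos = -1
    for k in np.flatnonzero(keep):
        lo, hi = alleles[k][rmin[k]], alleles[k][rmax[k]]
        pos = int(raw_pos[k])
        if pos <= last_pos:  # duplicates after flooring to int
            pos = last_pos + 1
        last_pos = pos
        positions.append(pos)
        derived_idx = rmax[k] if hi > lo else rmin[k]
        code_rows.append((G[k] == derived_idx).astype(np.int8))
        if want_bases:
            base_rows.append(np.where(G[k] == rmax[k], hi, lo))
    bases = (np.vstack(base_rows) if base_rows
             else np.empty((0, ts.num_samples), dtype="U1"))
    return (np.asarray(positions, dtype=np.int64), np.vstack(code_rows),
            bases)


def simulate_locus(config: SimulationConfig, seed=None,
                   outgroup_policy: str = "strict") -> HaplotypeMatrix:
    """Simulate one locus and return a polarized HaplotypeMatrix.

    Under HKY the derived state is defined by outgroup polarization
    (exactly as an empirical pipeline would); under infinite-sites the
    true ancestral state is known and used directly.
    """
    cfg = config.validate()
    ts = simulate_tree_sequence(cfg, seed=seed)
    pops = _pops_array(cfg)
    if cfg.substitution_model == "infinite-sites":
        geno = ts.genotype_matrix().astype(np.int8)
        keep = [i for i in range(geno.shape[0])
                if len(np.unique(geno[i])) == 2]
        pos = np.asarray([int(s.position * cfg.L) for s in ts.sites()],
                         dtype=np.int64)[keep]
        for k in range(1, len(pos)):
            if pos[k] <= pos[k - 1]:
                pos[k] = pos[k - 1] + 1
        return HaplotypeMatrix(geno[keep], pos, pops, polarized=True,
                               length=cfg.L, source="msprime")
    positions, codes, _ = _variant_columns(ts)
    raw = HaplotypeMatrix(codes, positions, pops, polarized=False,
                          length=cfg.L, source="msprime")
    polarized, _ = polarize(raw, policy=outgroup_policy)
    return polarized


def simulate_alignment(config: SimulationConfig, seed=None):
    """Variant-column alignment (names, sequences) for one HKY locus.

    The columns are exactly the biallelic variant sites of
    :func:`simulate_locus` before polarization, so reading the written
    PHYLIP back through :func:`distfrac.io.read_alignment` reproduces
    the simulator's internal matrix.
    """
    cfg = config.validate()
    if cfg.substitution_model != "hky":
        raise ValueError("alignments are produced by the HKY model")
    ts = simulate_tree_sequence(cfg, seed=seed)
    _, _, bases = _variant_columns(ts, want_bases=True)
    names = [f"{p}_{i+1}" for p in POPULATIONS
             for i in range(cfg.samples_per_pop)]
    seqs = ["".join(bases[:, h]) for h in range(bases.shape[1])]
    return names, seqs


def export_phylip(config, path, seed=None):
    names, seqs = simulate_alignment(config, seed=seed)
    return write_phylip(names, seqs, path)


def export_ms(matrices, path):
    return write_ms(matrices, path)


def simulate_grid(config: SimulationConfig, f_values, reps, seed=None):
    """reps independent loci per introgression fraction.

    Yields ``(f, replicate_index, HaplotypeMatrix)`` with per-locus
    seeds derived deterministically from the master seed.
    """
    cfg = config.validate()
    f_values = list(f_values)
    seeds = _child_seeds(seed if seed is not None else cfg.seed,
                         len(f_values) * reps)
    k = 0
    for f in f_values:
        cfg_f = cfg.replace(f=float(f))
        for rep in range(reps):
            yield float(f), rep, simulate_locus(cfg_f, seed=int(seeds[k]))
            k += 1


def simulate_detection_set(config_neutral, config_introgressed,
                           n_neutral, n_introgressed, seed=None):
    """Labeled loci for ROC analysis: label 0 = neutral, 1 = introgressed."""
    if n_neutral < 1 or n_introgressed < 1:
        raise ValueError("both classes need at least one locus")
    seeds = _child_seeds(seed, n_neutral + n_introgressed)
    loci, labels = [], []
    for i in range(n_neutral):
        loci.append(simulate_locus(config_neutral.replace(f=0.0),
                                   seed=int(seeds[i])))
        labels.append(0)
    for i in range(n_introgressed):
        loci.append(simulate_locus(config_introgressed,
                                   seed=int(seeds[n_neutral + i])))
        labels.append(1)
    return loci, np.asarray(labels)


def simulate_chromosome(config: SimulationConfig, total_length,
                        tract=None, tract_f=None, seed=None) -> HaplotypeMatrix:
    """A chromosome of independent segments with an optional introgressed tract.

    ``tract=(start, end)`` marks a bp interval simulated with
    introgression fraction ``tract_f`` (default ``config.f``); the rest
    of the chromosome is neutral (f=0).  Segments are simulated as
    independent loci at the per-bp recombination rate implied by
    ``config.rho / config.L`` and concatenated with shifted coordinates.
    """
    cfg = config.validate()
    bounds = [0, total_length]
    if tract is not None:
        start, end = tract
        if not 0 <= start < end <= total_length:
            raise ValueError("tract must lie inside [0, total_length)")
        bounds = sorted(set(bounds) | {start, end})
    segments = list(zip(bounds[:-1], bounds[1:]))
    seeds = _child_seeds(seed, len(segments))
    rho_per_bp = cfg.rho / cfg.L
    parts = []
    for (a, b), s in zip(segments, seeds):
        in_tract = tract is not None and a >= tract[0] and b <= tract[1]
        f = (tract_f if tract_f is not None else cfg.f) if in_tract else 0.0
        seg_cfg = cfg.replace(L=b - a, rho=rho_per_bp * (b - a), f=f)
        m = simulate_locus(seg_cfg, seed=int(s))
        parts.append((a, m))
    geno = np.vstack([m.genotypes for _, m in parts])
    pos = np.concatenate([m.positions + a for a, m in parts])
    return HaplotypeMatrix(geno, pos, parts[0][1].pops, polarized=True,
                           length=total_length, source="msprime")
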