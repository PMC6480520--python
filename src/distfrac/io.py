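"""Readers for haplotype data (VCF, alignments, ms output) and polarization.

All readers produce a :class:`HaplotypeMatrix`: a sites x haplotypes 0/1
matrix with per-haplotype population labels drawn from {P1, P2, P3, O}.
Before polarization the 0/1 codes are arbitrary allele indices; after
:func:`polarize` a 1 always means the derived allele, as required by the
statistics in :mod:`distfrac.core_stats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_stats import POPULATIONS, SiteFrequencyTable

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeMatrix",
    "read_popmap",
    "read_vcf",
    "read_alignment",
    "read_ms",
    "write_ms",
    "write_phylip",
    "polarize",
    "frequency_table",
]

_MISSING = -1
_BASES = "ACGT"


@dataclass
class HaplotypeMatrix:
    """Biallelic sites x haplotypes matrix with population labels.

    genotypes: (L, H) int8, values in {0, 1, -1(missing)}
    positions: (L,) 0-based bp coordinates, strictly increasing
    pops:      (H,) labels from {P1, P2, P3, O}
    polarized: True once 1 == derived allele
    length:    bp span of the underlying region (for windowing)
    counters:  dropped-site tallies accumulated by readers/polarization
    """

    genotypes: np.ndarray
    positions: np.ndarray
    pops: np.ndarray
    polarized: bool = False
    length: int | None = None
    source: str = "memory"
    counters: dict = field(default_factory=dict)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (sites x haplotypes)")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.pops = np.asarray(self.pops, dtype=object)
        if len(self.positions) != self.genotypes.shape[0]:
            raise ValueError("positions length != number of sites")
        if len(self.pops) != self.genotypes.shape[1]:
            raise ValueError("pops length != number of haplotypes")
        missing_pops = set(POPULATIONS) - set(self.pops)
        if missing_pops:
            raise ValueError(f"populations without haplotypes: {sorted(missing_pops)}")
        unknown = set(self.pops) - set(POPULATIONS)
        if unknown:
            raise ValueError(f"unknown population labels: {sorted(unknown)}")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.length is None:
            self.length = int(self.positions[-1]) + 1 if len(self.positions) else 0

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.genotypes.shape[1]

    def pop_columns(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.pops == pop)

    def select_sites(self, mask_or_index) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.genotypes[mask_or_index],
            self.positions[mask_or_index],
            self.pops,
            polarized=self.polarized,
            length=self.length,
            source=self.source,
            counters=dict(self.counters),
        )


def read_popmap(path) -> dict:
    """Two-column TSV/whitespace file: sample id, population label."""
    popmap = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed popmap line: {line!r}")
            sample, pop = parts[0], parts[1]
            if pop not in POPULATIONS:
                raise ValueError(
                    f"population label {pop!r} for sample {sample!r} "
                    f"not in {POPULATIONS}")
            popmap[sample] = pop
    if not popmap:
        raise ValueError("empty popmap")
    return popmap


def read_vcf(path, popmap, unphased_policy="drop", seed=None):
    """Read biallelic SNPs from a VCF into an (unpolarized) HaplotypeMatrix.

    Phased diploid samples contribute two haplotypes, haploid calls one.
    ``unphased_policy`` controls heterozygous unphased genotypes:
    ``"drop"`` removes the site, ``"random"`` assigns the two alleles to
    the two haplotypes in random order (seeded).

    Raises KeyError if a popmap sample is missing from the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    for sample in popmap:
        if sample not in vcf_samples:
            raise KeyError(f"popmap sample {sample!r} not found in VCF header")
    use = [s for s in vcf_samples if s in popmap]
    idx = [vcf_samples.index(s) for s in use]
    rng = np.random.default_rng(seed)

    counters = {"multiallelic": 0, "non_snp": 0, "unphased_het": 0,
                "uncalled_population": 0}
    rows, positions, pops_per_hap = [], [], None
    for variant in vcf:
        if len(variant.ALT) != 1:
            counters["multiallelic"] += 1
            continue
        if len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            counters["non_snp"] += 1
            continue
        calls = []
        hap_pops = []
        drop = False
        for i in idx:
            g = variant.genotypes[i]
            alleles, phased = list(g[:-1]), bool(g[-1])
            alleles = [a if a is not None else _MISSING for a in alleles]
            alleles = [_MISSING if a < 0 else a for a in alleles]
            if len(alleles) == 2 and not phased and alleles[0] != alleles[1] \
                    and _MISSING not in alleles:
                if unphased_policy == "drop":
                    counters["unphased_het"] += 1
                    drop = True
                    break
                alleles = list(rng.permutation(alleles))
            calls.extend(alleles)
            hap_pops.extend([popmap[vcf_samples[i]]] * len(alleles))
        if drop:
            continue
        if pops_per_hap is None:
            pops_per_hap = hap_pops
        row = np.asarray(calls, dtype=np.int8)
        # per-population missingness: drop site if any population fully uncalled
        pop_arr = np.asarray(pops_per_hap, dtype=object)
        bad = False
        for pop in POPULATIONS:
            cols = pop_arr == pop
            if cols.any() and np.all(row[cols] == _MISSING):
                bad = True
                break
        if bad:
            counters["uncalled_population"] += 1
            continue
        rows.append(row)
        positions.append(variant.POS - 1)  # 0-based internally
    if pops_per_hap is None:
        # empty body: infer haplotype layout from popmap (diploid assumption)
        pops_per_hap = [popmap[s] for s in use for _ in range(2)]
    genotypes = (np.vstack(rows) if rows
                 else np.empty((0, len(pops_per_hap)), dtype=np.int8))
    logger.info("read_vcf: %d sites kept, dropped %s", len(rows), counters)
    return HaplotypeMatrix(genotypes, np.asarray(positions, dtype=np.int64),
                           np.asarray(pops_per_hap, dtype=object),
                           polarized=False, source=f"vcf:{path}",
                           counters=counters)


def _resolve_pops(names, popmap, samples_per_pop):
    if popmap is not None:
        try:
            return np.asarray([popmap[n] for n in names], dtype=object)
        except KeyError as e:
            raise KeyError(f"sequence name {e.args[0]!r} not in popmap") from None
    if samples_per_pop is None:
        raise ValueError("need either popmap or samples_per_pop")
    pops = [p for p, n in zip(POPULATIONS, samples_per_pop) for _ in range(n)]
    if len(pops) != len(names):
        raise ValueError(
            f"{len(names)} sequences but samples_per_pop sums to {len(pops)}")
    return np.asarray(pops, dtype=object)


def read_alignment(path, format="phylip", popmap=None, samples_per_pop=None):
    """Read a multiple-sequence alignment and extract biallelic variant columns.

    ``format`` is "phylip" (relaxed names, as written by seq-gen) or
    "fasta".  Populations come from ``popmap`` (name -> label) or, for
    simulator-style block order, ``samples_per_pop`` (first block P1,
    then P2, P3, O).  Case-insensitive; columns containing anything
    other than two distinct A/C/G/T states are dropped and counted.
    0/1 codes are allele indices (0 = alphabetically smaller base);
    polarization is a separate step.
    """
    from Bio import AlignIO

    bio_format = {"phylip": "phylip-relaxed", "fasta": "fasta"}[format]
    aln = AlignIO.read(str(path), bio_format)
    names = [rec.id for rec in aln]
    seqs = np.array([list(str(rec.seq).upper()) for rec in aln], dtype="U1").T
    pops = _resolve_pops(names, popmap, samples_per_pop)

    counters = {"invariant": 0, "multiallelic": 0, "non_acgt": 0}
    rows, positions = [], []
    for j in range(seqs.shape[0]):
        col = seqs[j]
        alleles = np.unique(col)
        if not set(alleles) <= set(_BASES):
            counters["non_acgt"] += 1
            continue
        if len(alleles) == 1:
            counters["invariant"] += 1
            continue
        if len(alleles) > 2:
            counters["multiallelic"] += 1
            continue
        rows.append((col == alleles[1]).astype(np.int8))
        positions.append(j)
    genotypes = (np.vstack(rows) if rows
                 else np.empty((0, len(names)), dtype=np.int8))
    logger.info("read_alignment: %d variant sites kept, dropped %s",
                len(rows), counters)
    return HaplotypeMatrix(genotypes, np.asarray(positions, dtype=np.int64),
                           pops, polarized=False,
                           length=seqs.shape[0], source=f"{format}:{path}",
                           counters=counters)


def read_ms(path_or_text, samples_per_pop=(8, 8, 8, 8), length=None):
    """Parse ms-style output into one HaplotypeMatrix per replicate.

    Accepts both "//"-delimited replicates and pre-stripped streams.  ms
    0/1 is taken as ancestral/derived directly (ms simulates the
    ancestral state), so matrices come back ``polarized=True``.
    Positions in (0, 1] are scaled to [0, length) bp; ``length``
    defaults to the value on the ``-r rho nsites`` command line if one
    is present, else 1,000,000.
    """
    try:
        text = path_or_text.read_text()
    except AttributeError:
        if "\n" in str(path_or_text) or "segsites" in str(path_or_text):
            text = str(path_or_text)
        else:
            with open(path_or_text) as fh:
                text = fh.read()
    lines = text.splitlines()
    if length is None:
        length = 1_000_000
        if lines and lines[0].lstrip().startswith("ms"):
            tokens = lines[0].split()
            if "-r" in tokens:
                length = int(float(tokens[tokens.index("-r") + 2]))
    n_haps = sum(samples_per_pop)
    pops = np.asarray(
        [p for p, n in zip(POPULATIONS, samples_per_pop) for _ in range(n)],
        dtype=object)

    matrices = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line.startswith("segsites:"):
            i += 1
            continue
        segsites = int(line.split()[1])
        i += 1
        if segsites == 0:
            matrices.append(HaplotypeMatrix(
                np.empty((0, n_haps), dtype=np.int8),
                np.empty(0, dtype=np.int64), pops, polarized=True,
                length=length, source="ms"))
            continue
        while not lines[i].strip().startswith("positions:"):
            i += 1
        rel_pos = np.asarray(lines[i].split()[1:], dtype=float)
        i += 1
        haps = []
        while i < len(lines) and len(haps) < n_haps:
            row = lines[i].strip()
            if row and set(row) <= {"0", "1"}:
                haps.append(row)
            elif row:
                raise ValueError(f"unexpected line in ms haplotype block: {row!r}")
            i += 1
        if len(haps) != n_haps:
            raise ValueError(
                f"ms block has {len(haps)} haplotype rows, expected {n_haps}")
        geno = np.array([[int(c) for c in h] for h in haps], dtype=np.int8).T
        pos = np.minimum((rel_pos * length).astype(np.int64), length - 1)
        # collapse coordinate collisions from scaling while keeping order
        for k in range(1, len(pos)):
            if pos[k] <= pos[k - 1]:
                pos[k] = pos[k - 1] + 1
        matrices.append(HaplotypeMatrix(geno, pos, pops, polarized=True,
                                        length=length, source="ms"))
    return matrices


def write_ms(matrices, path, command=None):
    """Write HaplotypeMatrix replicates as ms-dialect text.

    The synthesized command line records the locus length after ``-r``
    so that :func:`read_ms` recovers bp coordinates on round trip.
    """
    if isinstance(matrices, HaplotypeMatrix):
        matrices = [matrices]
    if command is None:
        m0 = matrices[0]
        command = f"ms {m0.n_haplotypes} {len(matrices)} -r 0 {m0.length}"
    with open(path, "w") as fh:
        fh.write(f"{command}\n0 0 0\n")
        for m in matrices:
            fh.write("\n//\n")
            fh.write(f"segsites: {m.n_sites}\n")
            if m.n_sites:
                rel = (m.positions + 0.5) / m.length
                fh.write("positions: " + " ".join(f"{x:.6f}" for x in rel) + "\n")
                for h in range(m.n_haplotypes):
                    fh.write("".join(str(int(g)) for g in m.genotypes[:, h]) + "\n")
    return path


def write_phylip(names, sequences, path):
    """Write equal-length sequences as relaxed PHYLIP."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must be equal length")
    with open(path, "w") as fh:
        fh.write(f" {len(names)} {lengths.pop()}\n")
        for name, seq in zip(names, sequences):
            fh.write(f"{name}  {seq}\n")
    return path


def polarize(matrix: HaplotypeMatrix, policy: str = "strict"):
    """Polarize 0/1 allele codes so that 1 means derived, using the outgroup.

    strict: keep only sites where the outgroup is fixed; its allele is
        ancestral.  major: the outgroup's major allele is ancestral;
        50/50 outgroup ties are dropped (no defensible ancestral call).

    Returns ``(polarized_matrix, SiteFrequencyTable)``.
    """
    if policy not in ("strict", "major"):
        raise ValueError("policy must be 'strict' or 'major'")
    og = matrix.pop_columns("O")
    geno = matrix.genotypes
    counters = dict(matrix.counters)
    counters.setdefault("outgroup_polymorphic", 0)
    counters.setdefault("outgroup_tie", 0)
    counters.setdefault("outgroup_uncalled", 0)

    og_block = geno[:, og]
    miss = og_block == _MISSING
    ones = np.where(miss, 0, og_block).sum(axis=1)
    called = (~miss).sum(axis=1)
    uncalled = called == 0
    counters["outgroup_uncalled"] += int(uncalled.sum())
    if policy == "strict":
        polymorphic = (ones > 0) & (ones < called)
        counters["outgroup_polymorphic"] += int((polymorphic & ~uncalled).sum())
        keep = ~uncalled & ~polymorphic
        ancestral = (ones == called).astype(np.int8)
    else:
        tie = (2 * ones == called) & ~uncalled
        counters["outgroup_tie"] += int(tie.sum())
        keep = ~uncalled & ~tie
        ancestral = (2 * ones > called).astype(np.int8)

    geno = geno[keep].copy()
    flip = ancestral[keep] == 1
    miss = geno == _MISSING
    geno[flip] = 1 - geno[flip]
    geno[miss] = _MISSING
    out = HaplotypeMatrix(geno, matrix.positions[keep], matrix.pops,
                          polarized=True, length=matrix.length,
                          source=matrix.source, counters=counters)
    return out, frequency_table(out)


def frequency_table(matrix: HaplotypeMatrix) -> SiteFrequencyTable:
    """Per-site derived counts and called totals for a polarized matrix.

    Frequencies are computed over non-missing haplotypes; sites where
    any population has zero calls, or that are monomorphic across all
    four populations, are dropped (and counted).
    """
    if not matrix.polarized:
        raise ValueError("matrix must be polarized first")
    cols = [matrix.pop_columns(p) for p in POPULATIONS]
    L = matrix.n_sites
    derived = np.zeros((L, 4), dtype=np.int64)
    called = np.zeros((L, 4), dtype=np.int64)
    for i, c in enumerate(cols):
        block = matrix.genotypes[:, c]
        miss = block == _MISSING
        derived[:, i] = np.where(miss, 0, block).sum(axis=1)
        called[:, i] = (~miss).sum(axis=1)
    ok = (called > 0).all(axis=1)
    poly = ~((derived == 0).all(axis=1) | (derived == called).all(axis=1))
    keep = ok & poly
    matrix.counters["uncalled_population"] = \
        matrix.counters.get("uncalled_population", 0) + int((~ok).sum())
    matrix.counters["monomorphic"] = \
        matrix.counters.get("monomorphic", 0) + int((ok & ~poly).sum())
    return SiteFrequencyTable(derived[keep], called[keep], matrix.positions[keep])
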