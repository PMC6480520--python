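"""Four-taxon introgression statistics in their pairwise-distance form.

Given the rooted species tree (((P1,P2),P3),O) and derived-allele
frequencies ``p1..p4`` at each biallelic site, the classic ABBA/BABA
site patterns can be rewritten as weighted pairwise distances

    ABBA_k = [p2*d13 - p1*d23 + p3*d12] * (1 - p4) / 2
    BABA_k = [p1*d23 - p2*d13 + p3*d12] * (1 - p4) / 2

where ``d_xy = p_x(1-p_y) + (1-p_x)p_y`` is the average pairwise
nucleotide difference between populations x and y at that site.  This
module computes, over a window of L variant sites,

* Patterson's D      = sum(p2*d13 - p1*d23) / sum(p3*d12)
* f_hom              = same numerator / sum(p3*d13 - p1*pi3)
* f_d (Martin et al.)= same numerator / sum(pD*d1D - p1*piD)
                       with pD the larger of (p2, p3) per site
* d_f (distance
  fraction)          = sum(p2*d13 - p1*d23) / sum(p2*d13 + p1*d23)

d_f incorporates the BBAA species-tree distance into its denominator so
it is bounded in [-1, 1], symmetric (positive for P3<->P2 gene flow,
negative for P3<->P1) and estimates the fraction of introgression
directly.  All sites are assumed polarized so that 1 means derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SiteFrequencyTable",
    "WindowStats",
    "site_dxy",
    "site_pi",
    "site_abba_baba_bbaa",
    "laplace_smooth",
    "patterson_d",
    "f_hom",
    "f_d",
    "d_f",
    "compute_window_stats",
]

#: population order used in every (L, 4) frequency array
POPULATIONS = ("P1", "P2", "P3", "O")


def site_dxy(px, py):
    """Average pairwise difference between populations x and y at one site.

    ``d_xy = p_x (1 - p_y) + (1 - p_x) p_y``; symmetric, in [0, 1].
    Accepts scalars or numpy arrays.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    return px * (1.0 - py) + (1.0 - px) * py


def site_pi(p, n=None, unbiased=False):
    """Within-population diversity ``2 p (1 - p)`` at one site.

    With ``unbiased=True`` the small-sample factor ``n / (n - 1)`` is
    applied (requires ``n``, the number of haplotypes).  The default is
    the plain frequency form, matching the frequency-based d_xy used
    throughout this module.
    """
    p = np.asarray(p, dtype=float)
    pi = 2.0 * p * (1.0 - p)
    if unbiased:
        if n is None:
            raise ValueError("unbiased=True requires the haplotype count n")
        pi = pi * (n / (n - 1.0))
    return pi


def laplace_smooth(derived_count, n):
    """Laplace-smoothed derived-allele frequency ``(count + 1) / (n + 2)``.

    One derived and one ancestral allele are added to the sample; in
    genome scans this is applied to P1 and P2 only, stabilising windows
    where ``p1`` or ``p2`` would otherwise be exactly 0 or 1.
    """
    derived_count = np.asarray(derived_count, dtype=float)
    n = np.asarray(n, dtype=float)
    return (derived_count + 1.0) / (n + 2.0)


def site_abba_baba_bbaa(p1, p2, p3, p4=0.0):
    """Frequency-weighted ABBA, BABA and BBAA pattern weights at one site.

    Returns the distance-form expressions

        ABBA = [p2*d13 - p1*d23 + p3*d12] * (1 - p4) / 2
        BABA = [p1*d23 - p2*d13 + p3*d12] * (1 - p4) / 2
        BBAA = p1 * p2 * (1 - p3) * (1 - p4)

    Under strict outgroup polarization p4 is 0 for every retained site.
    """
    d12 = site_dxy(p1, p2)
    d13 = site_dxy(p1, p3)
    d23 = site_dxy(p2, p3)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    p4 = np.asarray(p4, dtype=float)
    core = p2 * d13 - p1 * d23
    abba = (core + p3 * d12) * (1.0 - p4) / 2.0
    baba = (-core + p3 * d12) * (1.0 - p4) / 2.0
    bbaa = p1 * p2 * (1.0 - p3) * (1.0 - p4)
    return abba, baba, bbaa


@dataclass
class SiteFrequencyTable:
    """Per-site derived-allele counts for the four populations.

    ``derived`` and ``called`` are (L, 4) integer arrays in the
    population order P1, P2, P3, O; ``called`` holds the number of
    non-missing haplotypes at each site so that frequencies are
    ``derived / called``.  Sites where any population has zero called
    haplotypes must be removed upstream.
    """

    derived: np.ndarray
    called: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.derived = np.atleast_2d(np.asarray(self.derived, dtype=np.int64))
        self.called = np.atleast_2d(np.asarray(self.called, dtype=np.int64))
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.derived.shape != self.called.shape or self.derived.shape[1] != 4:
            raise ValueError("derived/called must both be (L, 4)")
        if len(self.positions) != len(self.derived):
            raise ValueError("positions length mismatch")
        if np.any(self.called <= 0):
            raise ValueError("every population needs >= 1 called haplotype per site")
        if np.any(self.derived < 0) or np.any(self.derived > self.called):
            raise ValueError("derived counts must lie in [0, called]")

    def __len__(self):
        return len(self.positions)

    @property
    def p(self) -> np.ndarray:
        """(L, 4) derived-allele frequencies."""
        return self.derived / self.called

    def frequencies(self, smooth: bool = False) -> np.ndarray:
        """Frequencies, optionally Laplace-smoothing P1 and P2 only."""
        p = self.p
        if smooth:
            p = p.copy()
            for i in (0, 1):
                p[:, i] = laplace_smooth(self.derived[:, i], self.called[:, i])
        return p

    def select(self, mask_or_index) -> "SiteFrequencyTable":
        return SiteFrequencyTable(
            self.derived[mask_or_index],
            self.called[mask_or_index],
            self.positions[mask_or_index],
        )


@dataclass
class WindowStats:
    """All four statistics plus their accumulated sums for one window."""

    D: float
    f_hom: float
    f_d: float
    d_f: float
    num: float          # shared numerator sum(p2*d13 - p1*d23)
    den_D: float        # sum(p3*d12)
    den_fhom: float     # sum(p3*d13 - p1*pi3)
    den_fd: float       # sum(pD*d1D - p1*piD)
    den_df: float       # sum(p2*d13 + p1*d23)
    n_snps: int
    window_start: int = 0
    window_end: int = 0
    smoothed: bool = False
    flags: list = field(default_factory=list)


def _frequencies(sites, smooth=False):
    """Coerce input to an (L, 4) frequency array (P1, P2, P3, O)."""
    if isinstance(sites, SiteFrequencyTable):
        return sites.frequencies(smooth=smooth)
    p = np.atleast_2d(np.asarray(sites, dtype=float))
    if p.shape[1] != 4:
        raise ValueError("expected frequencies with shape (L, 4)")
    if smooth:
        raise ValueError("Laplace smoothing needs allele counts; pass a SiteFrequencyTable")
    return p


def _window_sums(p, unbiased_pi=False, n3=None, nD=None):
    p1, p2, p3 = p[:, 0], p[:, 1], p[:, 2]
    d12 = site_dxy(p1, p2)
    d13 = site_dxy(p1, p3)
    d23 = site_dxy(p2, p3)
    num = float(np.sum(p2 * d13 - p1 * d23))
    den_D = float(np.sum(p3 * d12))
    pi3 = site_pi(p3, n=n3, unbiased=unbiased_pi)
    den_fhom = float(np.sum(p3 * d13 - p1 * pi3))
    # PD: the population (P2 or P3) with the higher derived frequency,
    # P3 on ties (value-irrelevant since pD, d1D, piD coincide).
    use3 = p3 >= p2
    pD = np.where(use3, p3, p2)
    d1D = site_dxy(p1, pD)
    piD = site_pi(pD, n=nD, unbiased=unbiased_pi)
    den_fd = float(np.sum(pD * d1D - p1 * piD))
    den_df = float(np.sum(p2 * d13 + p1 * d23))
    return num, den_D, den_fhom, den_fd, den_df


def _ratio(num, den, positive_den=False):
    if den == 0 or (positive_den and den <= 0):
        return float("nan")
    return num / den


def compute_window_stats(
    sites,
    smooth: bool = False,
    unbiased_pi: bool = False,
    window_start: int = 0,
    window_end: int = 0,
) -> WindowStats:
    """Compute D, f_hom, f_d and d_f over a window of polarized sites.

    ``sites`` is a :class:`SiteFrequencyTable` or an (L, 4) array of
    derived-allele frequencies.  Zero denominators yield NaN for the
    affected statistic (never an exception); the cause is recorded in
    ``flags``.  With ``smooth=True``, P1 and P2 frequencies are Laplace
    smoothed before all distances are formed.
    """
    p = _frequencies(sites, smooth=smooth)
    flags = []
    if len(p) == 0:
        return WindowStats(*([float("nan")] * 4), 0.0, 0.0, 0.0, 0.0, 0.0, 0,
                           window_start, window_end, smooth, ["no_snps"])
    num, den_D, den_fhom, den_fd, den_df = _window_sums(p, unbiased_pi=unbiased_pi)
    D = _ratio(num, den_D, positive_den=True)
    fh = _ratio(num, den_fhom)
    fd = _ratio(num, den_fd)
    df = _ratio(num, den_df, positive_den=True)
    for name, val in (("D", D), ("f_hom", fh), ("f_d", fd), ("d_f", df)):
        if np.isnan(val):
            flags.append(f"undefined_{name}")
    return WindowStats(D, fh, fd, df, num, den_D, den_fhom, den_fd, den_df,
                       len(p), window_start, window_end, smooth, flags)


def patterson_d(sites, smooth=False):
    """Distance-form Patterson's D over a window; NaN if the denominator is 0."""
    return compute_window_stats(sites, smooth=smooth).D


def f_hom(sites, smooth=False):
    """Green et al.'s f_hom (assumes P3 -> P2 introgression); NaN if undefined."""
    return compute_window_stats(sites, smooth=smooth).f_hom


def f_d(sites, smooth=False):
    """Martin et al.'s dynamic f_d estimator; NaN if undefined."""
    return compute_window_stats(sites, smooth=smooth).f_d


def d_f(sites, smooth=False):
    """The distance fraction, bounded in [-1, 1]; NaN if the denominator is 0."""
    return compute_window_stats(sites, smooth=smooth).d_f
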