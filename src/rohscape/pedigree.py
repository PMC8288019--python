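"""Pedigree simulation of identity by descent with Poisson recombination.

Founder haplotypes carry globally unique allele labels.  A gamete is formed
by drawing a Poisson number of crossovers (no interference) at uniform
genetic positions and alternating between the parent's two haplotypes.  An
offspring's realized autozygous fraction is the physical fraction of its
genome where the maternal and paternal labels coincide — the quantity that
window-based ROH methods try to estimate.  For the offspring of two
first-degree relatives (full sibs) this fraction averages 0.25.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MATINGS = ("full_sib", "self")


@dataclass(frozen=True)
class Chromosome:
    """Physical length in bp and genetic length in Morgans."""

    phys_bp: int
    morgans: float


class _Hap:
    """Piecewise-constant founder labels along one chromosome (Morgans)."""

    __slots__ = ("breaks", "labels")

    def __init__(self, breaks: np.ndarray, labels: np.ndarray):
        self.breaks = breaks     # starts of segments; breaks[0] == 0.0
        self.labels = labels


def _founder_hap(label: int) -> _Hap:
    return _Hap(np.array([0.0]), np.array([label]))


def _gamete(rng, hap0: _Hap, hap1: _Hap, gen_len: float) -> _Hap:
    n_x = rng.poisson(gen_len)
    cur = int(rng.integers(2))
    if n_x == 0:
        h = hap0 if cur == 0 else hap1
        return _Hap(h.breaks.copy(), h.labels.copy())
    xs = np.sort(rng.uniform(0.0, gen_len, size=n_x))
    bounds = np.concatenate([[0.0], xs, [gen_len]])
    breaks: list[float] = []
    labels: list[int] = []
    for i in range(len(bounds) - 1):
        s, e = bounds[i], bounds[i + 1]
        h = hap0 if cur == 0 else hap1
        j0 = np.searchsorted(h.breaks, s, side="right") - 1
        j1 = np.searchsorted(h.breaks, e, side="left")
        seg_starts = np.concatenate([[s], h.breaks[j0 + 1:j1]])
        for b, lab in zip(seg_starts, h.labels[j0:j1]):
            if labels and labels[-1] == lab:
                continue
            breaks.append(float(b))
            labels.append(int(lab))
        cur ^= 1
    return _Hap(np.array(breaks), np.array(labels))


def _autozygous_segments(mat: _Hap, pat: _Hap, gen_len: float) -> np.ndarray:
    """Maximal [start, end) genetic intervals where labels coincide."""
    breaks = np.union1d(mat.breaks, pat.breaks)
    ends = np.concatenate([breaks[1:], [gen_len]])
    mi = np.searchsorted(mat.breaks, breaks, side="right") - 1
    pi = np.searchsorted(pat.breaks, breaks, side="right") - 1
    same = mat.labels[mi] == pat.labels[pi]
    segs = []
    open_start = None
    for s, e, eq in zip(breaks, ends, same):
        if eq and open_start is None:
            open_start = s
        elif not eq and open_start is not None:
            segs.append((open_start, s))
            open_start = None
    if open_start is not None:
        segs.append((open_start, gen_len))
    return np.array(segs, dtype=float).reshape(-1, 2)


@dataclass
class PedigreeSimResult:
    """Realized autozygosity of simulated offspring.

    fractions : array, one realized autozygous genome fraction per offspring
    ibd_segments : per offspring, per chromosome, an (n, 2) array of
        physical [start, end) autozygous intervals in bp
    """

    fractions: np.ndarray
    ibd_segments: list[list[np.ndarray]]
    chromosomes: tuple[Chromosome, ...]

    @property
    def mean_fraction(self) -> float:
        return float(self.fractions.mean())


def simulate_pedigree_ibd(n_offspring: int, chrom_map, mating: str = "full_sib",
                          seed: int | None = None) -> PedigreeSimResult:
    """Simulate realized autozygosity for offspring of an inbred mating.

    Parameters
    ----------
    n_offspring
        Number of offspring; each comes from an independently drawn family,
        so the mean converges to the pedigree expectation (0.25 for full
        sibs, 0.5 for selfing a non-inbred founder).
    chrom_map
        Iterable of (physical length bp, genetic length Morgans) pairs or
        :class:`Chromosome` objects.
    mating
        "full_sib" (founder couple -> two sibs -> offspring) or "self"
        (a non-inbred founder selfed).
    """
    chroms = tuple(c if isinstance(c, Chromosome) else Chromosome(*c)
                   for c in chrom_map)
    if not chroms:
        raise ValueError("empty chromosome map")
    if any(c.morgans < 0 or c.phys_bp <= 0 for c in chroms):
        raise ValueError("chromosomes need phys_bp > 0 and morgans >= 0")
    if mating not in MATINGS:
        raise ValueError(f"mating must be one of {MATINGS}")
    rng = np.random.default_rng(seed)
    total_bp = sum(c.phys_bp for c in chroms)
    fractions = np.empty(n_offspring)
    all_segments: list[list[np.ndarray]] = []
    for k in range(n_offspring):
        ibd_bp = 0.0
        per_chrom: list[np.ndarray] = []
        for c in chroms:
            g = c.morgans
            if mating == "full_sib":
                p1 = (_founder_hap(0), _founder_hap(1))
                p2 = (_founder_hap(2), _founder_hap(3))
                sib1 = (_gamete(rng, *p1, g), _gamete(rng, *p2, g))
                sib2 = (_gamete(rng, *p1, g), _gamete(rng, *p2, g))
                mat = _gamete(rng, *sib1, g)
                pat = _gamete(rng, *sib2, g)
            else:  # self
                f = (_founder_hap(0), _founder_hap(1))
                mat = _gamete(rng, *f, g)
                pat = _gamete(rng, *f, g)
            segs = _autozygous_segments(mat, pat, g) if g > 0 else (
                np.array([[0.0, 0.0]])[:0] if mat.labels[0] != pat.labels[0]
                else np.array([[0.0, 0.0]]))
            if g > 0:
                scale = c.phys_bp / g
                phys = np.round(segs * scale).astype(np.int64)
            else:
                # zero genetic length: whole chromosome is one locus
                phys = (np.array([[0, c.phys_bp]], dtype=np.int64)
                        if len(segs) else
                        np.empty((0, 2), dtype=np.int64))
            phys = phys[phys[:, 1] > phys[:, 0]] if len(phys) else phys
            per_chrom.append(phys)
            ibd_bp += float((phys[:, 1] - phys[:, 0]).sum()) if len(phys) else 0.0
        fractions[k] = ibd_bp / total_bp
        all_segments.append(per_chrom)
    return PedigreeSimResult(fractions, all_segments, chroms)
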