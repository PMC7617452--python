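"""Heterozygosity-conditioned divergence: the fraction of single-read
pseudo-haploid calls in a low-coverage sample that match the alternate allele
at a high-coverage individual's heterozygous transversion sites.

Expectations: 1/2 when the low-coverage reads come from the same individual,
1/3 for a same-population individual (with three lineages, the probability
that the third carries the derived allele given the first two differ), and
lower for diverged populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from . import simdata
from .popgen import pileup_from_alignments, pseudo_haploid_call
from .util import is_transversion


# ---------------------------------------------------------------------------
# heterozygous-site calling


def _genotype_likelihoods(n_ref: int, n_alt: int, n_other: int, eps: float):
    """Log10 likelihoods of (RR, RA, AA) for a biallelic pileup."""
    e3 = eps / 3.0
    het_match = 0.5 * (1.0 - eps) + 0.5 * e3
    ll = []
    for p_ref, p_alt in ((1.0 - eps, e3), (het_match, het_match), (e3, 1.0 - eps)):
        ll.append(n_ref * math.log10(p_ref) + n_alt * math.log10(p_alt)
                  + n_other * math.log10(e3))
    return ll


def call_het_sites(pileups: dict[int, list[str]], ref_alleles: dict[int, str],
                   min_call_qual: float = 20.0, min_mq: float = 25.0,
                   site_mq: dict[int, float] | None = None,
                   depth_range: tuple[int, int] = (15, 40),
                   transversions_only: bool = True, eps: float = 0.01) -> pd.DataFrame:
    """Maximum-likelihood diploid calls, retaining filtered heterozygous sites.

    ``pileups``: 1-based position -> read bases for the high-coverage sample.
    The alternate allele is the most common non-reference base.  Call quality
    is the Phred-scaled likelihood margin between the best and second-best
    genotype.  Returns a frame with pos, ref, alt, depth, qual.
    """
    if not (0.0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    lo, hi = depth_range
    rows = []
    for pos, bases in sorted(pileups.items()):
        ref = ref_alleles[pos]
        depth = len(bases)
        if depth < lo or depth > hi:
            continue
        if site_mq is not None and not site_mq.get(pos, 0.0) > min_mq:
            continue
        non_ref = [b for b in bases if b != ref and b in "ACGT"]
        if not non_ref:
            continue
        alt = max(set(non_ref), key=lambda b: (non_ref.count(b), -"ACGT".index(b)))
        if transversions_only and not is_transversion(ref, alt):
            continue
        n_ref = sum(b == ref for b in bases)
        n_alt = sum(b == alt for b in bases)
        ll = _genotype_likelihoods(n_ref, n_alt, depth - n_ref - n_alt, eps)
        order = sorted(range(3), key=lambda i: ll[i], reverse=True)
        if order[0] != 1:  # best genotype is not heterozygous
            continue
        qual = 10.0 * (ll[order[0]] - ll[order[1]])
        if qual > min_call_qual:
            rows.append({"pos": pos, "ref": ref, "alt": alt,
                         "depth": depth, "qual": qual})
    return pd.DataFrame(rows, columns=["pos", "ref", "alt", "depth", "qual"])


# ---------------------------------------------------------------------------
# the fraction statistic


@dataclass
class DerivedFractionResult:
    n_observed: int
    n_alt: int
    fraction: float
    ci_low: float
    ci_high: float
    status: str = "ok"

    @classmethod
    def from_counts(cls, n_alt: int, n_observed: int) -> "DerivedFractionResult":
        if n_observed == 0:
            return cls(0, 0, math.nan, math.nan, math.nan, status="undefined")
        ci = binomtest(n_alt, n_observed).proportion_ci(confidence_level=0.95,
                                                        method="exact")
        return cls(n_observed, n_alt, n_alt / n_observed, ci.low, ci.high)


def derived_allele_fraction(het_sites: pd.DataFrame,
                            low_pileups: dict[int, list[str]],
                            seed: int = 0) -> DerivedFractionResult:
    """Alternate-allele match fraction with mandatory single-read-only calls.

    Only het-site positions are considered; a site counts when exactly one
    read overlaps it and that read's base equals ref or alt.
    """
    phv = pseudo_haploid_call(
        {p: b for p, b in low_pileups.items() if p in set(het_sites["pos"])},
        het_sites, mode="single_read_only", seed=seed)
    observed = phv.calls != -1
    n_obs = int(observed.sum())
    n_alt = int((phv.calls == 1).sum())
    return DerivedFractionResult.from_counts(n_alt, n_obs)


# ---------------------------------------------------------------------------
# coalescent null and divergence scan


@dataclass
class NullResult:
    mean_fraction: float
    mc_se: float
    per_replicate: list[float]
    n_observed: int


def null_expectation_same_pop(theta: float, n_diploids: int = 20,
                              n_replicates: int = 10, n_loci: int = 200,
                              seed: int = 0,
                              same_individual: bool = False) -> NullResult:
    """Same-population expectation of the fraction statistic (closed form 1/3).

    Each replicate pools ``n_loci`` independent coalescent loci with per-locus
    theta = ``theta / n_loci``: individual 0 is the high-coverage truth and
    one random allele of individual 1 is sampled at individual 0's
    heterozygous sites.  With ``same_individual=True`` the sampled allele
    comes from individual 0 itself (symmetry forces expectation 1/2).

    Independent loci matter: on a single genealogy all sites are perfectly
    correlated and the replicate-level Monte-Carlo error stays large no
    matter how many sites segregate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_diploids < 2 and not same_individual:
        raise ValueError("need at least two diploids")
    rng = np.random.default_rng(seed)
    fractions = []
    total_obs = 0
    sampled_ind = 0 if same_individual else 1
    for _ in range(n_replicates):
        n_alt = n_obs = 0
        for _ in range(n_loci):
            panel = simdata.simulate_coalescent_panel(
                n_diploids, 1, theta=theta / n_loci,
                seed=int(rng.integers(2**63 - 1)))
            het = panel.het_sites(0)
            if het.size == 0:
                continue
            hap_choice = rng.integers(2, size=het.size)
            sampled = panel.haplotypes[2 * sampled_ind + hap_choice, het]
            n_alt += int(sampled.sum())
            n_obs += het.size
        if n_obs:
            fractions.append(n_alt / n_obs)
            total_obs += n_obs
    mean = float(np.mean(fractions))
    se = float(np.std(fractions, ddof=1) / math.sqrt(len(fractions))) \
        if len(fractions) > 1 else math.nan
    return NullResult(mean, se, fractions, total_obs)


def _scan_one_locus(split_time: float, theta: float, n_diploids_per_pop: int,
                    ref_length: int, n_reads: int,
                    fragment_model, damage_model, error_rate: float,
                    end_to_end: bool, rng: np.random.Generator) -> tuple[int, int]:
    """(n_alt, n_observed) at one simulated locus."""
    from . import readmap

    n_pops = 2 if split_time > 0 else 1
    panel = simdata.simulate_coalescent_panel(
        n_diploids_per_pop, n_pops, split_time, theta,
        seed=int(rng.integers(2**63 - 1)), chrom_length=ref_length)
    ref = simdata.random_seq(ref_length, rng)
    alleles = simdata.assign_alleles(panel, reference=ref,
                                     seed=int(rng.integers(2**63 - 1)))
    het = panel.het_sites(0)  # high-coverage individual: pop 0, individual 0
    tv = np.array([is_transversion(alleles["ref"][s], alleles["alt"][s]) for s in het]) \
        if het.size else np.array([], dtype=bool)
    het = het[tv]
    if het.size == 0:
        return 0, 0
    het_sites = pd.DataFrame({
        "pos": alleles["pos"].to_numpy()[het],
        "ref": alleles["ref"].to_numpy()[het],
        "alt": alleles["alt"].to_numpy()[het],
    })
    # low-coverage individual: first diploid of the other population (or the
    # second diploid under panmixia)
    low = n_diploids_per_pop if n_pops == 2 else 1
    hap0 = simdata.apply_haplotype(ref, panel, alleles, 2 * low)
    hap1 = simdata.apply_haplotype(ref, panel, alleles, 2 * low + 1)
    reads = simdata.simulate_diploid_reads(
        hap0, hap1, n_reads, fragment_model, damage_model, error_rate,
        seed=int(rng.integers(2**63 - 1)), individual_id=f"ind{low}")
    if end_to_end:
        recs, _ = readmap.map_reads_end_to_end(reads, ("ref", ref),
                                               max_mismatch_rate=0.1,
                                               min_len=fragment_model.min_len)
        recs, _ = readmap.filter_alignments(recs, min_map_score=25,
                                            min_len=fragment_model.min_len)
    else:
        recs = readmap.truth_alignments(reads, "ref")
    pile = pileup_from_alignments(recs, reads.sequences(), het_sites["pos"])
    res = derived_allele_fraction(het_sites, pile,
                                  seed=int(rng.integers(2**63 - 1)))
    return res.n_alt, res.n_observed


def divergence_scan(split_times: list[float], theta: float = 12.0,
                    n_diploids_per_pop: int = 1, n_loci: int = 50,
                    n_replicates: int = 10, ref_length: int = 3000,
                    n_reads_per_locus: int = 40,
                    fragment_model=None, damage_model=None,
                    error_rate: float = 0.001, end_to_end: bool = True,
                    seed: int = 0) -> pd.DataFrame:
    """Fraction statistic across a split-time grid, end-to-end through read
    simulation, mapping, filtering and single-read pseudo-haploid calling.

    Returns one row per split time: mean fraction across replicates, the MC
    standard error over replicates, and pooled counts.
    """
    if len(split_times) < 2 or 0.0 not in split_times:
        raise ValueError("split_times must include 0 and at least one other value")
    fragment_model = fragment_model or simdata.FragmentModel()
    damage_model = damage_model or simdata.DamageModel()
    rng = np.random.default_rng(seed)
    rows = []
    for t in split_times:
        rep_fracs = []
        tot_alt = tot_obs = 0
        for _ in range(n_replicates):
            n_alt = n_obs = 0
            for _ in range(n_loci):
                a, o = _scan_one_locus(t, theta, max(n_diploids_per_pop, 1 if t > 0 else 2),
                                       ref_length, n_reads_per_locus, fragment_model,
                                       damage_model, error_rate, end_to_end, rng)
                n_alt += a
                n_obs += o
            if n_obs:
                rep_fracs.append(n_alt / n_obs)
            tot_alt += n_alt
            tot_obs += n_obs
        mean = float(np.mean(rep_fracs)) if rep_fracs else math.nan
        se = float(np.std(rep_fracs, ddof=1) / math.sqrt(len(rep_fracs))) \
            if len(rep_fracs) > 1 else math.nan
        rows.append({"split_time": t, "fraction": mean, "mc_se": se,
                     "n_alt": tot_alt, "n_observed": tot_obs,
                     "n_replicates": len(rep_fracs)})
    return pd.DataFrame(rows)
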