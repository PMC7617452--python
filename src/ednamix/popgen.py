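"""Nuclear-panel statistics: site filtering, pseudo-haploid calls, rescaled
Hamming distances, neighbor joining, sparse-sample PCA projection and f4
statistics with a weighted block jackknife."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import is_transversion

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid panel: samples x sites alt-allele counts {0,1,2}, -1 missing."""

    genotypes: np.ndarray  # int8 (n_samples, n_sites)
    samples: list[str]
    sites: pd.DataFrame  # columns: chrom, pos, ref, alt, mq
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError("genotype matrix shape does not match samples x sites")
        bad = ~np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def an(self) -> np.ndarray:
        """Allele number per site: 2 x non-missing diploids."""
        return 2 * (self.genotypes != MISSING).sum(axis=0)

    def allele_frequencies(self, sample_idx=None) -> np.ndarray:
        """Alt-allele frequency per site (NaN where all genotypes missing)."""
        g = self.genotypes if sample_idx is None else self.genotypes[sample_idx]
        valid = g != MISSING
        n = valid.sum(axis=0)
        alt = np.where(valid, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def subset_sites(self, mask) -> "GenotypeMatrix":
        return GenotypeMatrix(self.genotypes[:, mask], list(self.samples),
                              self.sites.loc[mask].reset_index(drop=True),
                              dict(self.populations))


def genotype_matrix_from_panel(panel, alleles: pd.DataFrame | None = None,
                               chrom: str = "chr1", sample_prefix: str = "ind") -> GenotypeMatrix:
    """Build a GenotypeMatrix straight from a simdata CoalescentPanel."""
    from .simdata import assign_alleles

    if alleles is None:
        alleles = assign_alleles(panel)
    sites = pd.DataFrame({
        "chrom": chrom, "pos": panel.positions,
        "ref": alleles["ref"].to_numpy(), "alt": alleles["alt"].to_numpy(),
        "mq": 60.0,
    })
    samples = [f"{sample_prefix}{i}" for i in range(panel.n_diploids)]
    pops = {s: p for s, p in zip(samples, panel.pop_labels)}
    return GenotypeMatrix(panel.diploid_genotypes(), samples, sites, pops)


# ---------------------------------------------------------------------------
# VCF ingest


def read_vcf(path) -> GenotypeMatrix:
    """Read a diploid VCF (uncompressed text) into a GenotypeMatrix.

    Multi-allelic records are skipped; MQ defaults to 60 when absent.
    """
    import pysam

    rows, geno_rows = [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf.fetch():
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            mq = rec.info.get("MQ", 60.0)
            rows.append({"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                         "alt": rec.alts[0], "mq": float(mq)})
            codes = []
            for s in samples:
                alleles = rec.samples[s]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    codes.append(MISSING)
                else:
                    codes.append(int(sum(alleles)))
            geno_rows.append(codes)
    geno = (np.array(geno_rows, dtype=np.int8).T if geno_rows
            else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(geno, samples, pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "mq"]))


# ---------------------------------------------------------------------------
# site filtering


@dataclass
class SiteFilterResult:
    matrix: GenotypeMatrix
    removed_mq: int
    removed_an: int
    removed_biallelic: int


def filter_site_panel(gm: GenotypeMatrix, min_mq: float = 20.0, min_an: int = 150,
                      biallelic_only: bool = True) -> SiteFilterResult:
    """Strict filters: keep sites with MQ > min_mq AND AN > min_an."""
    mq = gm.sites["mq"].to_numpy(dtype=float)
    an = gm.an()
    ok_mq = mq > min_mq
    ok_an = an > min_an
    if biallelic_only:
        ref = gm.sites["ref"].to_numpy()
        alt = gm.sites["alt"].to_numpy()
        ok_bi = (ref != alt) & np.isin(ref, list("ACGT")) & np.isin(alt, list("ACGT"))
    else:
        ok_bi = np.ones(gm.n_sites, dtype=bool)
    keep = ok_mq & ok_an & ok_bi
    return SiteFilterResult(gm.subset_sites(keep),
                            removed_mq=int((~ok_mq).sum()),
                            removed_an=int((ok_mq & ~ok_an).sum()),
                            removed_biallelic=int((ok_mq & ok_an & ~ok_bi).sum()))


# ---------------------------------------------------------------------------
# pseudo-haploid calling


@dataclass
class PseudoHaploidVector:
    """Per-site haploid codes {0, 1, -1}; doubles to {0, 2} when merged with
    diploid codes."""

    calls: np.ndarray  # int8, aligned with a site table
    sites: pd.DataFrame
    mode: str
    seed: int

    def doubled(self) -> np.ndarray:
        return np.where(self.calls == MISSING, MISSING, 2 * self.calls).astype(np.int8)

    @property
    def n_called(self) -> int:
        return int((self.calls != MISSING).sum())


def pseudo_haploid_call(pileups: dict[int, list[str]], sites: pd.DataFrame,
                        mode: str = "random_read", seed: int = 0) -> PseudoHaploidVector:
    """One sampled allele per site from a read pileup.

    ``pileups`` maps 1-based position -> list of read bases.  random_read
    picks one read uniformly; single_read_only calls only where exactly one
    read overlaps.  A base that is neither ref nor alt leaves the site missing.
    """
    if mode not in ("random_read", "single_read_only"):
        raise ValueError(f"unknown mode {mode!r}")
    known = set(int(p) for p in sites["pos"])
    unknown = set(pileups) - known
    if unknown:
        raise KeyError(f"pileup positions absent from panel: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    calls = np.full(len(sites), MISSING, dtype=np.int8)
    for i, (pos, ref, alt) in enumerate(zip(sites["pos"], sites["ref"], sites["alt"])):
        bases = pileups.get(int(pos), [])
        if not bases:
            continue
        if mode == "single_read_only":
            if len(bases) != 1:
                continue
            b = bases[0]
        else:
            b = bases[int(rng.integers(len(bases)))]
        if b == ref:
            calls[i] = 0
        elif b == alt:
            calls[i] = 1
    return PseudoHaploidVector(calls, sites, mode, seed)


def pileup_from_alignments(alignments, reads: dict[str, str],
                           positions) -> dict[int, list[str]]:
    """Per-position read bases (reference orientation) at 1-based positions."""
    from .util import revcomp

    wanted = {int(p) for p in positions}
    pile: dict[int, list[str]] = {}
    for rec in alignments:
        seq = reads[rec.read_id]
        if rec.strand == "-":
            seq = revcomp(seq)
        for pos in range(rec.start + 1, rec.start + len(seq) + 1):
            if pos in wanted:
                pile.setdefault(pos, []).append(seq[pos - 1 - rec.start])
    return pile


# ---------------------------------------------------------------------------
# Hamming distances and neighbor joining


@dataclass
class DistanceMatrix:
    values: np.ndarray  # (n, n) float, NaN where undefined
    labels: list[str]
    pair_sites: np.ndarray  # observed-site counts per pair
    rescaled: bool

    def validate(self):
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise AssertionError("distance matrix must be symmetric")


def hamming_distance_matrix(codes: np.ndarray, labels: list[str],
                            rescale_missing: bool = True) -> DistanceMatrix:
    """Pairwise sum |g_i - g_j| over mutually observed sites.

    With rescaling, each pair distance is multiplied by
    total sites / pair-observed sites (flat-missing correction).
    """
    codes = np.asarray(codes)
    n, S = codes.shape
    if n < 2:
        raise ValueError("need at least two samples")
    values = np.zeros((n, n))
    pair_sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[i] != MISSING) & (codes[j] != MISSING)
            m = int(both.sum())
            pair_sites[i, j] = pair_sites[j, i] = m
            if m == 0:
                values[i, j] = values[j, i] = math.nan
                continue
            raw = float(np.abs(codes[i, both].astype(int) - codes[j, both]).sum())
            d = raw * S / m if rescale_missing else raw
            values[i, j] = values[j, i] = d
    np.fill_diagonal(pair_sites, (codes != MISSING).sum(axis=1))
    dm = DistanceMatrix(values, list(labels), pair_sites, rescale_missing)
    dm.validate()
    return dm


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string with branch
    lengths (negative estimates clamped to zero)."""
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains undefined entries")
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least three samples")
    D = dm.values.astype(float).copy()
    nodes = [f"{lab}" for lab in dm.labels]
    active = list(range(n))
    newick = {i: nodes[i] for i in active}
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        newick_new = f"({newick[i]}:{li:.12g},{newick[j]}:{lj:.12g})"
        # distances from the new node to the remaining ones
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        new_idx = D.shape[0] - 1
        newick[new_idx] = newick_new
        active = [a for a in active if a not in (i, j)] + [new_idx]
    i, j = active
    lij = max(D[i, j], 0.0)
    return f"({newick[i]}:{lij / 2.0:.12g},{newick[j]}:{lij / 2.0:.12g});"


# ---------------------------------------------------------------------------
# PCA with sparse projection


@dataclass
class PCAModel:
    mean: np.ndarray  # per-site 2p
    scale: np.ndarray  # per-site sqrt(p(1-p))
    loadings: np.ndarray  # (n_sites, k), orthonormal columns
    eigenvalues: np.ndarray
    modern_scores: np.ndarray  # (n_samples, k)
    samples: list[str]
    usable_sites: np.ndarray | None = None  # mask into the pre-filter site axis


def pca_fit(gm: GenotypeMatrix, k: int = 2, max_site_missing: float = 0.2) -> PCAModel:
    """Fit PCA on a modern diploid panel (mean/variance standardised sites).

    Missing entries (below the per-site cap) are mean-imputed, i.e. set to
    zero after standardisation.
    """
    g = gm.genotypes.astype(float)
    g[gm.genotypes == MISSING] = np.nan
    miss = np.isnan(g).mean(axis=0)
    if (miss > max_site_missing).any():
        raise ValueError("site missing rate exceeds the configured cap")
    p = np.nanmean(g, axis=0) / 2.0
    scale = np.sqrt(p * (1.0 - p))
    usable = scale > 0
    g, p, scale = g[:, usable], p[usable], scale[usable]
    z = (g - 2.0 * p) / scale
    z = np.nan_to_num(z)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(k, len(s))
    loadings = vt[:k].T
    eigvals = (s[:k] ** 2) / max(z.shape[0] - 1, 1)
    scores = z @ loadings
    return PCAModel(2.0 * p, scale, loadings, eigvals, scores[:, :k],
                    list(gm.samples), usable)


def pca_project(model: PCAModel, calls: np.ndarray) -> np.ndarray:
    """Least-squares projection of a sparse (pseudo-)haploid sample.

    ``calls`` are diploid-scale codes {0,1,2,-1} aligned with the sites the
    model was fitted on (pre-filter indexing; doubled pseudo-haploid codes).
    """
    usable = (model.usable_sites if model.usable_sites is not None
              else np.ones(len(model.mean), dtype=bool))
    x = np.asarray(calls, dtype=float)[usable]
    obs = x != MISSING
    if not obs.any():
        raise ValueError("sample has no observed sites")
    z = (x[obs] - model.mean[obs]) / model.scale[obs]
    V = model.loadings[obs]
    coef, *_ = np.linalg.lstsq(V, z, rcond=None)
    return coef


# ---------------------------------------------------------------------------
# f4 statistics


@dataclass
class F4Result:
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_sites: int


def f4_statistic(freqs: dict[str, np.ndarray], quadruple: tuple[str, str, str, str],
                 block_size_snps: int = 500) -> F4Result:
    """f4(A,B;C,D) = mean over usable sites of (pA-pB)(pC-pD).

    SE by weighted delete-one-block jackknife over consecutive blocks of
    ``block_size_snps`` usable sites (sites assumed coordinate-ordered).
    """
    a, b, c, d = (np.asarray(freqs[p], dtype=float) for p in quadruple)
    usable = np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & np.isfinite(d)
    if not usable.any():
        raise ValueError("no usable sites for the requested quadruple")
    vals = ((a - b) * (c - d))[usable]
    n = len(vals)
    est = float(vals.mean())
    starts = np.arange(0, n, block_size_snps)
    g = len(starts)
    if g < 2:
        return F4Result(est, math.nan, math.nan, g, n)
    total = vals.sum()
    theta_j = np.empty(g)
    m_j = np.empty(g)
    for bi, s in enumerate(starts):
        block = vals[s : s + block_size_snps]
        m_j[bi] = len(block)
        theta_j[bi] = (total - block.sum()) / (n - len(block))
    h_j = n / m_j
    # weighted block jackknife (Busing et al.); reduces to the standard
    # delete-one formula for equal blocks
    theta_jack = g * est - float(((1.0 - m_j / n) * theta_j).sum())
    tau = h_j * est - (h_j - 1.0) * theta_j
    var = float((((tau - theta_jack) ** 2) / (h_j - 1.0)).sum()) / g
    se = math.sqrt(var)
    z = est / se if se > 0 else math.nan
    return F4Result(est, se, z, g, n)


def population_frequencies(gm: GenotypeMatrix, groups: dict[str, list[str]]) -> dict[str, np.ndarray]:
    """Alt-allele frequency per site for each named sample group."""
    out = {}
    for name, members in groups.items():
        idx = [gm.samples.index(s) for s in members]
        out[name] = gm.allele_frequencies(idx)
    return out
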