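"""Synthetic inputs with known truth: diverged reference pairs, coalescent
genotype panels, damaged ancient-DNA read sets, and species mixtures.

Every generator is deterministic under an integer seed and records full
per-read / per-site provenance so downstream stages can be scored against
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .util import DNA, random_seq, revcomp, write_fastq


# ---------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class DamageModel:
    """Terminal deamination model.

    Position-``i`` rate from an end is ``delta * exp(-decay * i)``.
    ``double_stranded`` libraries show C->T at the 5' end and G->A at the 3'
    end; ``single_stranded`` libraries show C->T at both ends.
    """

    delta5: float = 0.3
    delta3: float = 0.3
    decay: float = 0.3
    library_mode: str = "double_stranded"

    def __post_init__(self):
        if not (0.0 <= self.delta5 <= 1.0 and 0.0 <= self.delta3 <= 1.0):
            raise ValueError("delta5/delta3 must lie in [0, 1]")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")
        if self.library_mode not in ("double_stranded", "single_stranded"):
            raise ValueError(f"unknown library_mode {self.library_mode!r}")

    def rate5(self, offset: int) -> float:
        return self.delta5 * math.exp(-self.decay * offset)

    def rate3(self, offset: int) -> float:
        return self.delta3 * math.exp(-self.decay * offset)


NO_DAMAGE = DamageModel(delta5=0.0, delta3=0.0, decay=0.0)


@dataclass(frozen=True)
class FragmentModel:
    """Fragment-length model; lengths never fall below ``min_len``."""

    min_len: int = 35
    mean_len: float = 55.0
    dispersion: float = 0.35
    family: str = "shifted_geometric"

    def __post_init__(self):
        if self.min_len < 25:
            raise ValueError("min_len must be >= 25")
        if self.mean_len <= self.min_len:
            raise ValueError("mean_len must exceed min_len")
        if self.family not in ("shifted_geometric", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")

    def sample_lengths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "shifted_geometric":
            p = 1.0 / (1.0 + (self.mean_len - self.min_len))
            return self.min_len + rng.geometric(p, size=n) - 1
        sigma = self.dispersion
        mu = math.log(self.mean_len) - sigma**2 / 2.0
        raw = np.round(rng.lognormal(mu, sigma, size=n)).astype(int)
        return np.maximum(raw, self.min_len)


# ---------------------------------------------------------------------------
# species pair


@dataclass(frozen=True)
class SpeciesPairTruth:
    ancestor: str
    ref_a: str
    ref_b: str
    diff_positions: tuple[int, ...]

    def __post_init__(self):
        if not (len(self.ancestor) == len(self.ref_a) == len(self.ref_b)):
            raise ValueError("sequences must have equal length")


def simulate_species_pair(length: int, divergence: float, seed: int) -> SpeciesPairTruth:
    """Two references diverged by independent per-site substitutions.

    At each differing site one of the two descendants (chosen at random)
    carries a substitution drawn uniformly from the three alternative bases.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= divergence < 0.75):
        raise ValueError("divergence must lie in [0, 0.75)")
    rng = np.random.default_rng(seed)
    ancestor = random_seq(length, rng)
    a = list(ancestor)
    b = list(ancestor)
    diff = np.flatnonzero(rng.random(length) < divergence)
    for pos in diff:
        alts = [c for c in DNA if c != ancestor[pos]]
        new = alts[rng.integers(3)]
        if rng.random() < 0.5:
            a[pos] = new
        else:
            b[pos] = new
    return SpeciesPairTruth("".join(ancestor), "".join(a), "".join(b), tuple(int(p) for p in diff))


# ---------------------------------------------------------------------------
# coalescent panel


@dataclass
class CoalescentPanel:
    """Binary haplotype matrix from an infinite-sites coalescent.

    ``haplotypes`` is H x S with 0 = ancestral/reference allele and
    1 = derived/alternate.  Haplotypes 2k and 2k+1 form diploid k.
    """

    haplotypes: np.ndarray
    positions: np.ndarray  # 1-based coordinates on a virtual chromosome
    pop_labels: list[str]  # one label per diploid individual
    split_time: float
    theta: float
    chrom_length: int

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_diploids(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def diploid_genotypes(self) -> np.ndarray:
        """(n_diploids, n_sites) alt-allele counts in {0,1,2}."""
        return self.haplotypes[0::2] + self.haplotypes[1::2]

    def het_sites(self, individual: int) -> np.ndarray:
        """Site indices where the individual's two haplotypes differ."""
        h = self.haplotypes
        return np.flatnonzero(h[2 * individual] != h[2 * individual + 1])

    def validate(self) -> None:
        h = self.haplotypes
        if h.shape[0] % 2:
            raise ValueError("haplotype count must be even")
        if h.shape[1] != len(self.positions):
            raise ValueError("positions length must equal site count")
        if h.size and not (h.min(axis=0).max() == 0 and h.max(axis=0).min() == 1):
            raise ValueError("every site must be segregating")


class _Lineage:
    __slots__ = ("leaves", "time", "pop")

    def __init__(self, leaves, time, pop):
        self.leaves = leaves
        self.time = time
        self.pop = pop


def _coalescent_sites(n_per_pop: int, n_pops: int, split_time: float, theta: float,
                      rng: np.random.Generator) -> list[frozenset]:
    """One genealogy; returns the derived-carrier leaf set of each mutation.

    Pairwise coalescence rate is 1 per pair (time in units of 2N generations)
    and mutations arrive at rate theta/2 per lineage per unit time.  With
    several populations, cross-population coalescence is forbidden more
    recently than ``split_time``.
    """
    lineages = []
    k = 2 * n_per_pop
    for p in range(n_pops):
        for i in range(k):
            lineages.append(_Lineage(frozenset([p * k + i]), 0.0, p))
    t = 0.0
    merged = n_pops == 1
    branches = []  # (leafset, length)
    while len(lineages) > 1:
        if merged:
            groups = {0: lineages}
        else:
            groups = {}
            for lin in lineages:
                groups.setdefault(lin.pop, []).append(lin)
        rates = {p: len(g) * (len(g) - 1) / 2.0 for p, g in groups.items()}
        total = sum(rates.values())
        if total == 0.0:
            wait = math.inf
        else:
            wait = rng.exponential(1.0 / total)
        if not merged and t + wait > split_time:
            t = split_time
            merged = True
            for lin in lineages:
                lin.pop = 0
            continue
        t += wait
        u = rng.random() * total
        for p, r in rates.items():
            if u < r:
                group = groups[p]
                break
            u -= r
        i, j = rng.choice(len(group), size=2, replace=False)
        a, b = group[i], group[j]
        for lin in (a, b):
            branches.append((lin.leaves, t - lin.time))
            lineages.remove(lin)
        lineages.append(_Lineage(a.leaves | b.leaves, t, a.pop if merged else p))
    carriers = []
    for leaves, length in branches:
        for _ in range(rng.poisson(theta / 2.0 * length)):
            carriers.append(leaves)
    return carriers


def simulate_coalescent_panel(n_diploids_per_pop: int, n_pops: int = 1,
                              split_time: float = 0.0, theta: float = 10.0,
                              seed: int = 0, chrom_length: int = 1_000_000,
                              _allow_many_pops: bool = False) -> CoalescentPanel:
    """Standard neutral coalescent with infinite-sites mutation.

    ``n_pops=2`` gives a clean split ``split_time`` (scaled) in the past;
    ``split_time=0`` is panmictic.
    """
    if n_diploids_per_pop < 1:
        raise ValueError("n_diploids_per_pop must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if split_time < 0:
        raise ValueError("split_time must be >= 0")
    if n_pops not in (1, 2) and not _allow_many_pops:
        raise ValueError("n_pops must be 1 or 2")
    rng = np.random.default_rng(seed)
    carriers = _coalescent_sites(n_diploids_per_pop, n_pops,
                                 split_time if n_pops > 1 else math.inf, theta, rng)
    H = 2 * n_diploids_per_pop * n_pops
    S = len(carriers)
    hap = np.zeros((H, S), dtype=np.int8)
    for s, leafset in enumerate(carriers):
        hap[list(leafset), s] = 1
    if S > chrom_length:
        raise ValueError("chrom_length too small for the realised site count")
    positions = np.sort(rng.choice(chrom_length, size=S, replace=False) + 1)
    order = rng.permutation(S)  # sites are exchangeable; shuffle before placing
    hap = hap[:, order]
    pops = [f"pop{p}" for p in range(n_pops) for _ in range(n_diploids_per_pop)]
    panel = CoalescentPanel(hap, positions, pops,
                            split_time if n_pops > 1 else 0.0, theta, chrom_length)
    panel.validate()
    return panel


def simulate_star_panel(n_diploids_per_pop: int, n_pops: int, split_time: float,
                        theta: float, seed: int, chrom_length: int = 1_000_000) -> CoalescentPanel:
    """Symmetric star phylogeny of ``n_pops`` populations splitting at once.

    Convenience generator for multi-population tests (PCA, f4); the
    two-population case coincides with :func:`simulate_coalescent_panel`.
    """
    return simulate_coalescent_panel(n_diploids_per_pop, n_pops, split_time, theta,
                                     seed, chrom_length, _allow_many_pops=True)


def concat_panels(panels: list[CoalescentPanel]) -> CoalescentPanel:
    """Concatenate independent loci side by side on one virtual chromosome.

    Positions of locus ``i`` are offset by ``i * chrom_length`` so site order
    reflects locus order (the layout block-jackknife code expects).
    """
    if not panels:
        raise ValueError("need at least one panel")
    first = panels[0]
    for p in panels[1:]:
        if p.n_haplotypes != first.n_haplotypes or p.pop_labels != first.pop_labels:
            raise ValueError("panels must share the sample configuration")
    hap = np.concatenate([p.haplotypes for p in panels], axis=1)
    positions = np.concatenate(
        [p.positions + i * first.chrom_length for i, p in enumerate(panels)])
    return CoalescentPanel(hap, positions, first.pop_labels, first.split_time,
                           first.theta, first.chrom_length * len(panels))


def simulate_multilocus_panel(n_loci: int, n_diploids_per_pop: int, n_pops: int,
                              split_time: float, theta: float, seed: int,
                              chrom_length: int = 100_000) -> CoalescentPanel:
    """Independent coalescent loci concatenated into one panel."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**63 - 1, size=n_loci)
    panels = [simulate_coalescent_panel(n_diploids_per_pop, n_pops, split_time, theta,
                                        int(s), chrom_length, _allow_many_pops=True)
              for s in seeds]
    return concat_panels(panels)


def admix_haplotypes(panel: CoalescentPanel, recipients: list[int],
                     donors: list[int], alpha: float, seed: int) -> CoalescentPanel:
    """Replace each recipient haplotype with a random donor haplotype w.p. alpha.

    Models a one-off gene-flow edge from the sampled donor individuals into
    the recipient individuals (indices are diploid individuals).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    hap = panel.haplotypes.copy()
    donor_haps = [2 * d + j for d in donors for j in (0, 1)]
    for r in recipients:
        for j in (0, 1):
            if rng.random() < alpha:
                hap[2 * r + j] = panel.haplotypes[donor_haps[rng.integers(len(donor_haps))]]
    return replace_haplotypes(panel, hap)


def replace_haplotypes(panel: CoalescentPanel, hap: np.ndarray) -> CoalescentPanel:
    return CoalescentPanel(hap, panel.positions, list(panel.pop_labels),
                           panel.split_time, panel.theta, panel.chrom_length)


# ---------------------------------------------------------------------------
# allele letters and haplotype overlay


def assign_alleles(panel: CoalescentPanel, reference: str | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Pick REF/ALT letters per site.

    REF comes from ``reference`` (base at the site position) when given,
    otherwise uniformly at random; ALT is uniform over the other three bases.
    """
    rng = np.random.default_rng(seed)
    refs, alts = [], []
    for pos in panel.positions:
        if reference is not None:
            ref = reference[int(pos) - 1]
        else:
            ref = DNA[rng.integers(4)]
        alt = [c for c in DNA if c != ref][rng.integers(3)]
        refs.append(ref)
        alts.append(alt)
    return pd.DataFrame({"pos": panel.positions, "ref": refs, "alt": alts})


def apply_haplotype(reference: str, panel: CoalescentPanel, alleles: pd.DataFrame,
                    hap_index: int) -> str:
    """Overlay one haplotype's derived alleles onto a reference sequence."""
    seq = list(reference)
    hap = panel.haplotypes[hap_index]
    for s, (pos, ref, alt) in enumerate(zip(alleles["pos"], alleles["ref"], alleles["alt"])):
        if pos > len(reference):
            raise ValueError("panel position beyond reference length")
        seq[int(pos) - 1] = alt if hap[s] else ref
    return "".join(seq)


# ---------------------------------------------------------------------------
# ancient reads


@dataclass(frozen=True)
class SimRead:
    id: str
    sequence: str
    species_id: str
    individual_id: str
    haplotype_index: int
    start: int  # 0-based inclusive on the source sequence
    end: int  # exclusive
    strand: str  # '+' or '-'
    damage_offsets: tuple[int, ...]  # read-oriented offsets altered by deamination
    error_offsets: tuple[int, ...] = ()


@dataclass
class AncientReadSet:
    reads: list[SimRead] = field(default_factory=list)

    def __len__(self):
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def sequences(self) -> dict[str, str]:
        return {r.id: r.sequence for r in self.reads}

    def to_fastq(self, path) -> None:
        write_fastq(path, [(r.id, r.sequence) for r in self.reads])

    def provenance(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": [r.id for r in self.reads],
                "species": [r.species_id for r in self.reads],
                "individual": [r.individual_id for r in self.reads],
                "haplotype": [r.haplotype_index for r in self.reads],
                "start": [r.start for r in self.reads],
                "end": [r.end for r in self.reads],
                "strand": [r.strand for r in self.reads],
                "n_damage": [len(r.damage_offsets) for r in self.reads],
            }
        )


def _apply_damage(seq: list[str], model: DamageModel, rng: np.random.Generator) -> list[int]:
    """Deaminate a read-oriented base list in place; returns altered offsets."""
    n = len(seq)
    hit = []
    for i in range(n):
        if seq[i] == "C" and rng.random() < model.rate5(i):
            seq[i] = "T"
            hit.append(i)
    for j in range(n):
        i = n - 1 - j
        if model.library_mode == "double_stranded":
            if seq[i] == "G" and rng.random() < model.rate3(j):
                seq[i] = "A"
                hit.append(i)
        else:
            if seq[i] == "C" and rng.random() < model.rate3(j):
                seq[i] = "T"
                hit.append(i)
    return sorted(hit)


def simulate_ancient_reads(source: str, n_reads: int,
                           fragment_model: FragmentModel = FragmentModel(),
                           damage_model: DamageModel = DamageModel(),
                           error_rate: float = 0.001, seed: int = 0,
                           species_id: str = "spA", individual_id: str = "ind0",
                           haplotype_index: int = 0,
                           read_prefix: str | None = None) -> AncientReadSet:
    """Draw damaged, error-bearing fragments uniformly from ``source``.

    Fragments take the reverse strand with probability 0.5 (the emitted
    sequence is then the reverse complement of the source interval).
    Deamination is applied before uniform sequencing error.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if not (0.0 <= error_rate < 0.1):
        raise ValueError("error_rate must lie in [0, 0.1)")
    if len(source) <= fragment_model.min_len:
        raise ValueError("source shorter than the minimum fragment length")
    rng = np.random.default_rng(seed)
    prefix = read_prefix or f"{species_id}_{individual_id}_h{haplotype_index}"
    lengths = np.minimum(fragment_model.sample_lengths(n_reads, rng), len(source))
    reads = []
    for i in range(n_reads):
        L = int(lengths[i])
        start = int(rng.integers(0, len(source) - L + 1))
        frag = source[start : start + L]
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            frag = revcomp(frag)
        bases = list(frag)
        dmg = _apply_damage(bases, damage_model, rng)
        err = []
        if error_rate > 0:
            for k in np.flatnonzero(rng.random(L) < error_rate):
                k = int(k)
                bases[k] = [c for c in DNA if c != bases[k]][rng.integers(3)]
                err.append(k)
        reads.append(SimRead(f"{prefix}_r{i}", "".join(bases), species_id, individual_id,
                             haplotype_index, start, start + L, strand,
                             tuple(dmg), tuple(err)))
    return AncientReadSet(reads)


def simulate_diploid_reads(hap0_seq: str, hap1_seq: str, n_reads: int,
                           fragment_model: FragmentModel = FragmentModel(),
                           damage_model: DamageModel = DamageModel(),
                           error_rate: float = 0.001, seed: int = 0,
                           species_id: str = "spA", individual_id: str = "ind0") -> AncientReadSet:
    """Reads drawn half-and-half (binomially) from the two haplotypes."""
    rng = np.random.default_rng(seed)
    n0 = int(rng.binomial(n_reads, 0.5))
    parts = []
    for hap, seq, n in ((0, hap0_seq, n0), (1, hap1_seq, n_reads - n0)):
        if n > 0:
            parts.append(simulate_ancient_reads(
                seq, n, fragment_model, damage_model, error_rate,
                seed=int(rng.integers(2**63 - 1)), species_id=species_id,
                individual_id=individual_id, haplotype_index=hap))
    merged, _ = mix_read_sets(parts[0], parts[1] if len(parts) > 1 else AncientReadSet(),
                              seed=int(rng.integers(2**63 - 1)))
    return merged


def mix_read_sets(set_a: AncientReadSet, set_b: AncientReadSet,
                  seed: int = 0) -> tuple[AncientReadSet, pd.DataFrame]:
    """Shuffled union of two read sets plus a read-id -> truth table."""
    rng = np.random.default_rng(seed)
    ids_a = {r.id for r in set_a}
    reads = list(set_a.reads)
    for r in set_b.reads:
        if r.id in ids_a:
            r = replace(r, id=f"{r.id}_b")
        reads.append(r)
    order = rng.permutation(len(reads))
    merged = AncientReadSet([reads[i] for i in order])
    return merged, merged.provenance()


# ---------------------------------------------------------------------------
# VCF emission


def panel_to_vcf(panel: CoalescentPanel, alleles: pd.DataFrame | None = None,
                 chrom: str = "chr1", sample_prefix: str = "ind",
                 seed: int = 0) -> str:
    """Serialise a panel as VCF v4.2 text (one record per segregating site)."""
    panel.validate()
    if alleles is None:
        alleles = assign_alleles(panel, seed=seed)
    if len(alleles) != panel.n_sites:
        raise ValueError("alleles table does not match the panel site count")
    n = panel.n_diploids
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    geno = panel.diploid_genotypes()
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={panel.chrom_length}>",
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total number of alleles">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    mq = alleles["mq"] if "mq" in alleles else pd.Series([60.0] * len(alleles))
    for s in range(panel.n_sites):
        an = 2 * n
        gts = "\t".join(gt_code[int(g)] for g in geno[:, s])
        lines.append(
            f"{chrom}\t{int(panel.positions[s])}\t.\t{alleles['ref'][s]}\t{alleles['alt'][s]}"
            f"\t.\tPASS\tAN={an};MQ={float(mq[s]):g}\tGT\t{gts}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# tree-structured MSA simulation (for the placement stage)


def simulate_msa_on_tree(tree, ancestor_length: int, mutations_per_branch: int,
                         seed: int, transversions_only: bool = True):
    """Evolve an alignment down a rooted tree under infinite sites.

    Each non-root branch receives exactly ``mutations_per_branch`` substitutions
    at distinct, previously unused columns (no homoplasy).  Returns
    ``(names, sequences, branch_truth)`` where ``branch_truth`` maps branch id
    -> list of (column, ancestral_base, derived_base).

    ``tree`` is a mitoplace ``RootedTree``.
    """
    rng = np.random.default_rng(seed)
    ancestor = random_seq(ancestor_length, rng)
    n_branches = sum(1 for n in tree.nodes if n.parent is not None)
    need = n_branches * mutations_per_branch
    if need > ancestor_length:
        raise ValueError("ancestor too short for the requested mutation count")
    cols = rng.choice(ancestor_length, size=need, replace=False)
    col_iter = iter(int(c) for c in cols)
    seqs = {tree.root.index: list(ancestor)}
    branch_truth: dict[str, list[tuple[int, str, str]]] = {}
    transversion_partner = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    for node in tree.preorder():
        if node.parent is None:
            continue
        seq = list(seqs[node.parent.index])
        events = []
        for _ in range(mutations_per_branch):
            col = next(col_iter)
            anc = seq[col]
            if transversions_only:
                der = transversion_partner[anc][rng.integers(2)]
            else:
                der = [c for c in DNA if c != anc][rng.integers(3)]
            seq[col] = der
            events.append((col, anc, der))
        seqs[node.index] = seq
        branch_truth[tree.branch_id(node)] = events
    names = [leaf.label for leaf in tree.leaves()]
    sequences = ["".join(seqs[leaf.index]) for leaf in tree.leaves()]
    return names, sequences, branch_truth
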