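import numpy as np
import pytest

from ednamix import mitoplace, readmap, simdata


@pytest.fixture(scope="session")
def species_pair():
    return simdata.simulate_species_pair(20_000, 0.05, seed=11)


@pytest.fixture(scope="session")
def small_panel():
    return simdata.simulate_coalescent_panel(5, 1, theta=10.0, seed=21)


@pytest.fixture(scope="session")
def toy_tree():
    return mitoplace.RootedTree.from_newick("((((A,B),C),(D,E)),OG);", outgroup="OG")


@pytest.fixture(scope="session")
def damaged_reads(species_pair):
    return simdata.simulate_ancient_reads(
        species_pair.ref_a, 400, error_rate=0.0,
        damage_model=simdata.DamageModel(delta5=0.3, delta3=0.3, decay=0.3),
        seed=31, species_id="spA")


@pytest.fixture(scope="session")
def two_species_mixture(species_pair):
    """Mixture of damaged reads from both references with provenance truth."""
    reads_a = simdata.simulate_ancient_reads(
        species_pair.ref_a, 300, error_rate=0.001, seed=41, species_id="spA")
    reads_b = simdata.simulate_ancient_reads(
        species_pair.ref_b, 200, error_rate=0.001, seed=42, species_id="spB")
    merged, truth = simdata.mix_read_sets(reads_a, reads_b, seed=43)
    return merged, truth


def brute_force_best(read: str, ref: str, max_mismatch_rate: float = 0.1):
    """Independent oracle: enumerate every end-to-end placement on both
    strands, count mismatches positionally, return (best placements, edit)."""
    import math

    from ednamix.util import revcomp

    L = len(read)
    budget = math.ceil(max_mismatch_rate * L)
    hits = []
    for strand, oriented in (("+", read), ("-", revcomp(read))):
        for start in range(len(ref) - L + 1):
            mm = sum(1 for a, b in zip(oriented, ref[start : start + L])
                     if a != b or a not in "ACGT")
            if mm <= budget:
                hits.append((mm, start, strand))
    if not hits:
        return None
    best = min(h[0] for h in hits)
    return [h for h in hits if h[0] == best]
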