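import pytest

from scatpop.genodata import GenotypeTable, Locus
from scatpop import synthsim as sim


def toy_table(rows: dict, n_loci: int | None = None) -> GenotypeTable:
    """Build a GenotypeTable from {id: {locus: (a, b)}} dicts."""
    loci: list[str] = []
    for calls in rows.values():
        for l in calls:
            if l not in loci:
                loci.append(l)
    panel = [Locus(name=l) for l in loci]
    return GenotypeTable(rows={i: dict(c) for i, c in rows.items()}, panel=panel)


@pytest.fixture(scope="session")
def truth_default():
    """One simulated population under the default territorial preset."""
    return sim.simulate_population(sim.lynx_nw_anatolia_preset(seed=42))


@pytest.fixture(scope="session")
def synthetic_reference_table():
    """Synthetic stand-in for an 18-individual field genotype table.

    Used only for data-free consistency properties (pair-count arithmetic,
    cross-statistic identities), never for comparisons against published
    values.
    """
    truth = sim.simulate_population(
        sim.lynx_nw_anatolia_preset(seed=18, n_kittens=4, n_floaters=2,
                                    n_dispersers=1))
    gt = truth.genotype_table(include_sexing=False)
    ids = sorted(gt.rows)[:18]
    assert len(ids) == 18
    return gt.subset(ids=ids)
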