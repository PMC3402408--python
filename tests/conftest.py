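import pytest

from tillkit.io import load_bundled_tables
from tillkit.simulate import (
    Genotype,
    M2Family,
    M2Individual,
    MutationRecord,
    Population,
    ReferenceSequence,
)


@pytest.fixture(scope="session")
def bundled():
    return load_bundled_tables()


@pytest.fixture
def tiny_reference():
    # 2000 bp, fixed content so sites/bases are predictable
    return ReferenceSequence(id="tiny", residues="ACGT" * 500)


def build_population(reference, carriers, truth_sites):
    """Hand-build a Population.

    carriers: {individual_id: {site: dosage}}; individual ids must look
    like '<line>-<n>'.  truth_sites: {site: (ref, alt, line)}.
    """
    truth = [
        MutationRecord(site=site, ref=ref, alt=alt, line=line, zygosity="het")
        for site, (ref, alt, line) in sorted(truth_sites.items())
    ]
    families = {}
    for indiv_id, sites in carriers.items():
        line = indiv_id.rsplit("-", 1)[0]
        genotypes = {}
        for site, dosage in sites.items():
            ref, alt, _ = truth_sites[site]
            alleles = {0: (ref, ref), 1: (ref, alt), 2: (alt, alt)}[dosage]
            genotypes[site] = Genotype(site=site, ref=ref, alt=alt, alleles=alleles)
        fam = families.setdefault(
            line, M2Family(line_id=line, m1_parent=f"M1-{line}", siblings=[])
        )
        fam.siblings.append(
            M2Individual(id=indiv_id, line=line, sector=0, genotypes=genotypes)
        )
    return Population(reference=reference, lines=list(families.values()), truth=truth)


@pytest.fixture
def build_pop():
    return build_population
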