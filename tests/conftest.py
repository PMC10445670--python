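import pytest

from ystr.io_qc import Allele, HaplotypeDataset, PairRecord
from ystr.locus_registry import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def _genotype(text):
    return tuple(sorted(Allele.parse(p) for p in str(text).split(",")))


@pytest.fixture
def make_dataset():
    """Build a HaplotypeDataset from {sample: {locus: 'a' or 'a,b'}}."""

    def build(table):
        loci = sorted({l for row in table.values() for l in row})
        alleles = {
            (s, l): _genotype(v)
            for s, row in table.items()
            for l, v in row.items()
            if v != ""
        }
        return HaplotypeDataset(
            samples=tuple(table), loci=tuple(loci), alleles=alleles
        )

    return build


@pytest.fixture
def make_pair():
    """Build a PairRecord from two {locus: allele-string} dicts."""

    def build(father, son, pedigree_id="P00001", age=None):
        return PairRecord(
            pedigree_id=pedigree_id,
            father={l: _genotype(v) for l, v in father.items() if v != ""},
            son={l: _genotype(v) for l, v in son.items() if v != ""},
            father_age=age,
        )

    return build


@pytest.fixture
def genotype():
    return _genotype
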