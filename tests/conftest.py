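import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cdsibrisk.panel import risk_panel
from cdsibrisk.pedigree import HlaDqGenotype, Person, Trio

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel3():
    return risk_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trio(gf, gm, gc, locus="rs1464510", fid="FAM1", hla=None):
    """Single-locus trio with genotype counts (father, mother, child)."""

    def hla_of(i):
        if hla is None:
            return HlaDqGenotype("DQX", "DQX")
        return HlaDqGenotype(*hla[i])

    father = Person(fid, "F", "0", "0", sex=1, affected=False, role="parent",
                    hla=hla_of(0), snps={locus: gf})
    mother = Person(fid, "M", "0", "0", sex=2, affected=False, role="parent",
                    hla=hla_of(1), snps={locus: gm})
    child = Person(fid, "C1", "F", "M", sex=1, affected=True, role="proband",
                   hla=hla_of(2), snps={locus: gc})
    return Trio(proband=child, father=father, mother=mother)


def make_trios(configs, locus="rs1464510"):
    """Trios from a list of (gf, gm, gc) or ((gf, gm, gc), n) entries."""
    trios = []
    for entry in configs:
        if len(entry) == 2 and isinstance(entry[1], int):
            (gf, gm, gc), n = entry
        else:
            (gf, gm, gc), n = entry, 1
        for k in range(n):
            trios.append(make_trio(gf, gm, gc, locus=locus, fid=f"FAM{len(trios)+1}"))
    return trios


@pytest.fixture
def trio_factory():
    return make_trio


@pytest.fixture
def trios_factory():
    return make_trios
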