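import numpy as np
import pytest

from tubetask import SubjectRecord, load_table1_fixture, simulate_tree
from tubetask.phylo import Phylogeny


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def cherry_tree():
    return Phylogeny.from_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def three_tip_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def big_tree():
    return simulate_tree(200, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_subject(
    subject_id="s1",
    species="Genus species",
    left=10,
    right=20,
    bouts=8,
    sex="F",
    age_class="adult",
    clade="Platyrrhini",
):
    return SubjectRecord(
        subject_id=subject_id,
        species=species,
        clade=clade,
        sex=sex,
        age_class=age_class,
        left_insertions=left,
        right_insertions=right,
        bouts=bouts,
    )
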