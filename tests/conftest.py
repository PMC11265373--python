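import numpy as np
import pandas as pd
import pytest

from symbiomet.io import BgcGene, BgcRecord
from symbiomet.tree import Phylogeny


@pytest.fixture
def quartet_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A:0.2,B:0.3):0.4,(C:0.5,D:0.1):0.6);")


@pytest.fixture
def binary_matrix() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.integers(0, 2, size=(10, 25)),
        index=[f"s{i:02d}" for i in range(10)],
        columns=[f"F{j:03d}" for j in range(25)],
    )


def make_bgc(
    bgc_id: str,
    labels: list[str],
    genome_id: str = "G1",
    proteins: list[str] | None = None,
    bgc_class: str = "PKS",
    contig_id: str = "c1",
    start: int = 0,
    end: int = 10_000,
) -> BgcRecord:
    if proteins is None:
        proteins = ["MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"] * len(labels)
    genes = [
        BgcGene(f"{bgc_id}_g{i}", lab, i == 0, prot)
        for i, (lab, prot) in enumerate(zip(labels, proteins))
    ]
    return BgcRecord(bgc_id, genome_id, contig_id, start, end, bgc_class, genes)
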