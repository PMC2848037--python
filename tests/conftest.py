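import numpy as np
import pytest

from sscphylo import Alignment, SequenceRecord, TaxonMetadata


@pytest.fixture
def small_nuc_alignment():
    """4 x 4 alignment with 2 variable (and PI) columns."""
    return Alignment(
        [
            SequenceRecord(id="a", residues="ACGT"),
            SequenceRecord(id="b", residues="ACGA"),
            SequenceRecord(id="c", residues="ATGA"),
            SequenceRecord(id="d", residues="ATGT"),
        ]
    )


@pytest.fixture
def plain_metadata():
    def make(taxa, non_seed=(), hybrids=()):
        groups = {t: ("Mosses" if t in non_seed else "Eurosids") for t in taxa}
        return {
            t: TaxonMetadata(t, lineage_group=groups[t], is_hybrid=t in hybrids)
            for t in taxa
        }

    return make


@pytest.fixture(scope="session")
def toy_study():
    from sscphylo import make_toy_study

    return make_toy_study(seed=7)


def random_unrooted_tree(rng: np.random.Generator, n_taxa: int,
                         min_bl: float = 0.1, max_bl: float = 1.0):
    """A random unrooted binary tree with positive branch lengths."""
    import dendropy

    taxa = [f"t{i}" for i in range(n_taxa)]
    newicks = {t: t for t in taxa}
    items = list(taxa)
    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        a, b = items[j], items[i]
        items = [x for x in items if x not in (a, b)]
        nm = (
            f"({newicks[a]}:{rng.uniform(min_bl, max_bl):.6f},"
            f"{newicks[b]}:{rng.uniform(min_bl, max_bl):.6f})"
        )
        key = a + b
        newicks[key] = nm
        items.append(key)
    a, b, c = items
    nw = (
        f"({newicks[a]}:{rng.uniform(min_bl, max_bl):.6f},"
        f"{newicks[b]}:{rng.uniform(min_bl, max_bl):.6f},"
        f"{newicks[c]}:{rng.uniform(min_bl, max_bl):.6f});"
    )
    return dendropy.Tree.get(data=nw, schema="newick")
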