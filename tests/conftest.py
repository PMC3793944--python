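import numpy as np
import pytest

from icclust.enrichment_elim import OntologyDAG, propagate_annotations
from icclust.expression_io import ExpressionMatrix

OBO_CHAIN = """\
format-version: 1.2

[Term]
id: T:0001
name: root

[Term]
id: T:0002
name: mid
is_a: T:0001 ! root

[Term]
id: T:0003
name: leaf
is_a: T:0002 ! mid

[Term]
id: T:0004
name: second parent
is_a: T:0001 ! root

[Term]
id: T:0005
name: diamond leaf
is_a: T:0002 ! mid
is_a: T:0004 ! second parent

[Term]
id: T:0006
name: gone
is_obsolete: true
"""

OBO_CYCLIC = """\
format-version: 1.2

[Term]
id: T:0001
name: a
is_a: T:0002

[Term]
id: T:0002
name: b
is_a: T:0001
"""


@pytest.fixture
def small_matrix():
    """4 genes x 4 samples with exact relations to the target row."""
    target = np.array([1.0, 2.0, 3.0, 4.0])
    return ExpressionMatrix(
        ["GA", "GB", "GC", "TGT"],
        ["s1", "s2", "s3", "s4"],
        np.vstack([
            2.0 * target + 1.0,   # GA: r = +1 with target
            -target,              # GB: r = -1
            [1.0, 3.0, 2.0, 4.0], # GC: r = 0.8 (hand-computed)
            target,
        ]),
    )


@pytest.fixture
def obo_chain_path(tmp_path):
    p = tmp_path / "chain.obo"
    p.write_text(OBO_CHAIN)
    return p


@pytest.fixture
def obo_cyclic_path(tmp_path):
    p = tmp_path / "cyclic.obo"
    p.write_text(OBO_CYCLIC)
    return p


@pytest.fixture
def chain_enrichment_fixture():
    """30-gene universe on a root->mid->leaf chain with known counts.

    leaf annotates genes g01..g10, mid directly adds g11..g20, root
    directly adds g21..g30; propagated sizes are therefore 10/20/30.
    """
    dag = OntologyDAG(
        {"root": "root", "mid": "mid", "leaf": "leaf"},
        {"root": set(), "mid": {"root"}, "leaf": {"mid"}},
    )
    genes = [f"g{i:02d}" for i in range(1, 31)]
    direct = {}
    for i, g in enumerate(genes, start=1):
        direct[g] = {"leaf"} if i <= 10 else ({"mid"} if i <= 20 else {"root"})
    ann = propagate_annotations(dag, direct)
    return dag, ann, genes
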