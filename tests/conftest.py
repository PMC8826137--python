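import numpy as np
import pytest

import biogeodec as bg


@pytest.fixture(scope="session")
def three_tip_tree():
    return bg.Chronogram.from_newick("((t1:1,t2:1):1,t3:2);")


@pytest.fixture(scope="session")
def small_dataset():
    """A 10-tip, 3-area dataset with a moderate number of true events."""
    cfg = bg.SimConfig(
        n_tips=10, birth=0.5, death=0.0, crown_age=10, n_areas=3, d=0.1, e=0.04,
        root_range="A",
    )
    tree, geog, truth = bg.simulate_dataset(cfg, seed=42)
    return cfg, tree, geog, truth


@pytest.fixture(scope="session")
def neotropical():
    return bg.neotropical_epochs()


@pytest.fixture(scope="session")
def study_fixture_tree():
    """A 150-taxon chronogram shaped like the study's sampling design.

    136 ingroup operational taxa (two of which, by construction, lack
    distribution data) plus 14 outgroup tips attached below the ingroup
    crown — the input from which the analysed 134-tip tree is carved.
    """
    cfg = bg.SimConfig(n_tips=136, birth=0.55, death=0.05, crown_age=8.6, n_areas=6,
                       d=0.0, e=0.0, root_range="B")
    ingroup = bg.simulate_chronogram(cfg, seed=2435)
    labels = [f"sp{i + 1:03d}" for i in range(134)] + ["nodata_sp1", "nodata_sp2"]
    ingroup = bg.Chronogram(
        ingroup.parent, ingroup.ages, labels, ingroup.children
    )
    # hang 14 outgroups on successively deeper stems below the ingroup crown
    newick = ingroup.to_newick().rstrip().rstrip(";")
    rng = np.random.default_rng(6)
    depth = 8.6
    for i in range(14):
        step = float(rng.uniform(0.5, 1.5))
        newick = f"({newick}:{step},outgroup{i + 1:02d}:{depth + step})"
        depth += step
    return bg.Chronogram.from_newick(newick + ";")
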