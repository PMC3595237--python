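"""Packaged study fixtures: published summary tables and a timed marsupial tree.

The species and gait-group summary tables transcribe the published
descriptive statistics for 41 marsupial distal tibiae (14 species in three
gait categories: B = bipedal, AQ = arboreal quadrupedal, TQ = terrestrial
quadrupedal).  The tree fixture is SYNTHETIC: the original dated tree file is
not distributed, so the shipped Newick reproduces the published topology
with approximate divergence times (millions of years) drawn from molecular
studies of marsupials.  Analyses depending on exact branch lengths should be
read qualitatively.
"""

from __future__ import annotations

from importlib import resources

import dendropy
import pandas as pd

from .phylo import read_newick

__all__ = ["study_fixture_tables", "study_fixture_tree", "species_label"]


def species_label(genus: str, species: str) -> str:
    """Tree tip label for a species row, e.g. 'Macropus_giganteus'."""
    return f"{genus}_{species}"


def _data_text(name: str) -> str:
    return resources.files("osteomip.data").joinpath(name).read_text()


def study_fixture_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (species_table, group_table) of published summary statistics.

    species_table : one row per species — genus, species, gait, n, and
        mean/SD of both pixel ratios (SD missing for n = 1). 14 rows, total
        n = 41.
    group_table : one row per gait category — n, mean, SD and range of both
        ratios.
    """
    import io

    species = pd.read_csv(io.StringIO(_data_text("species_table.csv")))
    species["species_label"] = [
        species_label(g, s) for g, s in zip(species["genus"], species["species"])
    ]
    groups = pd.read_csv(io.StringIO(_data_text("group_table.csv")))
    return species, groups


def study_fixture_tree() -> dendropy.Tree:
    """Return the synthetic 14-tip ultrametric marsupial tree.

    Tip labels match ``species_table['species_label']``; each leaf node also
    carries a ``gait`` attribute (B / AQ / TQ).
    """
    tree = read_newick(_data_text("marsupial_tree_synthetic.nwk"))
    species, _ = study_fixture_tables()
    gait = dict(zip(species["species_label"], species["gait"]))
    for leaf in tree.leaf_node_iter():
        leaf.gait = gait.get(leaf.taxon.label)
    return tree
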