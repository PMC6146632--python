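"""Shared fixtures: small taxonomies, ERSC tables, random-tree generators."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from biometha.reference import ECNumber, ERSC, MetabolicModule, RefGene
from biometha.taxonomy import TaxNode, TaxonomyTree


def make_tree(edges: dict[str, tuple[str, str]]) -> TaxonomyTree:
    """Build a tree from {node: (parent, rank)}; names mirror ids."""
    return TaxonomyTree({n: TaxNode(parent=p, rank=r, name=n) for n, (p, r) in edges.items()})


@pytest.fixture
def two_domain_tree() -> TaxonomyTree:
    """root -> {Bacteria, Archaea}; one genus with two species per domain,
    plus a second bacterial genus for sibling-genus cases."""
    return make_tree(
        {
            "root": ("root", "root"),
            "Bacteria": ("root", "domain"),
            "Archaea": ("root", "domain"),
            "p_Firm": ("Bacteria", "phylum"),
            "p_Eury": ("Archaea", "phylum"),
            "c_Clos": ("p_Firm", "class"),
            "c_Meth": ("p_Eury", "class"),
            "o_Clos": ("c_Clos", "order"),
            "o_Meth": ("c_Meth", "order"),
            "f_Clos": ("o_Clos", "family"),
            "f_Meth": ("o_Meth", "family"),
            "g_Clostridium": ("f_Clos", "genus"),
            "g_Ruminococcus": ("f_Clos", "genus"),
            "g_Methanoculleus": ("f_Meth", "genus"),
            "s_Cb": ("g_Clostridium", "species"),
            "s_Ck": ("g_Clostridium", "species"),
            "s_Rb": ("g_Ruminococcus", "species"),
            "s_Mb": ("g_Methanoculleus", "species"),
            "s_Mm": ("g_Methanoculleus", "species"),
        }
    )


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree: node i attaches to a uniform earlier node."""
    nodes = {"n0": TaxNode("n0", "root", "n0")}
    for i in range(1, n_nodes):
        parent = f"n{int(rng.integers(0, i))}"
        nodes[f"n{i}"] = TaxNode(parent, "clade", f"n{i}")
    return TaxonomyTree(nodes)


def brute_force_lca(taxa: list[str], tree: TaxonomyTree) -> str:
    """Independent oracle: intersect full ancestor sets, take the deepest."""
    common = set(tree.ancestors(taxa[0]))
    for t in taxa[1:]:
        common &= set(tree.ancestors(t))
    return max(common, key=lambda n: (tree.depth(n), n))


@pytest.fixture
def small_ersc() -> ERSC:
    """Hand-built collection: 3 modules, incl. a wildcard protease entry and
    an EC with no known sequence."""
    m_hydro = MetabolicModule(
        module_id="HYD",
        name="polymer hydrolysis",
        category="polymer degradation",
        ec_codes=[ECNumber.parse("3.4.-.-"), ECNumber.parse("3.2.1.4")],
    )
    m_trp = MetabolicModule(
        module_id="TRP",
        name="tryptophan metabolism",
        category="amino acid metabolism",
        ec_codes=[ECNumber.parse("4.1.99.1"), ECNumber.parse("1.13.11.11"), ECNumber.parse("2.6.1.27")],
    )
    m_mcr = MetabolicModule(
        module_id="MCR",
        name="methyl-CoA to methane",
        category="methanogenesis",
        ec_codes=[ECNumber.parse("2.8.4.1")],
    )
    sequences = {
        "3.4.-.-": [RefGene("seq_prot_1", 900), RefGene("seq_prot_2", 1200)],
        "3.2.1.4": [RefGene("seq_cel_1", 1500)],
        "4.1.99.1": [RefGene("seq_trp_1", 1000)],
        "2.8.4.1": [RefGene("seq_mcr_1", 1650, source="assembly-derived")],
        # 1.13.11.11 and 2.6.1.27 have no known sequence
    }
    return ERSC(modules=[m_hydro, m_trp, m_mcr], sequences=sequences)


def write_module_table(path, rows: list[tuple[str, str, str, str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ec\tmodule_id\tmodule_name\tcategory\n")
        for ec, mid, name, cat in rows:
            fh.write(f"{ec}\t{mid}\t{name}\t{cat}\n")
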