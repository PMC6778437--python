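"""Shared fixtures and independent oracles.

Oracle helpers are built on scikit-bio, a different tree library from the
one the implementation uses, so that tree-walking results are checked
against a genuinely independent code path.
"""

from __future__ import annotations

import io as _stdio

import pytest
import skbio

from taxawalk import SimConfig, TaxonomyTable, simulate_taxonomy
from taxawalk.io import newick_string


@pytest.fixture
def small_taxonomy() -> TaxonomyTable:
    """Hand-written six-rank table with one partially known species."""
    t = TaxonomyTable()
    t.add(
        "DESAJ",
        species="Desulfosporosinus acidiphilus",
        genus="Desulfosporosinus",
        family="Peptococcaceae",
        order="Clostridiales",
        **{"class": "Clostridia"},
        phylum="Firmicutes",
    )
    t.add(
        "DESAC",
        species="Desulfosporosinus acididurans",
        genus="Desulfosporosinus",
        family="Peptococcaceae",
        order="Clostridiales",
        **{"class": "Clostridia"},
        phylum="Firmicutes",
    )
    t.add(
        "DEHRE",
        species="Dehalobacter restrictus",
        genus="Dehalobacter",
        family="Peptococcaceae",
        order="Clostridiales",
        **{"class": "Clostridia"},
        phylum="Firmicutes",
    )
    # known only down to phylum: contributes "Firmicutes fam." etc.
    t.add("FIRMX", phylum="Firmicutes")
    return t


@pytest.fixture
def sim_taxonomy() -> TaxonomyTable:
    return simulate_taxonomy(SimConfig(seed=0))


# ---------------------------------------------------------------------------
# scikit-bio oracles
# ---------------------------------------------------------------------------

def skbio_tree(gt):
    """Re-parse a gene tree with scikit-bio (independent of dendropy)."""
    text = newick_string(gt)
    for marker in ("[&R] ", "[&U] "):
        text = text.replace(marker, "")
    return skbio.TreeNode.read(_stdio.StringIO(text), convert_underscores=False)


def _code(name: str) -> str:
    return name.rsplit("_", 1)[-1]


def oracle_assign(gt, query_leaf: str, threshold: float, query_code: str = "DCMF"):
    """Brute-force ancestor enumeration using scikit-bio.

    Returns (species_codes, support, root_fallback, none_flag).
    """
    tree = skbio_tree(gt)
    all_nonquery = {
        _code(t.name) for t in tree.tips() if _code(t.name) != query_code
    }
    if not all_nonquery:
        return frozenset(), None, False, True
    tip = next(t for t in tree.tips() if t.name == query_leaf)
    for anc in tip.ancestors():
        codes = {
            _code(t.name) for t in anc.tips() if _code(t.name) != query_code
        }
        support = None
        if anc.name not in (None, ""):
            support = float(anc.name)
        if codes and support is not None and support >= threshold:
            return frozenset(codes), support, False, False
    return frozenset(all_nonquery), None, True, False


def oracle_paralog_subfamilies(gt):
    """Exhaustive per-node paralog check using scikit-bio.

    Returns the set of subfamily leaf-label frozensets.
    """
    tree = skbio_tree(gt)
    found = set()
    for node in tree.non_tips(include_self=True):
        if len(node.children) != 2:
            continue
        left, right = (
            {_code(t.name) for t in ch.tips(include_self=True)}
            for ch in node.children
        )
        if len(left) >= 2 and len(right) >= 2 and (left & right):
            found.add(frozenset(t.name for t in node.tips()))
    return found
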