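"""Shared fixtures: tiny ontologies and corpora written at test time."""

from __future__ import annotations

import textwrap

import pytest

from reel.kb import Concept, KnowledgeBase


MINI_OBO = textwrap.dedent(
    """\
    format-version: 1.2
    ontology: test

    [Term]
    id: CHEBI:1
    name: alcohol
    synonym: "ethanol family" EXACT []
    synonym: "hydroxy compound" RELATED []
    synonym: "alkanol" EXACT []
    alt_id: CHEBI:901

    [Term]
    id: CHEBI:2
    name: aldehyde
    is_a: CHEBI:1 ! alcohol

    [Term]
    id: CHEBI:3
    name: old thing
    is_obsolete: true

    [Typedef]
    id: has_role
    name: has role
    """
)


@pytest.fixture
def mini_obo(tmp_path):
    path = tmp_path / "mini.obo"
    path.write_text(MINI_OBO, encoding="utf-8")
    return path


@pytest.fixture
def disease_kb():
    """Hand-built is-a chain: viral pneumonia -> viral infection -> disease."""
    kb = KnowledgeBase()
    for cid, name in [
        ("MESH:D001", "disease"),
        ("MESH:D002", "viral infection"),
        ("MESH:D003", "viral pneumonia"),
        ("MESH:D004", "bacterial infection"),
    ]:
        kb.add_concept(Concept(id=cid, primary_name=name))
    kb.add_relation("MESH:D002", "MESH:D001")
    kb.add_relation("MESH:D003", "MESH:D002")
    kb.add_relation("MESH:D004", "MESH:D001")
    return kb


PUBTATOR_3DOCS = (
    "100|t|Aspirin study\n"
    "100|a|Aspirin and heparin were given.\n"
    "100\t14\t21\tAspirin\tChemical\tD001241\n"
    "100\t26\t33\theparin\tChemical\tD006493\n"
    "\n"
    "200|t|Short title\n"
    "200|a|Nothing else here at all today.\n"
    "200\t12\t19\tNothing\tDisease\tD000001\n"
    "\n"
    "300|t|Third doc\n"
    "300|a|warfarin warfarin aspirin and naproxen here\n"
    "300\t10\t18\twarfarin\tChemical\tD014859\n"
    "300\t19\t27\twarfarin\tChemical\tD014859\n"
    "300\t28\t35\taspirin\tChemical\tD001241\n"
    "300\t40\t48\tnaproxen\tChemical\tD009288\n"
    "\n"
)


@pytest.fixture
def pubtator_file(tmp_path):
    path = tmp_path / "corpus.pubtator"
    path.write_text(PUBTATOR_3DOCS, encoding="utf-8")
    return path


def levenshtein_oracle(a: str, b: str) -> int:
    """Independent dynamic-programming edit distance for cross-checks."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[len(b)]
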