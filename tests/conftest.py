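"""Shared fixtures: small synthetic proteomes and random additive trees."""

from __future__ import annotations

import numpy as np
import pytest

from spacedist import Proteome, get_model
from spacedist.proteome import AMINO_ACIDS


def random_protein(rng: np.random.Generator, length: int, model_name: str = "jtt") -> str:
    model = get_model(model_name)
    codes = rng.choice(20, size=length, p=model.frequencies)
    return "".join(AMINO_ACIDS[c] for c in codes)


def evolve(seq: str, d: float, rng: np.random.Generator, model_name: str = "jtt") -> str:
    """Evolve a sequence for time d under the model's transition matrix."""
    model = get_model(model_name)
    P = model.transition_matrix(d)
    cum = P.cumsum(axis=1)
    cum[:, -1] = 1.0
    codes = np.array([AMINO_ACIDS.index(c) for c in seq])
    u = rng.random(len(seq))
    out = (u[:, None] > cum[codes]).sum(axis=1)
    return "".join(AMINO_ACIDS[c] for c in out)


@pytest.fixture(scope="session")
def trio_proteomes() -> list[Proteome]:
    """Three related single-sequence proteomes at known divergence order:
    b is closer to a than c is (a->b at d=0.15, b->c at d=0.25)."""
    rng = np.random.default_rng(2024)
    a = random_protein(rng, 6000)
    b = evolve(a, 0.15, rng)
    c = evolve(b, 0.25, rng)
    return [
        Proteome("tax_a", ("a1",), (a,)),
        Proteome("tax_b", ("b1",), (b,)),
        Proteome("tax_c", ("c1",), (c,)),
    ]


def random_binary_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Newick string of a random binary tree with positive branch lengths."""

    def build(labels: list[str]) -> str:
        if len(labels) == 1:
            return labels[0]
        k = int(rng.integers(1, len(labels)))
        left, right = labels[:k], labels[k:]
        bl, br = rng.uniform(0.1, 1.0, size=2)
        return f"({build(left)}:{bl:.6f},{build(right)}:{br:.6f})"

    labels = [f"T{i}" for i in range(n_leaves)]
    rng.shuffle(labels)
    return build(labels) + ";"


def tree_distance_matrix(newick: str):
    """Additive leaf-to-leaf distance matrix induced by a tree."""
    import dendropy

    from spacedist.distances import DistanceMatrix

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    names = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(names)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pdm.patristic_distance(taxa[names[i]], taxa[names[j]])
    return DistanceMatrix(tuple(names), M)
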