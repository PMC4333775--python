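"""Graph-equivalence utilities for directed Gaussian networks.

Two DAGs entail the same set of Gaussian distributions exactly when they
share a skeleton and the same v-structures (colliders i -> k <- j with i, j
non-adjacent).  Structure learning from observational data can therefore
only be judged up to this Markov equivalence class, which these helpers
make comparable.
"""

from __future__ import annotations

from .datatypes import DAGModel

__all__ = ["skeleton", "v_structures", "markov_equivalent", "structural_hamming_distance"]


def _adjacency(model_or_structure) -> dict[int, frozenset[int]]:
    if isinstance(model_or_structure, DAGModel):
        return model_or_structure.parent_sets()
    return {int(j): frozenset(int(i) for i in p) for j, p in model_or_structure.items()}


def skeleton(model_or_structure) -> frozenset[frozenset[int]]:
    """Undirected edge set: {i, j} for every directed edge i->j."""
    parents = _adjacency(model_or_structure)
    return frozenset(
        frozenset((i, j)) for j, ps in parents.items() for i in ps
    )


def v_structures(model_or_structure) -> frozenset[tuple[int, int, int]]:
    """Colliders (i, k, j), i < j, with i -> k <- j and i, j non-adjacent."""
    parents = _adjacency(model_or_structure)
    skel = skeleton(parents)
    out = set()
    for k, ps in parents.items():
        ps = sorted(ps)
        for a in range(len(ps)):
            for b in range(a + 1, len(ps)):
                i, j = ps[a], ps[b]
                if frozenset((i, j)) not in skel:
                    out.add((i, k, j))
    return frozenset(out)


def markov_equivalent(a, b) -> bool:
    """Whether two DAGs represent the same Gaussian equivalence class
    (identical skeletons and identical v-structures)."""
    return skeleton(a) == skeleton(b) and v_structures(a) == v_structures(b)


def structural_hamming_distance(a, b) -> int:
    """Count of node pairs whose edge status (absent / i->j / j->i) differs."""
    pa, pb = _adjacency(a), _adjacency(b)

    def oriented(parents):
        return {(i, j) for j, ps in parents.items() for i in ps}

    ea, eb = oriented(pa), oriented(pb)
    pairs_a = {frozenset(e) for e in ea}
    pairs_b = {frozenset(e) for e in eb}
    dist = len(pairs_a ^ pairs_b)
    for pair in pairs_a & pairs_b:
        i, j = sorted(pair)
        if ((i, j) in ea) != ((i, j) in eb):
            dist += 1
    return dist
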