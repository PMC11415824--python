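"""Independent oracles used by the test suite.

These are deliberately naive implementations kept separate from the package:
a quadratic affine-gap local-alignment DP, a column-majority consensus for
equal-length inputs, and maximum-cardinality bipartite matching.  They share
no code with the paths they check.
"""

from __future__ import annotations

import networkx as nx

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp_oracle(seq: str) -> str:
    return "".join(ch.translate(_COMP) for ch in reversed(seq))


def sw_score_oracle(query: str, target: str, match=2, mismatch=-4, gap_open=-4, gap_extend=-2) -> int:
    """Plain O(nm) affine-gap local alignment score; N scores 0 vs anything."""
    n, m = len(query), len(target)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            tj = target[j - 1]
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend, F[i - 1][j] + gap_extend)
            if qi == "N" or tj == "N":
                s = 0
            elif qi == tj:
                s = match
            else:
                s = mismatch
            h = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            H[i][j] = h
            best = max(best, h)
    return best


def sw_best_of_strands_oracle(query: str, target: str, **kwargs) -> int:
    return max(
        sw_score_oracle(query, target, **kwargs),
        sw_score_oracle(revcomp_oracle(query), target, **kwargs),
    )


def majority_consensus_oracle(sequences: list[str]) -> str:
    """Columnwise majority for equal-length sequences; ties break A<C<G<T."""
    assert len({len(s) for s in sequences}) == 1
    out = []
    for column in zip(*sequences):
        counts: dict[str, int] = {}
        for base in column:
            counts[base] = counts.get(base, 0) + 1
        out.append(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0])
    return "".join(out)


def max_matching_oracle(candidate_pairs: list[tuple[int, int]], n_calls: int, n_truth: int) -> int:
    """Maximum-cardinality bipartite matching size over candidate pairs."""
    graph = nx.Graph()
    graph.add_nodes_from((f"c{i}" for i in range(n_calls)), bipartite=0)
    graph.add_nodes_from((f"t{j}" for j in range(n_truth)), bipartite=1)
    graph.add_edges_from((f"c{i}", f"t{j}") for i, j in candidate_pairs)
    matching = nx.algorithms.matching.max_weight_matching(graph, maxcardinality=True)
    return len(matching)
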