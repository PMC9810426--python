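"""Summaries of tree samples and posterior state maps.

A clade is identified by the set of leaf populations beneath an internal
node.  The maximum clade credibility (MCC) tree is the *sampled* tree whose
clades have the largest product of sample frequencies — the same semantics
as the standard tree-annotator tools — annotated with per-clade support and
the mean age of each clade's MRCA across the trees containing it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .forward_sim import ObservationSet
from .history import Genealogy, LinearTree

__all__ = [
    "clade_frequencies",
    "mcc_tree",
    "state_map",
    "monochromatic_clade_score",
]


def _as_linear_list(trees) -> list[LinearTree]:
    out = []
    for t in trees:
        out.append(t.to_linear() if isinstance(t, Genealogy) else t)
    return out


def clade_frequencies(trees) -> dict[frozenset, float]:
    """Frequency of every observed clade (leaf-population set) in the sample."""
    lts = _as_linear_list(trees)
    if not lts:
        raise ValueError("empty tree sample")
    leafset = frozenset(int(p) for p in lts[0].leaf_populations)
    counts: dict[frozenset, int] = {}
    for lt in lts:
        if frozenset(int(p) for p in lt.leaf_populations) != leafset:
            raise ValueError("all trees must share the same leaf label set")
        for clade, _ in lt.clades():
            counts[clade] = counts.get(clade, 0) + 1
    return {c: k / len(lts) for c, k in counts.items()}


def mcc_tree(trees) -> Genealogy:
    """Maximum clade credibility tree of a tree sample.

    Selects the sampled tree maximizing the sum of log clade frequencies
    (ties broken by first occurrence in sample order); annotates each node
    with its clade's support and the mean age of that clade's MRCA over the
    trees that contain the clade.
    """
    lts = _as_linear_list(trees)
    freqs = clade_frequencies(lts)
    age_sums: dict[frozenset, float] = {}
    age_ns: dict[frozenset, int] = {}
    for lt in lts:
        for clade, i in lt.clades():
            age_sums[clade] = age_sums.get(clade, 0.0) + float(lt.age[i])
            age_ns[clade] = age_ns.get(clade, 0) + 1

    best_i, best_score = 0, -np.inf
    for i, lt in enumerate(lts):
        score = sum(np.log(freqs[c]) for c, _ in lt.clades())
        if score > best_score + 1e-12:
            best_i, best_score = i, score
    tree = Genealogy.from_linear(lts[best_i])
    for nd in tree.iter_nodes():
        clade = frozenset(leaf.population for leaf in _leaves_under(nd))
        nd.support = freqs[clade]
        nd.mean_age = age_sums[clade] / age_ns[clade]
    return tree


def _leaves_under(node):
    stack, out = [node], []
    while stack:
        nd = stack.pop()
        if nd.is_leaf():
            out.append(nd)
        stack.extend(nd.children)
    return out


def monochromatic_clade_score(trees, states: dict[int, int]) -> float:
    """Mean fraction of non-trivial clades whose leaves all share one state.

    A clade is non-trivial if it is neither a single leaf nor the full leaf
    set; the score contrasts how strongly a tree sample groups same-state
    populations (posterior samples should score higher than prior samples
    when mutation is rare).
    """
    lts = _as_linear_list(trees)
    total, count = 0.0, 0
    for lt in lts:
        leafset = frozenset(int(p) for p in lt.leaf_populations)
        mono = tot = 0
        for clade, _ in lt.clades():
            if len(clade) <= 1 or clade == leafset:
                continue
            tot += 1
            if len({states[p] for p in clade}) == 1:
                mono += 1
        if tot:
            total += mono / tot
            count += 1
    if count == 0:
        raise ValueError("no tree in the sample has a non-trivial clade")
    return total / count


def state_map(
    obs: ObservationSet,
    marginals: dict[int, np.ndarray] | None = None,
    layout: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabular posterior state map (1-based ids/states, grid coordinates).

    One row per population that is observed or inferred: its coordinates,
    status, the observed state (for data) and the posterior probability of
    each state (for inference targets).
    """
    coords = layout if layout is not None else obs.coords
    if coords is not None and len(coords) != obs.n:
        raise ValueError(f"layout has {len(coords)} rows but n={obs.n}")
    marginals = marginals or {}
    for p in marginals:
        if p not in set(obs.infer_targets):
            raise ValueError(f"population {p} is not an inference target")
    rows = []
    for p in sorted(set(obs.observed) | set(obs.infer_targets)):
        row = {"population_id": p + 1}
        if coords is not None:
            row["row"], row["col"] = int(coords[p][0]), int(coords[p][1])
        if p in obs.observed:
            row["status"] = "observed"
            row["state"] = obs.observed[p] + 1
            for s in range(obs.k):
                row[f"p_state{s+1}"] = 1.0 if obs.observed[p] == s else 0.0
        else:
            row["status"] = "inferred"
            row["state"] = None
            marg = marginals.get(p)
            for s in range(obs.k):
                row[f"p_state{s+1}"] = float(marg[s]) if marg is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
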