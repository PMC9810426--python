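"""Readers and writers for datasets, networks, histories, trees and traces.

All on-disk formats use 1-based population ids and 1-based states, matching
the printed convention P_1..P_n and states 1..k; the in-memory API is
0-based.

Dataset TSV columns: ``population_id  row  col  state`` where ``state`` is
an integer in 1..k, ``?`` for an unobserved population that is ignored, or
``!`` for a population whose state is an inference target.  An optional
``true_state`` column carries the simulated truth for benchmarking.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np
import pandas as pd

from .forward_sim import ObservationSet
from .history import Genealogy

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_explicit_network",
    "write_nexus_trees",
    "write_theta_table",
    "trace_to_dataframe",
    "write_trace",
    "write_metadata",
]


def write_dataset(
    path,
    n: int,
    k: int,
    observed: dict[int, int],
    infer_targets: Iterable[int] = (),
    coords: np.ndarray | None = None,
    true_states: np.ndarray | None = None,
) -> None:
    infer = set(infer_targets)
    with open(path, "w") as fh:
        cols = ["population_id", "row", "col", "state"]
        if true_states is not None:
            cols.append("true_state")
        fh.write("\t".join(cols) + "\n")
        for p in range(n):
            if p in observed:
                state = str(observed[p] + 1)
            elif p in infer:
                state = "!"
            else:
                state = "?"
            r, c = (int(coords[p][0]), int(coords[p][1])) if coords is not None else (0, p)
            row = [str(p + 1), str(r), str(c), state]
            if true_states is not None:
                row.append(str(int(true_states[p]) + 1))
            fh.write("\t".join(row) + "\n")


def read_dataset(path, k: int | None = None) -> ObservationSet:
    """Parse a dataset TSV into an :class:`ObservationSet`."""
    df = pd.read_csv(path, sep="\t", dtype={"state": str})
    for col in ("population_id", "state"):
        if col not in df.columns:
            raise ValueError(f"dataset is missing required column {col!r}")
    ids = df["population_id"].astype(int).to_numpy()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate population ids in dataset")
    n = int(ids.max())
    observed: dict[int, int] = {}
    infer: list[int] = []
    coords = np.zeros((n, 2), dtype=int)
    for _, row in df.iterrows():
        p = int(row["population_id"]) - 1
        if "row" in df.columns:
            coords[p] = (int(row["row"]), int(row["col"]))
        tok = str(row["state"]).strip()
        if tok == "?":
            continue
        if tok == "!":
            infer.append(p)
        else:
            observed[p] = int(tok) - 1
    if not observed:
        raise ValueError("dataset has no observed states (all '?'/'!')")
    if k is None:
        k = max(observed.values()) + 1
    if any(s >= k or s < 0 for s in observed.values()):
        raise ValueError(f"observed states must lie in 1..{k}")
    true_states = None
    if "true_state" in df.columns:
        true_states = np.zeros(n, dtype=int)
        for _, row in df.iterrows():
            true_states[int(row["population_id"]) - 1] = int(row["true_state"]) - 1
    return ObservationSet(
        n=n, k=k, observed=observed, infer_targets=sorted(infer),
        coords=coords if "row" in df.columns else None, true_states=true_states,
    )


def read_explicit_network(node_path, edge_path):
    """Explicit transmission family from a node table and an edge list.

    Node TSV: ``id  x  y  size``; edge TSV: ``i  j  weight`` (1-based ids,
    weight = a_ij).  Rows are validated, never silently renormalized.
    """
    from .models import TransmissionSpec

    nodes = pd.read_csv(node_path, sep="\t")
    edges = pd.read_csv(edge_path, sep="\t")
    n = len(nodes)
    A = np.zeros((n, n))
    for _, e in edges.iterrows():
        A[int(e["i"]) - 1, int(e["j"]) - 1] = float(e["weight"])
    spec = TransmissionSpec.explicit(A)
    coords = nodes[["x", "y"]].to_numpy() if {"x", "y"} <= set(nodes.columns) else None
    sizes = nodes["size"].to_numpy() if "size" in nodes.columns else None
    return spec, coords, sizes


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def write_nexus_trees(path, trees, leaves, tau_max=None, attempted=None) -> None:
    """NEXUS tree log with a translate block (1-based population labels)."""
    leaves = sorted(int(p) for p in leaves)
    labels = {p: str(i + 1) for i, p in enumerate(leaves)}
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\n")
        if tau_max is not None:
            fh.write(f"[tau_max={tau_max} attempted={attempted}]\n")
        fh.write("Begin taxa;\n")
        fh.write(f"    Dimensions ntax={len(leaves)};\n    Taxlabels\n")
        for p in leaves:
            fh.write(f"        P{p + 1}\n")
        fh.write("        ;\nEnd;\n\nBegin trees;\n    Translate\n")
        fh.write(
            ",\n".join(f"        {i + 1} P{p + 1}" for i, p in enumerate(leaves))
        )
        fh.write("\n        ;\n")
        for i, tree in enumerate(trees):
            g = tree if isinstance(tree, Genealogy) else Genealogy.from_linear(tree)
            fh.write(f"tree SAMPLE_{i} = {g.newick(labels=labels)}\n")
        fh.write("End;\n")


# ---------------------------------------------------------------------------
# traces and metadata
# ---------------------------------------------------------------------------


def write_theta_table(path, thetas: list[dict]) -> None:
    pd.DataFrame(thetas).to_csv(path, sep="\t", index=False)


def trace_to_dataframe(trace) -> pd.DataFrame:
    rows = []
    for s in trace.samples:
        row = {"iteration": s.iteration}
        row.update({k: v for k, v in s.theta_tau.items()})
        row.update({k: v for k, v in s.theta_mu.items()})
        row["S"] = s.S + 1
        for p, st in sorted(s.X.items()):
            row[f"X_P{p + 1}"] = st + 1
        row["tmrca"] = s.tmrca
        row["log_likelihood"] = s.log_likelihood
        row["log_posterior"] = s.log_posterior
        rows.append(row)
    return pd.DataFrame(rows)


def write_trace(path, trace) -> None:
    trace_to_dataframe(trace).to_csv(path, sep="\t", index=False)


def write_metadata(path, **fields) -> None:
    """Run-metadata JSON: config echo, seed, acceptance rates, versions."""
    import netcoal

    fields.setdefault("netcoal_version", netcoal.__version__)
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, default=str)
        fh.write("\n")
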