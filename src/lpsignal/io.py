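"""Plain-text file formats: networks (edge TSV / SIF), node tables,
observation and design matrices.

All tabular formats are tab-separated with a header row; missing values
are written and read as ``NA``.  Network round-trips (write -> read) are
identity up to float formatting.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import KnockdownDesign, ObservationMatrix, ReplicatedObservations
from .network import SignalingNetwork, Thresholds

__all__ = [
    "read_network",
    "write_network",
    "read_node_table",
    "write_node_table",
    "apply_node_table",
    "read_design",
    "read_tables",
    "write_tables",
    "read_observations",
    "write_observations",
]


def write_network(net: SignalingNetwork, path, dialect: str = "edge_tsv") -> None:
    path = Path(path)
    lines = []
    if dialect == "edge_tsv":
        lines.append("source\ttarget\tweight")
        for src, tgt, w in net.edges():
            lines.append(f"{src}\t{tgt}\t{w:g}")
    elif dialect == "sif":
        lines.append("source\tinteraction\ttarget\tmagnitude")
        for src, tgt, w in net.edges():
            kind = "activates" if w > 0 else "inhibits"
            lines.append(f"{src}\t{kind}\t{tgt}\t{abs(w):g}")
    else:
        raise ValueError(f"unknown network dialect: {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


def read_network(
    path,
    dialect: str = "edge_tsv",
    nodes: list[str] | None = None,
) -> SignalingNetwork:
    """Read a network; errors report 1-based line numbers.

    When ``nodes`` is given, edges must reference that node set and the
    returned network uses its ordering; otherwise nodes are collected from
    the edges in order of first appearance.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    if not raw:
        raise ValueError(f"{path}: empty network file")
    edges: list[tuple[str, str, float]] = []
    seen: dict[tuple[str, str], int] = {}
    order: list[str] = [] if nodes is None else list(nodes)
    known = None if nodes is None else set(nodes)

    for ln, line in enumerate(raw[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            if dialect == "edge_tsv":
                src, tgt, w_s = parts[0], parts[1], parts[2]
                w = float(w_s)
            elif dialect == "sif":
                src, kind, tgt = parts[0], parts[1], parts[2]
                mag = float(parts[3]) if len(parts) > 3 and parts[3] else 1.0
                if kind == "activates":
                    w = mag
                elif kind == "inhibits":
                    w = -mag
                else:
                    raise ValueError(f"unknown interaction {kind!r}")
            else:
                raise ValueError(f"unknown network dialect: {dialect!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{ln}: malformed row: {exc}") from exc
        if src == tgt:
            raise ValueError(f"{path}:{ln}: self-loop on {src!r}")
        if (src, tgt) in seen:
            raise ValueError(
                f"{path}:{ln}: duplicate edge ({src}, {tgt}), first at line {seen[(src, tgt)]}"
            )
        seen[(src, tgt)] = ln
        if known is not None:
            for lab in (src, tgt):
                if lab not in known:
                    raise ValueError(f"{path}:{ln}: unknown node {lab!r}")
        else:
            for lab in (src, tgt):
                if lab not in order:
                    order.append(lab)
        edges.append((src, tgt, w))
    return SignalingNetwork.from_edges(order, edges)


def write_node_table(
    net: SignalingNetwork, theta: Thresholds, path
) -> None:
    lines = ["node\tbias\ttheta\tis_source\tis_sink"]
    for i, lab in enumerate(net.nodes):
        lines.append(
            f"{lab}\t{net.bias[i]:g}\t{theta.theta[i]:g}"
            f"\t{int(lab in net.sources)}\t{int(lab in net.sinks)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_node_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"node": str})
    required = {"node", "bias", "theta", "is_source", "is_sink"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: node table missing columns {sorted(missing)}")
    return df


def apply_node_table(net: SignalingNetwork, table: pd.DataFrame) -> tuple[SignalingNetwork, Thresholds]:
    """Attach bias/theta/source/sink annotations to a network's nodes."""
    table = table.set_index("node")
    unknown = set(table.index) - set(net.nodes)
    if unknown:
        raise ValueError(f"node table references unknown nodes: {sorted(unknown)}")
    bias = np.array([table["bias"].get(lab, 0.0) for lab in net.nodes], dtype=float)
    theta = np.array([table["theta"].get(lab, np.nan) for lab in net.nodes], dtype=float)
    sources = frozenset(lab for lab in net.nodes
                        if lab in table.index and table.loc[lab, "is_source"])
    sinks = frozenset(lab for lab in net.nodes
                      if lab in table.index and table.loc[lab, "is_sink"])
    out = SignalingNetwork(list(net.nodes), net.weights.copy(), bias, sources, sinks)
    return out, Thresholds(theta)


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus gene columns")
    return df


def write_tables(D: ObservationMatrix, Z: KnockdownDesign, obs_path, design_path) -> None:
    D.to_frame().to_csv(obs_path, sep="\t", index_label="experiment", na_rep="NA")
    Z.to_frame().to_csv(design_path, sep="\t", index_label="experiment")


def read_design(
    design_path,
    genes: list[str] | None = None,
    experiment_ids: list[str] | None = None,
) -> KnockdownDesign:
    """Read a design TSV; when ``genes`` is given, columns are aligned by
    header (not position) and experiment ids must match row-for-row."""
    ddf = _read_matrix(design_path)
    ddf = ddf.set_index(ddf.columns[0])
    if genes is not None:
        missing_genes = set(genes) - set(ddf.columns)
        if missing_genes:
            raise ValueError(
                f"{design_path}: design lacks gene columns {sorted(missing_genes)}"
            )
        ddf = ddf[genes]
    if experiment_ids is not None and list(ddf.index.astype(str)) != list(experiment_ids):
        raise ValueError("experiment ids differ between observations and design")
    vals = ddf.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{design_path}: design entries must be 0 or 1")
    return KnockdownDesign(vals, list(ddf.index.astype(str)), list(ddf.columns))


def read_tables(obs_path, design_path) -> tuple[ObservationMatrix, KnockdownDesign]:
    """Read paired observation/design TSVs, aligning genes by header.

    The design's columns are reordered to the observation file's gene
    order; experiment ids must match row-for-row.
    """
    obs = read_observations(obs_path)
    if isinstance(obs, ReplicatedObservations):
        raise ValueError(
            f"{obs_path}: contains a replicate column; summarize replicates first"
        )
    design = read_design(design_path, genes=obs.genes, experiment_ids=obs.experiment_ids)
    return obs, design


def write_observations(
    obs: ObservationMatrix | ReplicatedObservations, path
) -> None:
    """Write observations; replicated data uses a long format with a
    ``replicate`` column after the experiment id."""
    if isinstance(obs, ReplicatedObservations):
        rows = []
        for r in range(obs.n_replicates):
            df = pd.DataFrame(obs.values[r], index=obs.experiment_ids, columns=obs.genes)
            df.insert(0, "replicate", r + 1)
            rows.append(df)
        out = pd.concat(rows).sort_index(kind="stable")
        out.to_csv(path, sep="\t", index_label="experiment", na_rep="NA")
    else:
        obs.to_frame().to_csv(path, sep="\t", index_label="experiment", na_rep="NA")


def read_observations(path) -> ObservationMatrix | ReplicatedObservations:
    """Read an observation TSV; a ``replicate`` column triggers long format."""
    df = _read_matrix(path)
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    if "replicate" in df.columns[1:]:
        genes = [c for c in df.columns[1:] if c != "replicate"]
        exp_ids = list(dict.fromkeys(df[id_col]))
        reps = sorted(df["replicate"].unique())
        values = np.full((len(reps), len(exp_ids), len(genes)), np.nan)
        rindex = {r: pos for pos, r in enumerate(reps)}
        eindex = {e: pos for pos, e in enumerate(exp_ids)}
        for _, row in df.iterrows():
            values[rindex[row["replicate"]], eindex[row[id_col]], :] = (
                row[genes].to_numpy(dtype=float)
            )
        return ReplicatedObservations(values, exp_ids, genes)
    genes = list(df.columns[1:])
    return ObservationMatrix(
        df[genes].to_numpy(dtype=float), list(df[id_col]), genes
    )
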