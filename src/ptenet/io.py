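"""Plain-text serialization: connectomes, cohorts, epoch sets, viewer exports.

Everything is delimited text or JSON so runs are diffable and portable:
connectomes are dense matrices with a one-line header naming the weight
kind, cohorts are one matrix file per subject plus a subject table and the
ground-truth edge list, and significant networks can be exported in the
BrainNet Viewer ``.node`` / ``.edge`` convention.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CouplingSpec, SourceTimeSeries, SubjectRecord
from .preprocess import EpochSet
from .pte import WEIGHT_KINDS, Connectome
from .stats import SignificantNetwork

__all__ = [
    "write_connectome",
    "read_connectome",
    "write_cohort",
    "read_cohort",
    "write_epochs",
    "read_epochs",
    "write_network",
    "export_brainnet",
]


def write_connectome(connectome: Connectome, path: str | Path) -> None:
    """Dense matrix file with a ``# weight_kind=<kind> n=<nodes>`` header."""
    path = Path(path)
    header = f"weight_kind={connectome.weight_kind} n={connectome.n_nodes}"
    np.savetxt(path, connectome.weights, header=header, fmt="%.17g")


def read_connectome(path: str | Path) -> Connectome:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#") or "weight_kind=" not in first:
        raise ValueError(f"{path}: missing 'weight_kind=... n=...' header")
    fields = dict(tok.split("=", 1) for tok in first.lstrip("# ").split())
    kind = fields.get("weight_kind")
    if kind not in WEIGHT_KINDS:
        raise ValueError(f"{path}: unknown weight_kind {kind!r}")
    weights = np.loadtxt(path, ndmin=2)
    n = int(fields.get("n", weights.shape[0]))
    if weights.shape != (n, n):
        raise ValueError(f"{path}: expected a {n} x {n} matrix, got {weights.shape}")
    return Connectome(weights=weights, weight_kind=kind)


def write_cohort(
    cohort: list[tuple[SourceTimeSeries, SubjectRecord]],
    out_dir: str | Path,
    spec_control: CouplingSpec | None = None,
    spec_patient: CouplingSpec | None = None,
) -> None:
    """One ``<subject>.tsv`` matrix per subject + subject table + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, rec in cohort:
        np.savetxt(out / f"{rec.subject_id}.tsv", ts.data, delimiter="\t", fmt="%.8g",
                   header=f"fs={ts.fs}")
        rows.append({"subject_id": rec.subject_id, "group": rec.group, **rec.scores})
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)
    for name, spec in (("control", spec_control), ("patient", spec_patient)):
        if spec is not None:
            pd.DataFrame(
                list(spec.edges), columns=["source", "target", "strength", "delay"]
            ).to_csv(out / f"ground_truth_{name}.tsv", sep="\t", index=False)


def read_cohort(in_dir: str | Path) -> list[tuple[SourceTimeSeries, SubjectRecord]]:
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "subjects.tsv", sep="\t")
    cohort = []
    for _, row in table.iterrows():
        sid = row["subject_id"]
        path = in_dir / f"{sid}.tsv"
        with open(path) as fh:
            first = fh.readline()
        fs = float(first.lstrip("# ").split("=", 1)[1]) if "fs=" in first else 1.0
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
        scores = {
            k: float(v)
            for k, v in row.items()
            if k not in ("subject_id", "group") and pd.notna(v)
        }
        cohort.append(
            (
                SourceTimeSeries(data=data, fs=fs, subject_id=sid),
                SubjectRecord(subject_id=sid, group=row["group"], scores=scores),
            )
        )
    return cohort


def write_epochs(epoch_set: EpochSet, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, ep in enumerate(epoch_set.epochs):
        np.savetxt(out / f"epoch{i:02d}.tsv", ep, delimiter="\t", fmt="%.8g")
    meta = {
        "fs": epoch_set.fs,
        "epoch_starts": [int(s) for s in epoch_set.epoch_starts],
        "subject_id": epoch_set.subject_id,
    }
    (out / "epochs.json").write_text(json.dumps(meta, indent=2))


def read_epochs(in_dir: str | Path) -> EpochSet:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "epochs.json").read_text())
    epochs = [
        np.loadtxt(p, delimiter="\t", ndmin=2) for p in sorted(in_dir.glob("epoch*.tsv"))
    ]
    return EpochSet(
        epochs=epochs,
        fs=meta["fs"],
        epoch_starts=np.asarray(meta["epoch_starts"], dtype=int),
        subject_id=meta.get("subject_id", ""),
    )


def write_network(net: SignificantNetwork, stats, path: str | Path) -> None:
    """Edge list (source, target, t, p, p significant under the mask) + JSON summary."""
    path = Path(path)
    rows = [
        {"source": s, "target": t, "t": tv, "p": float(stats.p[s, t])}
        for s, t, tv in net.edges
    ]
    pd.DataFrame(rows, columns=["source", "target", "t", "p"]).to_csv(
        path, sep="\t", index=False
    )
    summary = {
        "n_nodes": len(net.nodes),
        "n_edges": net.n_edges,
        "alpha_q": net.alpha_q,
        "n_permutations": int(stats.n_permutations),
        "test_kind": stats.test_kind,
    }
    path.with_suffix(".json").write_text(json.dumps(summary, indent=2))


def export_brainnet(
    net: SignificantNetwork,
    coords: np.ndarray,
    path_prefix: str | Path,
    labels: list[str] | None = None,
) -> None:
    """BrainNet Viewer export: ``.node`` (x y z color size label) + ``.edge``.

    Node size carries node strength; node color marks membership in the
    significant network (1) vs isolated (0).  The ``.edge`` file is the full
    N x N weight matrix.
    """
    from .graphs import node_strength  # local import to avoid a cycle

    prefix = Path(path_prefix)
    n = net.n_nodes_total or (max(net.nodes) + 1 if net.nodes else 0)
    coords = np.asarray(coords, dtype=float)
    if net.n_edges == 0:
        warnings.warn("exporting an empty network", stacklevel=2)
        prefix.with_suffix(".node").write_text("")
        prefix.with_suffix(".edge").write_text("")
        return
    if coords.shape != (n, 3):
        raise ValueError(f"need coordinates for all {n} nodes, got {coords.shape}")
    if labels is None:
        labels = [f"node{i}" for i in range(n)]
    strengths = node_strength(net, n)
    lines = []
    for i in range(n):
        color = 1 if i in net.nodes else 0
        x, y, z = coords[i]
        lines.append(f"{x:.3f}\t{y:.3f}\t{z:.3f}\t{color}\t{strengths[i]:.6g}\t{labels[i]}")
    prefix.with_suffix(".node").write_text("\n".join(lines) + "\n")
    np.savetxt(prefix.with_suffix(".edge"), net.to_matrix(n), delimiter="\t", fmt="%.6g")
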