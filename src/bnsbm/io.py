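"""Serialization: TSV matrices, JSON fits and run configurations.

One tabular dialect is used throughout: UTF-8 tab-separated values with a
header row and the first column holding identifiers. Matrices are oriented
rows = axis-1 features (e.g. taxa), columns = axis-2 features (e.g.
metabolites). Parameters, fits and run configurations are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import BlockModelParams, DensitySpec, LatentTruth, ScoreMatrix, VariationalState
from .vem import FitOptions, FitResult
from .zscores import OmicsBlock


# ---------------------------------------------------------------------------
# TSV


def read_score_matrix(path) -> ScoreMatrix:
    """Read a score matrix from TSV (header = column ids, first column = row ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    bad = df.columns[~df.dtypes.apply(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValueError(f"malformed TSV {path}: non-numeric column {bad[0]!r}")
    nan = np.argwhere(df.isna().values)
    if nan.size:
        i, j = nan[0]
        raise ValueError(f"malformed TSV {path}: missing value at row {i + 2}, column {j + 2}")
    return ScoreMatrix(df.values, list(df.index), list(df.columns))


def write_score_matrix(X: ScoreMatrix, path) -> None:
    pd.DataFrame(X.values, index=X.row_ids, columns=X.col_ids).to_csv(path, sep="\t")


def write_int_matrix(values: np.ndarray, row_ids, col_ids, path) -> None:
    pd.DataFrame(np.asarray(values, dtype=int), index=row_ids, columns=col_ids).to_csv(
        path, sep="\t"
    )


def write_memberships(labels: np.ndarray, ids, path) -> None:
    """One-based block labels keyed by identifier."""
    pd.DataFrame({"id": list(ids), "block": np.asarray(labels) + 1}).to_csv(
        path, sep="\t", index=False
    )


def read_omics_block(path) -> OmicsBlock:
    """Read a samples x features TSV (header = feature ids, first column = sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    return OmicsBlock(df.values, list(df.index), list(df.columns))


def read_groups(path) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"group file {path} must have exactly two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


# ---------------------------------------------------------------------------
# JSON


def _theta_to_dict(theta: BlockModelParams) -> dict:
    return {
        "alpha1": theta.alpha1.tolist(),
        "alpha2": theta.alpha2.tolist(),
        "Pi": theta.Pi.tolist(),
        "nu0": {
            "family": theta.nu0.family,
            "params": list(theta.nu0.params),
            "n_free_params": theta.nu0.n_free_params,
        },
        "nu": [
            [
                {"family": d.family, "params": list(d.params), "n_free_params": d.n_free_params}
                for d in row
            ]
            for row in theta.nu
        ],
    }


def _theta_from_dict(d: dict) -> BlockModelParams:
    mk = lambda s: DensitySpec(s["family"], tuple(s["params"]), s["n_free_params"])
    return BlockModelParams(
        alpha1=np.asarray(d["alpha1"]),
        alpha2=np.asarray(d["alpha2"]),
        Pi=np.asarray(d["Pi"]),
        nu0=mk(d["nu0"]),
        nu=[[mk(s) for s in row] for row in d["nu"]],
    )


def fit_to_json(fit: FitResult, path) -> None:
    doc = {
        "theta": _theta_to_dict(fit.theta_hat),
        "beta1": fit.state.beta1.tolist(),
        "beta2": fit.state.beta2.tolist(),
        "Z1_hat": fit.Z1_hat.tolist(),
        "Z2_hat": fit.Z2_hat.tolist(),
        "elbo_trace": fit.elbo_trace.tolist(),
        "converged": bool(fit.converged),
        "icl": fit.icl,
        "options": dataclasses.asdict(fit.options) if fit.options else None,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def fit_from_json(path) -> FitResult:
    doc = json.loads(Path(path).read_text())
    return FitResult(
        theta_hat=_theta_from_dict(doc["theta"]),
        state=VariationalState(np.asarray(doc["beta1"]), np.asarray(doc["beta2"])),
        Z1_hat=np.asarray(doc["Z1_hat"], dtype=int),
        Z2_hat=np.asarray(doc["Z2_hat"], dtype=int),
        elbo_trace=np.asarray(doc["elbo_trace"]),
        converged=doc["converged"],
        icl=doc["icl"],
        options=FitOptions(**doc["options"]) if doc.get("options") else None,
    )


@dataclass
class RunConfig:
    """A serializable record of one command invocation.

    Round-trips losslessly through a single JSON document; unknown keys are
    rejected on load so stale configurations fail loudly.
    """

    command: str
    options: dict

    def to_json(self, path=None) -> str:
        text = json.dumps({"command": self.command, "options": self.options}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "RunConfig":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        doc = json.loads(text)
        unknown = set(doc) - {"command", "options"}
        if unknown:
            raise ValueError(f"unknown keys in run configuration: {sorted(unknown)}")
        if not isinstance(doc.get("command"), str) or not isinstance(doc.get("options"), dict):
            raise ValueError("run configuration must carry 'command' (str) and 'options' (dict)")
        return cls(command=doc["command"], options=doc["options"])


def export_rejected_graphml(X: ScoreMatrix, reject: np.ndarray, path) -> None:
    """Write the rejected-edge bipartite network as GraphML for viewers."""
    import networkx as nx

    G = nx.Graph()
    for r in X.row_ids:
        G.add_node(f"row:{r}", bipartite=0, label=r)
    for c in X.col_ids:
        G.add_node(f"col:{c}", bipartite=1, label=c)
    for i, j in np.argwhere(np.asarray(reject) == 1):
        G.add_edge(f"row:{X.row_ids[i]}", f"col:{X.col_ids[j]}", score=float(X.values[i, j]))
    nx.write_graphml(G, path)


def write_latent_truth(truth: LatentTruth, X: ScoreMatrix, prefix) -> None:
    """Write A, Z1, Z2 next to a simulated score matrix under a path prefix."""
    prefix = str(prefix)
    write_int_matrix(truth.A, X.row_ids, X.col_ids, prefix + ".A.tsv")
    write_memberships(truth.Z1, X.row_ids, prefix + ".Z1.tsv")
    write_memberships(truth.Z2, X.col_ids, prefix + ".Z2.tsv")
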