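"""Export of generated models and simulation results.

Qualitative models are written in the BooleanNet text dialect
(``Node* = A and not B``); probabilistic models in the BoolNet dialect for
probabilistic networks (``targets, factors, probabilities`` header, one
rule per line with ``& | !`` operators).  Node identifiers containing
characters those dialects reject (``--``, ``{P}``, brackets) are
sanitized; the original ↔ sanitized mapping is emitted as a sidecar TSV.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .bbn import BipartiteBooleanModel
from .simulate import TrajectoryEnsemble

__all__ = [
    "sanitize_names",
    "write_booleannet",
    "write_boolnet",
    "write_name_map",
    "ensemble_mean_frame",
    "write_trajectory_tsv",
    "write_mean_tsv",
    "write_heatmap_matrix",
]

_ILLEGAL = re.compile(r"[^A-Za-z0-9_]")


def sanitize_names(names: list[str]) -> dict[str, str]:
    """Deterministic map of node ids to dialect-safe identifiers."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        clean = _ILLEGAL.sub("_", name)
        clean = re.sub(r"_+", "_", clean).strip("_")
        if not clean or not clean[0].isalpha():
            clean = "n_" + clean
        candidate, k = clean, 1
        while candidate in used:
            k += 1
            candidate = f"{clean}_{k}"
        mapping[name] = candidate
        used.add(candidate)
    return mapping


def _format_prob(p: float) -> str:
    text = f"{p:.6f}".rstrip("0").rstrip(".")
    return text or "0"


def write_booleannet(model: BipartiteBooleanModel) -> tuple[str, dict[str, str]]:
    """Qualitative model as BooleanNet rules; returns (text, name map)."""
    names = sanitize_names(model.nodes)
    lines = []
    for node in model.nodes:
        expr = model.single_rule(node)
        rhs = expr.to_text("booleannet")
        for orig, clean in names.items():
            rhs = _replace_ident(rhs, orig, clean)
        lines.append(f"{names[node]}* = {rhs}")
    return "\n".join(lines) + "\n", names


def write_boolnet(model: BipartiteBooleanModel) -> tuple[str, dict[str, str]]:
    """Probabilistic model in BoolNet format; returns (text, name map).

    Reaction nodes emit one line per update rule with its reported
    probability (six-decimal residue convention); deterministic nodes emit
    a single line with probability 1.
    """
    names = sanitize_names(model.nodes)
    lines = ["targets, factors, probabilities"]
    for node in model.nodes:
        rules = model.rules[node]
        reported = model.reported_probabilities.get(node)
        probs = reported if reported is not None else [p for _, p in rules]
        for (expr, _), p in zip(rules, probs):
            rhs = expr.to_text("boolnet")
            for orig, clean in names.items():
                rhs = _replace_ident(rhs, orig, clean)
            lines.append(f"{names[node]}, {rhs}, {_format_prob(p)}")
    return "\n".join(lines) + "\n", names


def _replace_ident(text: str, orig: str, clean: str) -> str:
    if orig == clean:
        return text
    return re.sub(rf"(?<![\w]){re.escape(orig)}(?![\w])", clean, text)


def write_name_map(names: dict[str, str], path: str | Path) -> None:
    frame = pd.DataFrame(
        {"original": list(names), "sanitized": list(names.values())}
    )
    frame.to_csv(path, sep="\t", index=False)


def ensemble_mean_frame(ensemble: TrajectoryEnsemble) -> pd.DataFrame:
    frame = pd.DataFrame(ensemble.mean(), columns=ensemble.nodes)
    frame.index.name = "time"
    return frame


def write_trajectory_tsv(
    trajectory: np.ndarray, nodes: list[str], path: str | Path
) -> None:
    """Single run as TSV: ``time`` column plus one 0/1 column per node."""
    frame = pd.DataFrame(trajectory.astype(int), columns=nodes)
    frame.index.name = "time"
    frame.to_csv(path, sep="\t")


def write_mean_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.6g")


def write_heatmap_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    """Wide nodes × time matrix of means (heat-map layout)."""
    frame.T.to_csv(path, sep="\t", float_format="%.6g")


def read_mean_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="time")
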