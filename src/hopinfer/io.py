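"""Plain-text readers/writers for patterns, spin datasets and couplings.

Matrix files are tab-separated, one row per pattern/sample, entries written
as "+1"/"-1" ("1"/"-1" accepted on read).  Comment lines start with '#'.
A '#meta' header line carries run metadata as key=value pairs.
Coupling files are tab-separated N x N real matrices with the same comment
convention.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np

from .model import CouplingMatrix, SpinDataset, TeacherModel

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_teacher",
    "read_teacher",
    "write_dataset",
    "read_dataset",
    "write_coupling",
    "read_coupling",
]


def _format_meta(meta: dict) -> str:
    return "#meta " + " ".join(f"{k}={v}" for k, v in meta.items())


def _parse_meta(path: Path) -> dict:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#meta"):
                for tok in line[len("#meta"):].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
            elif not line.startswith("#"):
                break
    return meta


def write_matrix(path: str | Path, a: np.ndarray, meta: dict | None = None,
                 fmt: str = "%+d") -> None:
    path = Path(path)
    buf = _io.StringIO()
    if meta:
        buf.write(_format_meta(meta) + "\n")
    np.savetxt(buf, np.asarray(a), fmt=fmt, delimiter="\t")
    path.write_text(buf.getvalue())


def read_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    a = np.loadtxt(path, comments="#", delimiter="\t", ndmin=2)
    return a, _parse_meta(path)


def write_teacher(path: str | Path, teacher: TeacherModel,
                  seed: int | None = None) -> None:
    meta = {"N": teacher.N, "P": teacher.P, "beta": teacher.beta}
    if seed is not None:
        meta["seed"] = seed
    write_matrix(path, teacher.patterns.astype(int), meta=meta)


def read_teacher(path: str | Path, beta: float | None = None) -> TeacherModel:
    a, meta = read_matrix(path)
    if beta is None:
        if "beta" not in meta:
            raise ValueError(f"{path}: no beta in #meta header and none given")
        beta = float(meta["beta"])
    return TeacherModel(patterns=a, beta=beta)


def write_dataset(path: str | Path, dataset: SpinDataset,
                  meta: dict | None = None) -> None:
    full = {"M": dataset.M, "N": dataset.N}
    if meta:
        full.update(meta)
    if dataset.state_labels is not None:
        full["state_labels"] = ",".join(str(i) for i in dataset.state_labels)
    write_matrix(path, dataset.samples.astype(int), meta=full)


def read_dataset(path: str | Path) -> SpinDataset:
    a, meta = read_matrix(path)
    labels = None
    if "state_labels" in meta:
        labels = np.array([int(x) for x in meta["state_labels"].split(",")])
    return SpinDataset(samples=a, state_labels=labels)


def write_coupling(path: str | Path, J: CouplingMatrix,
                   meta: dict | None = None) -> None:
    full = {"N": J.n, "diagonal_included": int(J.diagonal_included)}
    if meta:
        full.update(meta)
    write_matrix(path, J.J, meta=full, fmt="%.17g")


def read_coupling(path: str | Path) -> CouplingMatrix:
    a, meta = read_matrix(path)
    a = (a + a.T) / 2.0  # guard against last-digit asymmetry on round-trip
    diag = bool(int(meta.get("diagonal_included", 1)))
    return CouplingMatrix(J=a, diagonal_included=diag)
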